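"""Per-read alignment decoding.

Everything downstream (coverage, pileups, SNP/InDel tracks, read glyphs)
consumes the facts extracted here from a single alignment record: reference
blocks split at splice gaps, mismatches reconstructed from the MD tag without
touching the reference genome, insertions/deletions from the CIGAR (deleted
bases from the MD ^-runs), the transcript strand under the library protocol,
and the signature used to collapse exact duplicate reads.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .formats_io import GenomicInterval

CIGAR_OPS = "MIDNSHP=X"
_QUERY_CONSUMING = frozenset("MIS=X")
_REF_CONSUMING = frozenset("MDN=X")
_ALIGNED = frozenset("M=X")  # base-to-base aligned ops

PROTOCOLS = ("unstranded", "fr_firststrand", "fr_secondstrand")

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_MD_TOKEN_RE = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


class AlignmentError(ValueError):
    """Inconsistent CIGAR/MD/sequence on a record."""


@dataclass(frozen=True)
class CigarOp:
    op: str
    length: int

    def __post_init__(self) -> None:
        if self.op not in CIGAR_OPS:
            raise ValueError(f"unknown CIGAR op {self.op!r}")
        if self.length < 1:
            raise ValueError(f"CIGAR op length must be >= 1, got {self.length}")


def parse_cigar(text: str) -> tuple[CigarOp, ...]:
    if text in ("*", ""):
        return ()
    ops = tuple(CigarOp(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(text))
    if "".join(f"{o.length}{o.op}" for o in ops) != text:
        raise AlignmentError(f"malformed CIGAR string {text!r}")
    return ops


@dataclass(frozen=True)
class AlignedRead:
    """One alignment record's facts, decoupled from the underlying BAM API."""

    read_id: str
    chrom: str
    pos: int  # 0-based leftmost reference offset
    cigar: tuple[CigarOp, ...]
    seq: str
    quals: tuple[int, ...]
    md: str | None = None
    is_reverse: bool = False
    is_paired: bool = False
    is_first_in_pair: bool = False
    is_proper_pair: bool = False
    mate_chrom: str | None = None
    mate_pos: int | None = None
    mapq: int = 0

    def __post_init__(self) -> None:
        if self.seq:
            qlen = sum(op.length for op in self.cigar if op.op in _QUERY_CONSUMING)
            if qlen != len(self.seq):
                raise AlignmentError(
                    f"{self.read_id}: CIGAR query length {qlen} != seq length "
                    f"{len(self.seq)}"
                )
            if len(self.quals) != len(self.seq):
                raise AlignmentError(f"{self.read_id}: quals/seq length mismatch")

    @property
    def cigar_string(self) -> str:
        return "".join(f"{o.length}{o.op}" for o in self.cigar)

    @property
    def strand(self) -> str:
        """Alignment (not transcript) strand."""
        return "-" if self.is_reverse else "+"

    @property
    def reference_end(self) -> int:
        return self.pos + sum(o.length for o in self.cigar if o.op in _REF_CONSUMING)

    @classmethod
    def from_pysam(cls, rec) -> "AlignedRead":
        """Build from a pysam AlignedSegment."""
        md = None
        if rec.has_tag("MD"):
            md = rec.get_tag("MD")
        quals = tuple(rec.query_qualities) if rec.query_qualities is not None else ()
        seq = rec.query_sequence or ""
        if not quals and seq:
            quals = (0,) * len(seq)
        return cls(
            read_id=rec.query_name,
            chrom=rec.reference_name,
            pos=rec.reference_start,
            cigar=parse_cigar(rec.cigarstring or "*"),
            seq=seq,
            quals=quals,
            md=md,
            is_reverse=rec.is_reverse,
            is_paired=rec.is_paired,
            is_first_in_pair=rec.is_read1 if rec.is_paired else True,
            is_proper_pair=rec.is_proper_pair,
            mate_chrom=(rec.next_reference_name
                        if rec.is_paired and rec.next_reference_id >= 0 else None),
            mate_pos=(rec.next_reference_start
                      if rec.is_paired and rec.next_reference_start >= 0 else None),
            mapq=rec.mapping_quality,
        )


@dataclass(frozen=True)
class Mismatch:
    ref_pos: int
    ref_base: str
    read_base: str
    base_qual: int

    def __post_init__(self) -> None:
        if self.ref_base == self.read_base:
            raise ValueError("mismatch with identical bases")


@dataclass(frozen=True)
class InsertionEvent:
    """Insertion; ref_pos is the reference base immediately after the insert."""

    ref_pos: int
    inserted_seq: str

    def __post_init__(self) -> None:
        if not self.inserted_seq:
            raise ValueError("inserted_seq must be non-empty")


@dataclass(frozen=True)
class DeletionEvent:
    ref_start: int
    deleted_seq: str

    def __post_init__(self) -> None:
        if not self.deleted_seq:
            raise ValueError("deleted_seq must be non-empty")

    @property
    def ref_end(self) -> int:
        return self.ref_start + len(self.deleted_seq)


@dataclass(frozen=True)
class MdToken:
    kind: str  # match_run | mismatch | deletion
    length: int = 0
    base: str = ""
    deleted_seq: str = ""


# ---------------------------------------------------------------------------
# MD tag
# ---------------------------------------------------------------------------


def parse_md(md: str) -> list[MdToken]:
    """Tokenize an MD tag string.

    Grammar: ``[0-9]+(([A-Z]|\\^[A-Z]+)[0-9]+)*``.  Zero-length match runs are
    kept (they separate adjacent events in the grammar but span no bases).
    """
    tokens: list[MdToken] = []
    offset = 0
    for m in _MD_TOKEN_RE.finditer(md):
        if m.start() != offset:
            raise AlignmentError(f"MD tag {md!r}: unparsable at offset {offset}")
        if m.group(1) is not None:
            tokens.append(MdToken("match_run", length=int(m.group(1))))
        elif m.group(2) is not None:
            tokens.append(MdToken("deletion", deleted_seq=m.group(2)[1:].upper()))
        else:
            tokens.append(MdToken("mismatch", base=m.group(3).upper()))
        offset = m.end()
    if offset != len(md):
        raise AlignmentError(f"MD tag {md!r}: unparsable at offset {offset}")
    if not tokens or tokens[0].kind != "match_run":
        raise AlignmentError(f"MD tag {md!r}: must start with a match count")
    return tokens


def md_reference_span(tokens: Iterable[MdToken]) -> int:
    """Reference bases implied by the tokens (matches + mismatches + deletions)."""
    span = 0
    for t in tokens:
        if t.kind == "match_run":
            span += t.length
        elif t.kind == "mismatch":
            span += 1
        else:
            span += len(t.deleted_seq)
    return span


# ---------------------------------------------------------------------------
# CIGAR geometry
# ---------------------------------------------------------------------------


def reference_blocks(read: AlignedRead) -> tuple[list[GenomicInterval], list[DeletionEvent]]:
    """Maximal reference-consuming runs, split only at N (splice) ops.

    M/D/=/X merge into one block so a small deletion does not break a read
    glyph; the deletions are reported separately (sequence from MD when
    available, else ``N`` placeholders) for annotation.
    """
    _, deletions = extract_indels(read)
    blocks: list[GenomicInterval] = []
    ref = read.pos
    block_start: int | None = None
    for op in read.cigar:
        if op.op in ("M", "=", "X", "D"):
            if block_start is None:
                block_start = ref
            ref += op.length
        elif op.op == "N":
            if block_start is not None:
                blocks.append(GenomicInterval(read.chrom, block_start, ref))
                block_start = None
            ref += op.length
        # I/S/H/P consume no reference
    if block_start is not None:
        blocks.append(GenomicInterval(read.chrom, block_start, ref))
    return blocks, deletions


def aligned_pairs(read: AlignedRead) -> list[tuple[int, int]]:
    """(query_offset, ref_pos) for every M/=/X-aligned base."""
    pairs = []
    q, r = 0, read.pos
    for op in read.cigar:
        if op.op in _ALIGNED:
            for i in range(op.length):
                pairs.append((q + i, r + i))
            q += op.length
            r += op.length
        elif op.op in ("I", "S"):
            q += op.length
        elif op.op in ("D", "N"):
            r += op.length
    return pairs


# ---------------------------------------------------------------------------
# Mismatch and indel extraction
# ---------------------------------------------------------------------------


def extract_mismatches(read: AlignedRead) -> list[Mismatch]:
    """Mismatches reconstructed from MD + CIGAR + query sequence.

    The MD tag walks reference positions of M/=/X and D ops only; insertions
    and clips shift the query cursor without advancing MD.  The returned
    count always equals the number of MD mismatch tokens.
    """
    if read.md is None:
        raise AlignmentError(f"{read.read_id}: MD tag required for mismatch extraction")
    if not read.seq:
        raise AlignmentError(f"{read.read_id}: sequence required for mismatch extraction")
    tokens = parse_md(read.md)
    cigar_span = sum(o.length for o in read.cigar if o.op in ("M", "=", "X", "D"))
    md_span = md_reference_span(tokens)
    if md_span != cigar_span:
        raise AlignmentError(
            f"{read.read_id}: MD span {md_span} != CIGAR reference span {cigar_span}"
        )
    # Map "MD walk offset" (position along M/D ops) -> (query_offset|None, ref_pos)
    walk: list[tuple[int | None, int]] = []
    q, r = 0, read.pos
    for op in read.cigar:
        if op.op in _ALIGNED:
            for i in range(op.length):
                walk.append((q + i, r + i))
            q += op.length
            r += op.length
        elif op.op == "D":
            for i in range(op.length):
                walk.append((None, r + i))
            r += op.length
        elif op.op == "N":
            r += op.length
        elif op.op in ("I", "S"):
            q += op.length
    mismatches: list[Mismatch] = []
    cursor = 0
    for t in tokens:
        if t.kind == "match_run":
            cursor += t.length
        elif t.kind == "deletion":
            cursor += len(t.deleted_seq)
        else:
            q_off, ref_pos = walk[cursor]
            if q_off is None:
                raise AlignmentError(
                    f"{read.read_id}: MD mismatch token inside a deletion"
                )
            mismatches.append(Mismatch(
                ref_pos=ref_pos,
                ref_base=t.base,
                read_base=read.seq[q_off].upper(),
                base_qual=read.quals[q_off],
            ))
            cursor += 1
    return mismatches


def extract_indels(read: AlignedRead) -> tuple[list[InsertionEvent], list[DeletionEvent]]:
    """One InsertionEvent per I op, one DeletionEvent per D op.

    Deleted sequences come from the MD tag's ^-runs; when the record has no
    MD tag they are ``N`` placeholders of the right length.
    """
    del_seqs: list[str] | None = None
    if read.md is not None:
        del_seqs = [t.deleted_seq for t in parse_md(read.md) if t.kind == "deletion"]
    insertions: list[InsertionEvent] = []
    deletions: list[DeletionEvent] = []
    q, r = 0, read.pos
    d_i = 0
    for op in read.cigar:
        if op.op in _ALIGNED:
            q += op.length
            r += op.length
        elif op.op == "I":
            insertions.append(InsertionEvent(ref_pos=r, inserted_seq=read.seq[q:q + op.length]))
            q += op.length
        elif op.op == "D":
            if del_seqs is not None:
                if d_i >= len(del_seqs) or len(del_seqs[d_i]) != op.length:
                    raise AlignmentError(
                        f"{read.read_id}: CIGAR D op of length {op.length} has no "
                        "matching ^-run in MD tag"
                    )
                seq = del_seqs[d_i]
                d_i += 1
            else:
                seq = "N" * op.length
            deletions.append(DeletionEvent(ref_start=r, deleted_seq=seq))
            r += op.length
        elif op.op == "N":
            r += op.length
        elif op.op == "S":
            q += op.length
    if del_seqs is not None and d_i != len(del_seqs):
        raise AlignmentError(f"{read.read_id}: MD has more deletions than CIGAR")
    return insertions, deletions


# ---------------------------------------------------------------------------
# Transcript strand and duplicate signature
# ---------------------------------------------------------------------------


def transcript_strand(read: AlignedRead, protocol: str) -> str:
    """Transcript strand of the fragment a read came from.

    unstranded: the alignment strand.  fr_secondstrand: read1 (or a
    single-end read) carries the transcript orientation, read2 the opposite.
    fr_firststrand (dUTP): the reverse of fr_secondstrand.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"protocol must be one of {PROTOCOLS}, got {protocol!r}")
    aln = read.strand
    if protocol == "unstranded":
        return aln
    first = read.is_first_in_pair or not read.is_paired
    same_as_read1 = aln if first else ("-" if aln == "+" else "+")
    if protocol == "fr_secondstrand":
        return same_as_read1
    return "-" if same_as_read1 == "+" else "+"


def _unit_key(read: AlignedRead) -> tuple:
    return (read.chrom, read.pos, read.cigar_string, read.strand, read.seq.upper())


def duplicate_key(unit: AlignedRead | tuple[AlignedRead, AlignedRead | None]) -> tuple:
    """Signature under which exact duplicates collide.

    Two units are exact duplicates iff chrom, start, CIGAR, alignment strand
    and base sequence all agree — for pairs, on both mates, with mate order
    canonicalized by (chrom, pos) so either read order yields the same key.
    """
    if isinstance(unit, AlignedRead):
        return ("single", _unit_key(unit))
    a, b = unit
    if b is None:
        return ("single", _unit_key(a))
    ka, kb = _unit_key(a), _unit_key(b)
    return ("pair",) + (tuple(sorted((ka, kb))),)
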
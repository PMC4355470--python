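"""Read glyph construction and row packing for the individual-reads track.

Reads become drawable glyphs: mates are joined into one layout unit (pairs
always share a row), exact duplicates collapse into one glyph whose stroke
thickness grows with multiplicity, and glyphs are packed first-fit into rows
counted outward from the central line — positive-strand transcripts above,
negative-strand below.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .alignment_core import (
    AlignedRead,
    Mismatch,
    duplicate_key,
    extract_mismatches,
    reference_blocks,
    transcript_strand,
)
from .formats_io import GenomicInterval

THICKNESS_CAP = 5


@dataclass(frozen=True)
class ReadGlyph:
    """One read's drawable parts: segments, splice connectors, arrow, marks."""

    strand: str  # transcript strand: "+" above, "-" below the central line
    segments: tuple[GenomicInterval, ...]
    splice_connectors: tuple[tuple[int, int], ...]
    arrow: str  # "right" (forward alignment, red) or "left" (reverse, blue)
    mismatch_marks: tuple[Mismatch, ...] = ()
    read_id: str = ""

    @property
    def start(self) -> int:
        return self.segments[0].start

    @property
    def end(self) -> int:
        return self.segments[-1].end


@dataclass(frozen=True)
class PairGlyph:
    """A layout unit: a read pair (or singleton) with duplicate multiplicity."""

    left_read: ReadGlyph
    right_read: ReadGlyph | None
    span: GenomicInterval
    multiplicity: int = 1
    proper: bool = False
    mate_label: str | None = None  # mate location note for off-window mates
    dup_key: tuple = ()

    @property
    def strand(self) -> str:
        return self.left_read.strand

    @property
    def pair_connector(self) -> tuple[int, int] | None:
        """Gap between the mates' inner ends (drawn solid green), if any."""
        if self.right_read is None:
            return None
        gap = (self.left_read.end, self.right_read.start)
        return gap if gap[0] < gap[1] else None

    @property
    def read_ids(self) -> tuple[str, ...]:
        ids = [self.left_read.read_id]
        if self.right_read is not None and self.right_read.read_id != ids[0]:
            ids.append(self.right_read.read_id)
        return tuple(ids)

    @property
    def thickness(self) -> int:
        """Stroke width in display units: 1 + floor(log2(multiplicity)), capped."""
        return min(THICKNESS_CAP, 1 + self.multiplicity.bit_length() - 1)


@dataclass
class LayoutResult:
    """Row assignment per glyph, counted outward from the central line."""

    rows: list[int]  # parallel to the glyph sequence passed in
    n_rows_pos: int
    n_rows_neg: int

    def row_of(self, index: int) -> int:
        return self.rows[index]


# ---------------------------------------------------------------------------
# Glyph construction
# ---------------------------------------------------------------------------


def _read_glyph(read: AlignedRead, protocol: str, with_mismatches: bool) -> ReadGlyph:
    blocks, _ = reference_blocks(read)
    if not blocks:
        raise ValueError(f"{read.read_id}: unaligned (no reference blocks)")
    connectors = tuple(
        (blocks[i].end, blocks[i + 1].start) for i in range(len(blocks) - 1)
    )
    marks: tuple[Mismatch, ...] = ()
    if with_mismatches and read.md is not None and read.seq:
        marks = tuple(extract_mismatches(read))
    return ReadGlyph(
        strand=transcript_strand(read, protocol),
        segments=tuple(blocks),
        splice_connectors=connectors,
        arrow="left" if read.is_reverse else "right",
        mismatch_marks=marks,
        read_id=read.read_id,
    )


def build_glyphs(reads: Sequence[AlignedRead], protocol: str,
                 with_mismatches: bool = True) -> list[PairGlyph]:
    """Join mates into PairGlyphs; unmated reads become singletons.

    Mates are matched by read_id plus first/second-in-pair complementarity
    within the queried region; a mate falling outside the region leaves a
    singleton annotated with the mate's location.  Every input read ends up
    in exactly one glyph.
    """
    by_id: dict[tuple[str, bool], AlignedRead] = {}
    order: list[AlignedRead] = []
    for read in reads:
        key = (read.read_id, read.is_first_in_pair)
        if key in by_id:
            # secondary/duplicate record of the same mate: keep as its own unit
            order.append(read)
        else:
            by_id[key] = read
            order.append(read)

    used: set[int] = set()
    glyphs: list[PairGlyph] = []
    for read in order:
        if id(read) in used:
            continue
        used.add(id(read))
        mate = None
        if read.is_paired:
            cand = by_id.get((read.read_id, not read.is_first_in_pair))
            if cand is not None and id(cand) not in used and cand.chrom == read.chrom:
                mate = cand
                used.add(id(mate))
        g1 = _read_glyph(read, protocol, with_mismatches)
        if mate is not None:
            g2 = _read_glyph(mate, protocol, with_mismatches)
            left, right = (g1, g2) if g1.start <= g2.start else (g2, g1)
            lread, rread = ((read, mate) if left is g1 else (mate, read))
            span = GenomicInterval(read.chrom, left.start, max(left.end, right.end))
            proper = lread.strand == "+" and rread.strand == "-"
            glyphs.append(PairGlyph(
                left_read=left, right_read=right, span=span, proper=proper,
                dup_key=duplicate_key((read, mate)),
            ))
        else:
            label = None
            if read.is_paired and read.mate_chrom is not None:
                label = f"mate: {read.mate_chrom}:{(read.mate_pos or 0) + 1}"
            span = GenomicInterval(read.chrom, g1.start, g1.end)
            glyphs.append(PairGlyph(
                left_read=g1, right_read=None, span=span, proper=False,
                mate_label=label, dup_key=duplicate_key(read),
            ))
    return glyphs


# ---------------------------------------------------------------------------
# Duplicate aggregation
# ---------------------------------------------------------------------------


def aggregate_duplicates(glyphs: Iterable[PairGlyph]) -> list[PairGlyph]:
    """Merge glyphs with equal duplicate signatures, summing multiplicity.

    The signature covers coordinates, CIGAR, alignment strand and base
    sequence of every member read, so reads differing by a single base never
    merge.  The sum of output multiplicities equals the input glyph count
    (times their own multiplicities, for pre-aggregated input).
    """
    merged: dict[tuple, PairGlyph] = {}
    order: list[tuple] = []
    for g in glyphs:
        if g.dup_key in merged:
            prev = merged[g.dup_key]
            merged[g.dup_key] = replace(prev, multiplicity=prev.multiplicity + g.multiplicity)
        else:
            merged[g.dup_key] = g
            order.append(g.dup_key)
    return [merged[k] for k in order]


# ---------------------------------------------------------------------------
# Row packing
# ---------------------------------------------------------------------------


def assign_rows(glyphs: Sequence[PairGlyph], min_gap: int = 1) -> LayoutResult:
    """First-fit row packing per strand.

    Per strand, glyphs are taken in (span.start, span.end, read_id) order and
    placed into the lowest-index row whose previous occupant ends at least
    ``min_gap`` bases before the new span starts.  Deterministic, and no two
    same-row glyphs ever overlap; pairs are single units so mates always
    share a row.
    """
    rows = [0] * len(glyphs)
    n_rows = {"+": 0, "-": 0}
    for strand in ("+", "-"):
        indexed = [(i, g) for i, g in enumerate(glyphs) if g.strand == strand]
        indexed.sort(key=lambda ig: (ig[1].span.start, ig[1].span.end,
                                     ig[1].read_ids[0]))
        row_ends: list[int] = []  # last occupied end per row
        for i, g in indexed:
            placed = False
            for r, last_end in enumerate(row_ends):
                if last_end + min_gap <= g.span.start:
                    rows[i] = r
                    row_ends[r] = g.span.end
                    placed = True
                    break
            if not placed:
                rows[i] = len(row_ends)
                row_ends.append(g.span.end)
        n_rows[strand] = len(row_ends)
    return LayoutResult(rows=rows, n_rows_pos=n_rows["+"], n_rows_neg=n_rows["-"])


def glyph_metadata(glyphs: Sequence[PairGlyph]) -> list[dict]:
    """Tooltip-equivalent metadata (read IDs, multiplicity, mate location)."""
    out = []
    for g in glyphs:
        out.append({
            "read_ids": list(g.read_ids),
            "multiplicity": g.multiplicity,
            "strand": g.strand,
            "span": [g.span.chrom, g.span.start, g.span.end],
            "proper": g.proper,
            "mate": g.mate_label,
        })
    return out
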
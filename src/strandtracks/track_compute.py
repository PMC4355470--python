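"""Track computation: coverage, pileups, SNP and InDel calls.

Coverage is strand-signed: bases from positive-strand transcripts accumulate
in one array, negative-strand in another, and the signed wiggle encoding
carries the strand in the sign of the value.  SNP calling follows the
five-criteria scheme (minimum depth, minimum variant reads, minimum variant
allele frequency, minimum base quality, maximum p-value) with a one-sided
Fisher exact test of the observed ref/variant split against the split
expected from the null sequencing-error rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

from .alignment_core import (
    AlignedRead,
    DeletionEvent,
    InsertionEvent,
    aligned_pairs,
    extract_indels,
    transcript_strand,
)
from .formats_io import DEFAULT_SNP_PARAM_VALUES, GenomicInterval, WigInterval

logger = logging.getLogger("strandtracks")

ALLELES = "ACGT"  # fixed order; also the alt-allele tie-break order

# Display colors for called alleles.
SNP_ALLELE_COLORS = {"A": "green", "T": "red", "C": "black", "G": "orange"}


@dataclass
class StrandCoverage:
    """Per-base coverage split by transcript strand over one region."""

    region: GenomicInterval
    pos_counts: np.ndarray
    neg_counts: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.region)
        if len(self.pos_counts) != n or len(self.neg_counts) != n:
            raise ValueError("coverage array length must equal region length")


@dataclass(frozen=True)
class SnpParams:
    """The five calling criteria plus the null error rate of the exact test."""

    min_depth: int = DEFAULT_SNP_PARAM_VALUES["min_depth"]
    min_var_reads: int = DEFAULT_SNP_PARAM_VALUES["min_var_reads"]
    min_vaf: float = DEFAULT_SNP_PARAM_VALUES["min_vaf"]
    min_base_qual: int = DEFAULT_SNP_PARAM_VALUES["min_base_qual"]
    max_p: float = DEFAULT_SNP_PARAM_VALUES["max_p"]
    error_rate: float = DEFAULT_SNP_PARAM_VALUES["error_rate"]

    def __post_init__(self) -> None:
        if min(self.min_depth, self.min_var_reads, self.min_base_qual) < 0:
            raise ValueError("thresholds must be >= 0")
        if not (0.0 <= self.min_vaf <= 1.0):
            raise ValueError("min_vaf must be in [0,1]")
        if not (0.0 < self.max_p <= 1.0):
            raise ValueError("max_p must be in (0,1]")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0,1)")


@dataclass
class PileupColumn:
    chrom: str
    ref_pos: int
    ref_base: str
    counts: dict[str, int]
    strand_counts: dict[str, tuple[int, int]]  # allele -> (fwd, rev)

    @property
    def filtered_depth(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class SnpCall:
    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    depth: int
    var_count: int
    vaf: float
    p_value: float

    @property
    def display_color(self) -> str:
        return SNP_ALLELE_COLORS[self.alt_base]


@dataclass(frozen=True)
class IndelTrackEntry:
    event: InsertionEvent | DeletionEvent
    support: int

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("support must be >= 1")

    @property
    def is_insertion(self) -> bool:
        return isinstance(self.event, InsertionEvent)

    @property
    def display_color(self) -> str:
        return "red" if self.is_insertion else "blue"

    @property
    def position(self) -> int:
        return self.event.ref_pos if self.is_insertion else self.event.ref_start


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------


def compute_strand_coverage(reads: Iterable[AlignedRead], region: GenomicInterval,
                            protocol: str) -> StrandCoverage:
    """Strand-split per-base coverage of M/=/X-aligned bases.

    N (splice) gaps and D (deletion) bases contribute nothing, so the sum of
    both arrays equals the number of in-region aligned bases exactly.
    """
    n = len(region)
    pos_counts = np.zeros(n, dtype=np.int64)
    neg_counts = np.zeros(n, dtype=np.int64)
    for read in reads:
        if read.chrom != region.chrom:
            continue
        target = pos_counts if transcript_strand(read, protocol) == "+" else neg_counts
        r = read.pos
        for op in read.cigar:
            if op.op in ("M", "=", "X"):
                lo = max(r, region.start) - region.start
                hi = min(r + op.length, region.end) - region.start
                if lo < hi:
                    target[lo:hi] += 1
                r += op.length
            elif op.op in ("D", "N"):
                r += op.length
    return StrandCoverage(region, pos_counts, neg_counts)


def _rle_runs(values: np.ndarray):
    """(start, end, value) runs over a 1-D array."""
    if len(values) == 0:
        return
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(values)]))
    for s, e in zip(starts, ends):
        yield int(s), int(e), values[s]


def coverage_to_wig(cov: StrandCoverage) -> list[WigInterval]:
    """Run-length encode coverage into signed wiggle intervals.

    Positive-strand runs get value +count, negative-strand runs −count; zero
    runs are omitted.  Decoding the output reproduces the arrays exactly.
    """
    out: list[WigInterval] = []
    base = cov.region.start
    for arr, sign in ((cov.pos_counts, 1), (cov.neg_counts, -1)):
        for s, e, v in _rle_runs(arr):
            if v != 0:
                out.append(WigInterval(cov.region.chrom, base + s, base + e,
                                       float(sign * v)))
    out.sort(key=lambda w: (w.start, w.end, -w.value))
    return out


def wig_to_arrays(intervals: Iterable[WigInterval],
                  region: GenomicInterval) -> tuple[np.ndarray, np.ndarray]:
    """Decode signed wiggle intervals into (positive, negative) per-base arrays."""
    n = len(region)
    pos = np.zeros(n, dtype=float)
    neg = np.zeros(n, dtype=float)
    for w in intervals:
        if w.chrom != region.chrom:
            continue
        lo = max(w.start, region.start) - region.start
        hi = min(w.end, region.end) - region.start
        if lo >= hi:
            continue
        if w.value >= 0:
            pos[lo:hi] += w.value
        else:
            neg[lo:hi] += -w.value
    return pos, neg


def overlay_scale(tracks: Sequence[Sequence[WigInterval]],
                  window: GenomicInterval) -> tuple[float, float]:
    """Shared y-maxima (positive half, negative magnitude) over all tracks.

    Every overlaid wiggle is rendered against these shared maxima, so equal
    signal heights mean equal values across tracks.  All-empty input yields
    (1, 1) to keep the axes non-degenerate.
    """
    pos_max = 0.0
    neg_max = 0.0
    for track in tracks:
        for w in track:
            if w.chrom != window.chrom or w.end <= window.start or w.start >= window.end:
                continue
            if w.value >= 0:
                pos_max = max(pos_max, w.value)
            else:
                neg_max = max(neg_max, -w.value)
    if pos_max == 0.0 and neg_max == 0.0:
        return 1.0, 1.0
    return pos_max or 1.0, neg_max or 1.0


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------


def build_pileup(reads: Iterable[AlignedRead], region: GenomicInterval,
                 reference_bases: str, min_base_qual: int) -> list[PileupColumn]:
    """Quality-filtered allele counts per reference base of ``region``.

    Only M/=/X-aligned bases with quality >= ``min_base_qual`` are counted;
    deleted and splice-skipped positions contribute nothing, so no column's
    depth can exceed the number of overlapping reads.
    """
    n = len(region)
    if len(reference_bases) != n:
        raise ValueError(
            f"reference length {len(reference_bases)} != region length {n}"
        )
    counts = np.zeros((n, 4), dtype=np.int64)
    strand = np.zeros((n, 4, 2), dtype=np.int64)
    for read in reads:
        if read.chrom != region.chrom or not read.seq:
            continue
        s = 1 if read.is_reverse else 0
        for q_off, ref_pos in aligned_pairs(read):
            if not (region.start <= ref_pos < region.end):
                continue
            if read.quals[q_off] < min_base_qual:
                continue
            a = ALLELES.find(read.seq[q_off].upper())
            if a < 0:
                continue
            i = ref_pos - region.start
            counts[i, a] += 1
            strand[i, a, s] += 1
    columns: list[PileupColumn] = []
    for i in range(n):
        columns.append(PileupColumn(
            chrom=region.chrom,
            ref_pos=region.start + i,
            ref_base=reference_bases[i].upper(),
            counts={al: int(counts[i, j]) for j, al in enumerate(ALLELES)},
            strand_counts={al: (int(strand[i, j, 0]), int(strand[i, j, 1]))
                           for j, al in enumerate(ALLELES)},
        ))
    return columns


# ---------------------------------------------------------------------------
# Fisher exact test (one-sided) and SNP calling
# ---------------------------------------------------------------------------


def fisher_exact_one_sided(n_ref, n_var, e_ref, e_var):
    """One-sided Fisher exact p for variant excess in the observed row.

    For the 2x2 table [[n_ref, n_var], [e_ref, e_var]] with all margins
    fixed, returns P(X >= n_var) where X is the hypergeometric count of
    variant reads in the observed row.  Accepts scalars or arrays
    (broadcast); an all-zero table yields p = 1 by convention.
    """
    n_ref = np.asarray(n_ref, dtype=np.int64)
    n_var = np.asarray(n_var, dtype=np.int64)
    e_ref = np.asarray(e_ref, dtype=np.int64)
    e_var = np.asarray(e_var, dtype=np.int64)
    if np.any(n_ref < 0) or np.any(n_var < 0) or np.any(e_ref < 0) or np.any(e_var < 0):
        raise ValueError("table counts must be >= 0")
    total = n_ref + n_var + e_ref + e_var
    row1 = n_ref + n_var
    var_col = n_var + e_var
    # sf(k-1) = P(X >= k); hypergeom handles the degenerate margins, but an
    # empty table has no law — pin it to 1.
    p = hypergeom.sf(n_var - 1, total, var_col, row1)
    p = np.where(total == 0, 1.0, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    if p.ndim == 0:
        return float(p)
    return p


def call_snps(columns: Sequence[PileupColumn], params: SnpParams) -> list[SnpCall]:
    """Apply the five criteria to pileup columns.

    The candidate alternate allele is the most frequent non-reference allele
    (ties broken in A<C<G<T order); a call is emitted iff depth, variant
    reads, VAF and the one-sided exact p against the expected error split all
    pass.  Columns with an N (or otherwise uncalled) reference base are never
    called.
    """
    candidates: list[tuple[PileupColumn, str, int, int]] = []
    for col in columns:
        if col.ref_base not in ALLELES:
            continue
        depth = col.filtered_depth
        if depth == 0:
            continue
        best_alt, best_count = "", -1
        tied = False
        for al in ALLELES:  # fixed order => deterministic tie-break
            if al == col.ref_base:
                continue
            c = col.counts[al]
            if c > best_count:
                best_alt, best_count = al, c
                tied = False
            elif c == best_count and c > 0:
                tied = True
        if best_count <= 0:
            continue
        if tied:
            logger.debug("pileup %s:%d: alt allele tie broken toward %s",
                         col.chrom, col.ref_pos, best_alt)
        candidates.append((col, best_alt, best_count, depth))
    if not candidates:
        return []

    depths = np.array([c[3] for c in candidates], dtype=np.int64)
    var_counts = np.array([c[2] for c in candidates], dtype=np.int64)
    e_var = np.rint(depths * params.error_rate).astype(np.int64)
    e_ref = np.rint(depths * (1.0 - params.error_rate)).astype(np.int64)
    p_values = np.atleast_1d(
        fisher_exact_one_sided(depths - var_counts, var_counts, e_ref, e_var)
    )

    calls: list[SnpCall] = []
    for (col, alt, var_count, depth), p in zip(candidates, p_values):
        vaf = var_count / depth
        if (depth >= params.min_depth
                and var_count >= params.min_var_reads
                and vaf >= params.min_vaf
                and p <= params.max_p):
            calls.append(SnpCall(col.chrom, col.ref_pos, col.ref_base, alt,
                                 depth, var_count, vaf, float(p)))
    return calls


# ---------------------------------------------------------------------------
# InDel track
# ---------------------------------------------------------------------------


def collect_indels(reads: Iterable[AlignedRead],
                   region: GenomicInterval | None = None) -> list[IndelTrackEntry]:
    """Merge identical insertion/deletion events across reads with support counts.

    Events are identical iff type, position and sequence all match; an
    insertion and a deletion at the same position stay distinct.  Entries are
    sorted by position (insertions before deletions at ties).
    """
    support: dict[tuple, int] = {}
    events: dict[tuple, InsertionEvent | DeletionEvent] = {}
    for read in reads:
        ins, dels = extract_indels(read)
        for ev in ins:
            if region is not None and not (region.start <= ev.ref_pos < region.end):
                continue
            key = ("I", ev.ref_pos, ev.inserted_seq)
            support[key] = support.get(key, 0) + 1
            events[key] = ev
        for ev in dels:
            if region is not None and not (region.start <= ev.ref_start < region.end):
                continue
            key = ("D", ev.ref_start, ev.deleted_seq)
            support[key] = support.get(key, 0) + 1
            events[key] = ev
    entries = [IndelTrackEntry(events[k], support[k]) for k in support]
    entries.sort(key=lambda e: (e.position, e.is_insertion is False,
                                e.event.inserted_seq if e.is_insertion
                                else e.event.deleted_seq))
    return entries


# ---------------------------------------------------------------------------
# TSV sidecars (1-based display coordinates)
# ---------------------------------------------------------------------------


def snp_table(calls: Sequence[SnpCall]) -> str:
    lines = ["chrom\tpos\tref\talt\tdepth\tvar_count\tvaf\tp_value"]
    for c in calls:
        lines.append(f"{c.chrom}\t{c.pos + 1}\t{c.ref_base}\t{c.alt_base}\t"
                     f"{c.depth}\t{c.var_count}\t{c.vaf:.4f}\t{c.p_value:.3e}")
    return "\n".join(lines) + "\n"


def indel_table(entries: Sequence[IndelTrackEntry]) -> str:
    lines = ["pos\ttype\tsequence\tsupport"]
    for e in entries:
        kind = "insertion" if e.is_insertion else "deletion"
        seq = e.event.inserted_seq if e.is_insertion else e.event.deleted_seq
        lines.append(f"{e.position + 1}\t{kind}\t{seq}\t{e.support}")
    return "\n".join(lines) + "\n"
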
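"""Coverage, wiggle encoding, pileups, the exact test and SNP/InDel calling."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strandtracks.alignment_core import parse_cigar
from strandtracks.formats_io import GenomicInterval, WigInterval
from strandtracks.track_compute import (
    PileupColumn,
    SnpParams,
    StrandCoverage,
    build_pileup,
    call_snps,
    collect_indels,
    compute_strand_coverage,
    coverage_to_wig,
    fisher_exact_one_sided,
    overlay_scale,
    wig_to_arrays,
)
from .test_alignment_core import make_read


def fisher_oracle(n_ref, n_var, e_ref, e_var) -> float:
    """Exhaustive enumeration over all 2x2 tables with the given margins."""
    r1, r2 = n_ref + n_var, e_ref + e_var
    c1 = n_var + e_var
    denom = comb(r1 + r2, c1)
    if denom == 0:
        return 1.0
    total = Fraction(0)
    for a in range(max(0, c1 - r2), min(r1, c1) + 1):
        if a >= n_var:
            total += Fraction(comb(r1, a) * comb(r2, c1 - a))
    return float(total / denom)


class TestStrandCoverage:
    REGION = GenomicInterval("chr1", 90, 130)

    def test_single_plus_read(self):
        read = make_read("10M", "A" * 10, is_paired=False)
        cov = compute_strand_coverage([read], self.REGION, "unstranded")
        assert cov.pos_counts.sum() == 10
        assert (cov.pos_counts[10:20] == 1).all()
        assert cov.neg_counts.sum() == 0

    def test_reverse_read_mirrors_to_negative(self):
        read = make_read("10M", "A" * 10, is_reverse=True)
        cov = compute_strand_coverage([read], self.REGION, "unstranded")
        assert cov.pos_counts.sum() == 0 and cov.neg_counts.sum() == 10

    def test_deletion_and_splice_not_counted(self):
        read = make_read("5M3D2M10N3M", "A" * 10)
        cov = compute_strand_coverage([read], self.REGION, "unstranded")
        assert cov.pos_counts.sum() + cov.neg_counts.sum() == 10

    def test_conservation_against_per_read_counting(self, basic_bundle,
                                                    basic_reads):
        region = GenomicInterval("chrT", 0, 12000)
        cov = compute_strand_coverage(basic_reads, region,
                                      basic_bundle.truth["protocol"])
        expect = sum(op.length for r in basic_reads for op in r.cigar
                     if op.op in ("M", "=", "X"))
        assert int(cov.pos_counts.sum() + cov.neg_counts.sum()) == expect
        t = basic_bundle.truth["conditions"]["reads"]["aligned_bases"]
        assert int(cov.pos_counts.sum()) == t["+"]
        assert int(cov.neg_counts.sum()) == t["-"]


class TestCoverageToWig:
    def test_run_length_encoding(self):
        region = GenomicInterval("c", 0, 4)
        cov = StrandCoverage(region, np.array([0, 2, 2, 1]), np.zeros(4, int))
        assert coverage_to_wig(cov) == [
            WigInterval("c", 1, 3, 2.0), WigInterval("c", 3, 4, 1.0)]

    def test_all_zero_is_empty(self):
        region = GenomicInterval("c", 0, 5)
        cov = StrandCoverage(region, np.zeros(5, int), np.zeros(5, int))
        assert coverage_to_wig(cov) == []

    @given(pos=st.lists(st.integers(0, 5), min_size=1, max_size=40),
           neg=st.lists(st.integers(0, 5), min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_decode_inverts_encode(self, pos, neg):
        n = max(len(pos), len(neg))
        pos += [0] * (n - len(pos))
        neg += [0] * (n - len(neg))
        region = GenomicInterval("c", 7, 7 + n)
        cov = StrandCoverage(region, np.array(pos), np.array(neg))
        got_pos, got_neg = wig_to_arrays(coverage_to_wig(cov), region)
        assert (got_pos == np.array(pos, float)).all()
        assert (got_neg == np.array(neg, float)).all()


class TestOverlayScale:
    WINDOW = GenomicInterval("c", 0, 1000)

    def test_shared_positive_max(self):
        t1 = [WigInterval("c", 0, 10, 10.0)]
        t2 = [WigInterval("c", 5, 15, 25.0)]
        assert overlay_scale([t1, t2], self.WINDOW)[0] == 25.0

    def test_shared_negative_extent(self):
        t1 = [WigInterval("c", 0, 10, -7.0)]
        t2 = [WigInterval("c", 0, 10, -3.0)]
        assert overlay_scale([t1, t2], self.WINDOW)[1] == 7.0

    def test_all_empty_degenerate(self):
        assert overlay_scale([[], []], self.WINDOW) == (1.0, 1.0)

    def test_single_track_own_extent(self):
        t = [WigInterval("c", 0, 10, 4.0), WigInterval("c", 10, 20, -2.0)]
        assert overlay_scale([t], self.WINDOW) == (4.0, 2.0)

    def test_out_of_window_ignored(self):
        t = [WigInterval("c", 2000, 2010, 99.0), WigInterval("c", 0, 5, 3.0)]
        assert overlay_scale([t, t], self.WINDOW) == (3.0, 1.0)


class TestBuildPileup:
    REGION = GenomicInterval("chr1", 100, 110)
    REF = "AAAAAAAAAA"

    def test_matching_reads_counted(self):
        reads = [make_read("10M", "A" * 10, read_id=f"r{i}") for i in range(10)]
        cols = build_pileup(reads, self.REGION, self.REF, 15)
        assert all(c.counts == {"A": 10, "C": 0, "G": 0, "T": 0} for c in cols)
        assert all(c.filtered_depth == 10 for c in cols)

    def test_variant_allele_split(self):
        reads = [make_read("10M", "A" * 10, read_id=f"r{i}") for i in range(6)]
        reads += [make_read("10M", "AAAATAAAAA", read_id=f"v{i}") for i in range(4)]
        col = build_pileup(reads, self.REGION, self.REF, 15)[4]
        assert col.counts["A"] == 6 and col.counts["T"] == 4

    def test_low_quality_base_excluded(self):
        quals = [30] * 10
        quals[4] = 5
        reads = [make_read("10M", "A" * 10, quals=tuple(quals))]
        cols = build_pileup(reads, self.REGION, self.REF, 15)
        assert cols[4].filtered_depth == 0 and cols[5].filtered_depth == 1

    def test_strand_counts_sum_to_allele_counts(self):
        reads = [make_read("10M", "A" * 10),
                 make_read("10M", "A" * 10, is_reverse=True)]
        col = build_pileup(reads, self.REGION, self.REF, 0)[0]
        assert col.strand_counts["A"] == (1, 1)
        assert sum(col.strand_counts["A"]) == col.counts["A"]

    def test_reference_length_mismatch(self):
        with pytest.raises(ValueError):
            build_pileup([], self.REGION, "AAA", 15)

    def test_depth_matches_brute_force_on_fixture(self, basic_bundle,
                                                  basic_reads):
        from strandtracks.formats_io import read_fasta_region
        region = GenomicInterval("chrT", 1250, 1350)
        ref = read_fasta_region(basic_bundle.fasta, region)
        cols = build_pileup(basic_reads, region, ref, 15)
        # oracle: per-read walk over aligned pairs
        from strandtracks.alignment_core import aligned_pairs
        depth = {p: 0 for p in range(region.start, region.end)}
        for r in basic_reads:
            for q, p in aligned_pairs(r):
                if p in depth and r.quals[q] >= 15 and r.seq[q] in "ACGT":
                    depth[p] += 1
        for col in cols:
            assert col.filtered_depth == depth[col.ref_pos]


class TestFisherExact:
    def test_degenerate_single_table(self):
        assert fisher_exact_one_sided(5, 0, 5, 0) == 1.0

    def test_extreme_table_exact_value(self):
        # only C(5,5)*C(5,0)/C(10,5) = 1/252 of the mass is as extreme
        assert fisher_exact_one_sided(0, 5, 5, 0) == pytest.approx(1 / 252,
                                                                   abs=1e-12)

    def test_all_zero_table_convention(self):
        assert fisher_exact_one_sided(0, 0, 0, 0) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_one_sided(-1, 2, 3, 4)

    @given(n_ref=st.integers(0, 60), n_var=st.integers(0, 60),
           e_ref=st.integers(0, 60), e_var=st.integers(0, 60))
    @settings(max_examples=300, deadline=None)
    def test_matches_enumeration_oracle(self, n_ref, n_var, e_ref, e_var):
        got = fisher_exact_one_sided(n_ref, n_var, e_ref, e_var)
        assert got == pytest.approx(fisher_oracle(n_ref, n_var, e_ref, e_var),
                                    abs=1e-12)

    def test_vectorized_equals_scalar(self):
        tables = [(10, 2, 12, 0), (30, 15, 44, 1), (0, 0, 0, 0)]
        vec = fisher_exact_one_sided(*map(np.array, zip(*tables)))
        for row, t in zip(vec, tables):
            assert row == fisher_exact_one_sided(*t)


def _column(ref, counts, pos=500):
    full = {a: 0 for a in "ACGT"}
    full.update(counts)
    return PileupColumn("chr1", pos, ref, full,
                        {a: (full[a], 0) for a in "ACGT"})


class TestCallSnps:
    def test_clear_het_call(self):
        col = _column("A", {"A": 25, "T": 25})
        (call,) = call_snps([col], SnpParams())
        assert call.alt_base == "T" and call.vaf == 0.5
        assert call.depth == 50 and call.var_count == 25
        assert call.p_value <= 0.01
        assert call.display_color == "red"

    @pytest.mark.parametrize("counts,params,reason", [
        ({"A": 3, "T": 2}, SnpParams(), "depth below min_depth"),
        ({"A": 48, "T": 1}, SnpParams(), "single variant read"),
        ({"A": 45, "T": 5}, SnpParams(), "vaf 0.1 below 0.2"),
        ({"A": 25, "T": 25}, SnpParams(max_p=1e-30), "p above max_p"),
    ])
    def test_each_criterion_blocks(self, counts, params, reason):
        assert call_snps([_column("A", counts)], params) == [], reason

    def test_reference_n_never_called(self):
        assert call_snps([_column("N", {"A": 30, "T": 20})], SnpParams()) == []

    def test_alt_tie_broken_in_allele_order(self):
        col = _column("A", {"A": 20, "C": 15, "G": 15})
        (call,) = call_snps([col], SnpParams(max_p=1.0))
        assert call.alt_base == "C"

    def test_planted_het_snp_exactly_one_call(self, basic_bundle, basic_reads):
        from strandtracks.formats_io import read_fasta_region
        region = GenomicInterval("chrT", 0, 12000)
        ref = read_fasta_region(basic_bundle.fasta, region)
        cols = build_pileup(basic_reads, region, ref, 15)
        calls = call_snps(cols, SnpParams())
        truth = basic_bundle.truth["snps"][0]
        assert len(calls) == 1
        assert calls[0].pos == truth["pos"]
        assert calls[0].alt_base == truth["alt"]
        assert calls[0].var_count == truth["var_reads"]

    def test_null_fixture_zero_calls(self, null_bundle):
        from .conftest import load_reads
        from strandtracks.formats_io import read_fasta_region
        region = GenomicInterval("chrT", 0, 12000)
        reads = load_reads(null_bundle.bam)
        ref = read_fasta_region(null_bundle.fasta, region)
        cols = build_pileup(reads, region, ref, 15)
        assert call_snps(cols, SnpParams(max_p=0.99)) == []

    @given(data=st.data())
    @settings(max_examples=40, deadline=None)
    def test_raising_any_threshold_never_adds_calls(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        cols = []
        for i in range(30):
            ref = "ACGT"[rng.integers(0, 4)]
            counts = {a: int(rng.integers(0, 30)) for a in "ACGT"}
            cols.append(_column(ref, counts, pos=i))
        base = SnpParams(min_depth=5, min_var_reads=2, min_vaf=0.1,
                         max_p=0.5)
        n_base = len(call_snps(cols, base))
        for raised in [
            SnpParams(min_depth=15, min_var_reads=2, min_vaf=0.1, max_p=0.5),
            SnpParams(min_depth=5, min_var_reads=8, min_vaf=0.1, max_p=0.5),
            SnpParams(min_depth=5, min_var_reads=2, min_vaf=0.4, max_p=0.5),
            SnpParams(min_depth=5, min_var_reads=2, min_vaf=0.1, max_p=0.01),
            SnpParams(min_depth=5, min_var_reads=2, min_vaf=0.1, max_p=0.5,
                      min_base_qual=40),
        ]:
            assert len(call_snps(cols, raised)) <= n_base


class TestCollectIndels:
    def test_identical_insertions_merge(self):
        reads = [make_read("5M2I5M", "AAAAATTAAAAA", md="10", read_id=f"r{i}")
                 for i in range(3)]
        (entry,) = collect_indels(reads)
        assert entry.is_insertion and entry.support == 3
        assert entry.display_color == "red"

    def test_insertion_and_deletion_at_same_position_distinct(self):
        reads = [make_read("5M2I5M", "AAAAATTAAAAA", md="10"),
                 make_read("5M2D5M", "A" * 10, md="5^GG5")]
        entries = collect_indels(reads)
        assert len(entries) == 2
        assert {e.display_color for e in entries} == {"red", "blue"}

    def test_different_sequences_stay_separate(self):
        reads = [make_read("5M2I5M", "AAAAATTAAAAA", md="10"),
                 make_read("5M2I5M", "AAAAAGGAAAAA", md="10", read_id="r2")]
        assert len(collect_indels(reads)) == 2

    def test_planted_deletion_recovered(self, basic_bundle, basic_reads):
        entries = collect_indels(basic_reads)
        truth_dels = basic_bundle.truth["deletions"]
        (key,) = truth_dels
        pos = int(key.split(":")[1])
        match = [e for e in entries if not e.is_insertion
                 and e.event.ref_start == pos]
        assert len(match) == 1
        assert match[0].event.deleted_seq == truth_dels[key]["seq"]
        assert match[0].support == truth_dels[key]["support"]
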
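"""Deterministic synthetic RNA-seq fixture generator.

Simulates a toy genome, a spliced transcriptome and strand-specific
paired-end reads with planted truth: heterozygous SNPs at a target variant
allele frequency, insertions/deletions carried by a stated fraction of
fragments, splice and fusion junctions, and literal duplicate read pairs.
Reads are built from an explicit haplotype (the transcript's exon chain with
the carried events applied), so CIGAR, MD tag and sequence are mutually
consistent by construction and every planted event's exact coordinates and
realized supporting-read counts land in a machine-readable truth file.

Reads are error-free except planted events unless ``error_rate`` is set, so
truth recovery is exact at the designed depths.  SAM text is the canonical
output; sorting/indexing to BAM is left to the caller.

Named scenarios mirror the three study vignettes: a fusion transcript joining
the third exon of one gene to the fourth exon of another, a novel isoform in
which a third of the reads skip two adjacent exons, and a two-condition
overlay with a known fold change on one strand and an antisense transcript
on the other.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class Transcript:
    name: str
    chrom: str
    strand: str  # transcript strand: "+" or "-"
    exons: tuple[tuple[int, int], ...]  # ascending, disjoint genomic intervals
    depth: float  # target per-base coverage

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class PlantedSnp:
    chrom: str
    pos: int
    vaf: float  # fraction of fragments carrying the alternate allele
    alt: str | None = None  # None: picked deterministically (next base after ref)


@dataclass(frozen=True)
class PlantedIndel:
    chrom: str
    pos: int
    kind: str  # "ins" | "del"
    seq_or_len: str | int  # inserted sequence, or deletion length
    fraction: float  # fraction of fragments carrying the event


@dataclass
class SimSpec:
    """The study conditions of one synthetic bundle."""

    chrom_lengths: dict[str, int]
    transcripts: list[Transcript]
    read_length: int = 50
    fragment_mean: float = 180.0
    fragment_sd: float = 20.0
    planted_snps: list[PlantedSnp] = field(default_factory=list)
    planted_indels: list[PlantedIndel] = field(default_factory=list)
    duplicate_rate: float = 0.0
    error_rate: float = 0.0
    protocol: str = "fr_firststrand"
    base_qual: int = 30
    seed: int = 0


@dataclass
class Bundle:
    """Paths of one generated fixture plus its parsed truth."""

    fasta: str
    bed: str
    sams: dict[str, str]  # condition name -> SAM path
    truth_path: str
    truth: dict

    @property
    def sam(self) -> str:
        """The single SAM path of one-condition bundles."""
        (path,) = self.sams.values()
        return path


class InfeasibleSpec(ValueError):
    """The spec cannot produce valid reads (e.g. read longer than exon chain)."""


# ---------------------------------------------------------------------------
# Genome and haplotypes
# ---------------------------------------------------------------------------


def _make_genome(spec: SimSpec, rng: np.random.Generator) -> dict[str, str]:
    genome = {}
    for chrom in sorted(spec.chrom_lengths):
        n = spec.chrom_lengths[chrom]
        genome[chrom] = "".join(np.array(list(BASES))[rng.integers(0, 4, n)])
    return genome


def _resolve_alt(genome: dict[str, str], snp: PlantedSnp) -> str:
    ref = genome[snp.chrom][snp.pos]
    if snp.alt is not None:
        if snp.alt == ref:
            raise InfeasibleSpec(f"SNP at {snp.chrom}:{snp.pos}: alt equals ref {ref}")
        return snp.alt
    return BASES[(BASES.index(ref) + 1) % 4]


def _exon_positions(t: Transcript) -> list[int]:
    pos: list[int] = []
    for s, e in t.exons:
        pos.extend(range(s, e))
    return pos


def _haplotype(positions: Sequence[int], genome_seq: str,
               snps: Sequence[tuple[int, str]],
               indels: Sequence[PlantedIndel],
               genome: dict[str, str], chrom: str) -> list[tuple[int | None, str]]:
    """Exon-chain elements (genomic_pos_or_None, base) with events applied."""
    alt_at = dict(snps)
    elems: list[tuple[int | None, str]] = [
        (p, alt_at.get(p, genome_seq[p])) for p in positions
    ]
    for indel in indels:
        if indel.kind == "del":
            k = int(indel.seq_or_len)
            lo, hi = indel.pos, indel.pos + k
            elems = [(g, b) for g, b in elems if g is None or not (lo <= g < hi)]
        else:
            seq = str(indel.seq_or_len)
            idx = next((i for i, (g, _) in enumerate(elems) if g == indel.pos), None)
            if idx is None:
                raise InfeasibleSpec(
                    f"insertion point {chrom}:{indel.pos} not inside the exon chain")
            elems = elems[:idx] + [(None, b) for b in seq] + elems[idx:]
    return elems


# ---------------------------------------------------------------------------
# Read construction
# ---------------------------------------------------------------------------


def _cigar_and_pos(elems: Sequence[tuple[int | None, str]],
                   deletions: set[tuple[int, int]]) -> tuple[int, list[tuple[str, int]]]:
    """CIGAR ops for one read's haplotype slice; gaps matching a carried
    deletion interval become D, all other gaps N.  Leading/trailing inserted
    bases become soft clips."""
    ops: list[tuple[str, int]] = []

    def push(op: str, n: int) -> None:
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    prev: int | None = None
    start: int | None = None
    for g, _ in elems:
        if g is None:
            push("I", 1)
            continue
        if start is None:
            start = g
        elif prev is not None and g != prev + 1:
            gap = (prev + 1, g)
            push("D" if gap in deletions else "N", gap[1] - gap[0])
        push("M", 1)
        prev = g
    if start is None:
        raise InfeasibleSpec("read consists only of inserted bases")
    if ops and ops[0][0] == "I":
        ops[0] = ("S", ops[0][1])
    if ops and ops[-1][0] == "I":
        ops[-1] = ("S", ops[-1][1])
    return start, ops


def _md_and_nm(pos: int, ops: Sequence[tuple[str, int]], seq: str,
               chrom_seq: str) -> tuple[str, int]:
    md: list[str] = []
    match = 0
    nm = 0
    q, r = 0, pos
    for op, ln in ops:
        if op == "M":
            for _ in range(ln):
                if seq[q] == chrom_seq[r]:
                    match += 1
                else:
                    md.append(str(match))
                    md.append(chrom_seq[r])
                    match = 0
                    nm += 1
                q += 1
                r += 1
        elif op in ("I", "S"):
            q += ln
            if op == "I":
                nm += ln
        elif op == "D":
            md.append(str(match))
            md.append("^" + chrom_seq[r:r + ln])
            match = 0
            nm += ln
            r += ln
        elif op == "N":
            r += ln
    md.append(str(match))
    return "".join(md), nm


def _cigar_str(ops: Sequence[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in ops)


@dataclass
class _SamRecord:
    qname: str
    flag: int
    chrom: str
    pos: int  # 0-based
    cigar: str
    pnext: int
    tlen: int
    seq: str
    qual: str
    md: str
    nm: int

    def line(self) -> str:
        return "\t".join([
            self.qname, str(self.flag), self.chrom, str(self.pos + 1), "60",
            self.cigar, "=", str(self.pnext + 1), str(self.tlen), self.seq,
            self.qual, f"NM:i:{self.nm}", f"MD:Z:{self.md}",
        ])


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate(spec: SimSpec, outdir: str,
             conditions: dict[str, list[Transcript]] | None = None) -> Bundle:
    """Generate a bundle {genome.fa, genes.bed, reads.sam, truth.json}.

    ``conditions`` maps condition names to transcript lists for multi-sample
    bundles (one SAM per condition, shared genome/annotation); by default a
    single ``reads`` condition holds ``spec.transcripts``.  Same spec and
    seed yield byte-identical outputs.
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    genome = _make_genome(spec, rng)

    if conditions is None:
        conditions = {"reads": spec.transcripts}
    all_transcripts = [t for ts in conditions.values() for t in ts]
    for t in all_transcripts:
        if t.spliced_length < spec.read_length:
            raise InfeasibleSpec(
                f"{t.name}: read length {spec.read_length} exceeds exon chain "
                f"length {t.spliced_length}")
        for s, e in t.exons:
            if not (0 <= s < e <= spec.chrom_lengths[t.chrom]):
                raise InfeasibleSpec(f"{t.name}: exon ({s},{e}) outside {t.chrom}")

    snp_alts = [(s, _resolve_alt(genome, s)) for s in spec.planted_snps]

    truth: dict = {
        "protocol": spec.protocol,
        "read_length": spec.read_length,
        "conditions": {},
        "snps": [{"chrom": s.chrom, "pos": s.pos,
                  "ref": genome[s.chrom][s.pos], "alt": alt,
                  "target_vaf": s.vaf, "var_reads": 0, "ref_reads": 0, "depth": 0}
                 for s, alt in snp_alts],
        "insertions": {}, "deletions": {},
        "mismatches": [], "insertion_events": [], "deletion_events": [],
        "junctions": {},
    }
    for ind in spec.planted_indels:
        key = f"{ind.chrom}:{ind.pos}"
        if ind.kind == "ins":
            truth["insertions"][key] = {"seq": str(ind.seq_or_len), "support": 0}
        else:
            k = int(ind.seq_or_len)
            truth["deletions"][key] = {
                "seq": genome[ind.chrom][ind.pos:ind.pos + k], "support": 0}

    qual_char = chr(33 + spec.base_qual)
    sam_paths: dict[str, str] = {}

    for cond_name in conditions:
        transcripts = conditions[cond_name]
        records: list[_SamRecord] = []
        cond_stats = {"fragments": 0, "duplicate_pairs": 0, "reads": 0,
                      "aligned_bases": {"+": 0, "-": 0},
                      "aligned_bases_by_transcript": {}}
        for t in transcripts:
            n_frag = max(1, round(t.depth * t.spliced_length
                                  / (2 * spec.read_length)))
            records_t = _simulate_transcript(
                t, n_frag, spec, snp_alts, genome, rng, truth, cond_stats,
                qual_char)
            records.extend(records_t)
        records.sort(key=lambda r: (r.chrom, r.pos, r.qname, r.flag))
        sam_path = os.path.join(outdir, f"{cond_name}.sam")
        with open(sam_path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:coordinate\n")
            for chrom in sorted(spec.chrom_lengths):
                fh.write(f"@SQ\tSN:{chrom}\tLN:{spec.chrom_lengths[chrom]}\n")
            for rec in records:
                fh.write(rec.line() + "\n")
        sam_paths[cond_name] = sam_path
        cond_stats["reads"] = len(records)
        truth["conditions"][cond_name] = cond_stats

    for entry in truth["snps"]:
        entry["realized_vaf"] = (entry["var_reads"] / entry["depth"]
                                 if entry["depth"] else 0.0)

    fasta = os.path.join(outdir, "genome.fa")
    with open(fasta, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")

    bed = os.path.join(outdir, "genes.bed")
    seen = set()
    with open(bed, "w") as fh:
        for t in all_transcripts:
            if t.name in seen:
                continue
            seen.add(t.name)
            start, end = t.exons[0][0], t.exons[-1][1]
            sizes = ",".join(str(e - s) for s, e in t.exons) + ","
            starts = ",".join(str(s - start) for s, _ in t.exons) + ","
            fh.write("\t".join([
                t.chrom, str(start), str(end), t.name, "0", t.strand,
                str(start), str(end), "0", str(len(t.exons)), sizes, starts,
            ]) + "\n")

    truth_path = os.path.join(outdir, "truth.json")
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return Bundle(fasta=fasta, bed=bed, sams=sam_paths, truth_path=truth_path,
                  truth=truth)


def _simulate_transcript(t: Transcript, n_frag: int, spec: SimSpec,
                         snp_alts, genome, rng, truth, cond_stats,
                         qual_char: str) -> list[_SamRecord]:
    chrom_seq = genome[t.chrom]
    positions = _exon_positions(t)
    pos_set = set(positions)
    snps_on_t = [(s.pos, alt, s.vaf) for s, alt in snp_alts
                 if s.chrom == t.chrom and s.pos in pos_set]
    indels_on_t = [i for i in spec.planted_indels
                   if i.chrom == t.chrom and i.pos in pos_set]
    hap_cache: dict[tuple, list] = {}
    records: list[_SamRecord] = []
    rl = spec.read_length

    for i in range(n_frag):
        snp_carried = tuple(rng.random() < vaf for _, _, vaf in snps_on_t)
        ind_carried = tuple(rng.random() < ind.fraction for ind in indels_on_t)
        key = (snp_carried, ind_carried)
        if key not in hap_cache:
            hap_cache[key] = _haplotype(
                positions, chrom_seq,
                [(p, a) for (p, a, _), c in zip(snps_on_t, snp_carried) if c],
                [ind for ind, c in zip(indels_on_t, ind_carried) if c],
                genome, t.chrom)
        elems = hap_cache[key]
        hap_len = len(elems)
        if hap_len < rl:
            continue
        frag_len = int(np.clip(round(rng.normal(spec.fragment_mean,
                                                spec.fragment_sd)), rl, hap_len))
        start = int(rng.integers(0, hap_len - frag_len + 1))
        carried_dels = {
            (ind.pos, ind.pos + int(ind.seq_or_len))
            for ind, c in zip(indels_on_t, ind_carried) if c and ind.kind == "del"
        }
        qname = f"{t.name}_f{i}"
        pair = _make_pair(t, elems, start, frag_len, rl, carried_dels, spec,
                          rng, qname, qual_char, chrom_seq)
        cond_stats["fragments"] += 1
        emitted = [pair]
        if rng.random() < spec.duplicate_rate:
            dup = [_SamRecord(**{**r.__dict__, "qname": qname + "d"}) for r in pair]
            emitted.append(dup)
            cond_stats["duplicate_pairs"] += 1
        for recs in emitted:
            for rec in recs:
                _record_truth(rec, t, chrom_seq, truth, cond_stats)
            records.extend(recs)
    return records


def _make_pair(t: Transcript, elems, start: int, frag_len: int, rl: int,
               carried_dels, spec: SimSpec, rng, qname: str, qual_char: str,
               chrom_seq: str) -> list[_SamRecord]:
    left_elems = elems[start:start + rl]
    right_elems = elems[start + frag_len - rl:start + frag_len]
    left_pos, left_ops = _cigar_and_pos(left_elems, carried_dels)
    right_pos, right_ops = _cigar_and_pos(right_elems, carried_dels)
    left_seq = "".join(b for _, b in left_elems)
    right_seq = "".join(b for _, b in right_elems)
    if spec.error_rate > 0:
        left_seq = _apply_errors(left_seq, spec.error_rate, rng)
        right_seq = _apply_errors(right_seq, spec.error_rate, rng)
    left_md, left_nm = _md_and_nm(left_pos, left_ops, left_seq, chrom_seq)
    right_md, right_nm = _md_and_nm(right_pos, right_ops, right_seq, chrom_seq)
    right_end = right_pos + sum(n for op, n in right_ops if op in "MDN")
    tlen = right_end - left_pos

    # Which genomic-left mate is read1 is what encodes the transcript strand
    # under the library protocol.
    if spec.protocol == "unstranded":
        left_is_read1 = True
    elif spec.protocol == "fr_secondstrand":
        left_is_read1 = t.strand == "+"
    else:  # fr_firststrand (dUTP)
        left_is_read1 = t.strand == "-"
    left_flag = 0x1 | 0x2 | 0x20 | (0x40 if left_is_read1 else 0x80)
    right_flag = 0x1 | 0x2 | 0x10 | (0x80 if left_is_read1 else 0x40)
    qual = qual_char * rl
    return [
        _SamRecord(qname, left_flag, t.chrom, left_pos, _cigar_str(left_ops),
                   right_pos, tlen, left_seq, qual, left_md, left_nm),
        _SamRecord(qname, right_flag, t.chrom, right_pos, _cigar_str(right_ops),
                   left_pos, -tlen, right_seq, qual, right_md, right_nm),
    ]


def _apply_errors(seq: str, rate: float, rng) -> str:
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < rate):
        choices = [b for b in BASES if b != out[i]]
        out[i] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def _record_truth(rec: _SamRecord, t: Transcript, chrom_seq: str,
                  truth: dict, cond_stats: dict) -> None:
    """Walk the finished record once, logging every planted/realized event."""
    import re

    q, r = 0, rec.pos
    aligned = 0
    for m in re.finditer(r"(\d+)([MIDNS])", rec.cigar):
        ln, op = int(m.group(1)), m.group(2)
        if op == "M":
            for i in range(ln):
                if rec.seq[q + i] != chrom_seq[r + i]:
                    truth["mismatches"].append(
                        [rec.qname, rec.chrom, r + i, chrom_seq[r + i],
                         rec.seq[q + i]])
                for snp in truth["snps"]:
                    if snp["chrom"] == rec.chrom and snp["pos"] == r + i:
                        snp["depth"] += 1
                        if rec.seq[q + i] == snp["alt"]:
                            snp["var_reads"] += 1
                        elif rec.seq[q + i] == snp["ref"]:
                            snp["ref_reads"] += 1
            aligned += ln
            q += ln
            r += ln
        elif op == "I":
            ins_seq = rec.seq[q:q + ln]
            truth["insertion_events"].append([rec.qname, rec.chrom, r, ins_seq])
            key = f"{rec.chrom}:{r}"
            if key in truth["insertions"] and truth["insertions"][key]["seq"] == ins_seq:
                truth["insertions"][key]["support"] += 1
            q += ln
        elif op == "S":
            q += ln
        elif op == "D":
            del_seq = chrom_seq[r:r + ln]
            truth["deletion_events"].append([rec.qname, rec.chrom, r, del_seq])
            key = f"{rec.chrom}:{r}"
            if key in truth["deletions"] and truth["deletions"][key]["seq"] == del_seq:
                truth["deletions"][key]["support"] += 1
            r += ln
        elif op == "N":
            jkey = f"{rec.chrom}:{r}-{r + ln}"
            truth["junctions"][jkey] = truth["junctions"].get(jkey, 0) + 1
            r += ln
    cond_stats["aligned_bases"][t.strand] += aligned
    by_t = cond_stats["aligned_bases_by_transcript"]
    by_t[t.name] = by_t.get(t.name, 0) + aligned


# ---------------------------------------------------------------------------
# Named scenarios
# ---------------------------------------------------------------------------


def basic_scenario(outdir: str, seed: int = 0) -> Bundle:
    """Two genes on opposite strands with one heterozygous SNP (target VAF
    0.5 at ~40x), one insertion, one deletion, splices and 10% duplicates."""
    spec = SimSpec(
        chrom_lengths={"chrT": 12000},
        transcripts=[
            Transcript("geneA", "chrT", "+",
                       ((1000, 1600), (2200, 2800), (3400, 4000)), depth=40),
            Transcript("geneB", "chrT", "-", ((6000, 6700), (7300, 8000)),
                       depth=25),
        ],
        planted_snps=[PlantedSnp("chrT", 1300, vaf=0.5)],
        planted_indels=[
            PlantedIndel("chrT", 2500, "ins", "TT", fraction=0.5),
            PlantedIndel("chrT", 3600, "del", 3, fraction=0.5),
        ],
        duplicate_rate=0.10,
        seed=seed,
    )
    return simulate(spec, outdir)


def null_scenario(outdir: str, seed: int = 0) -> Bundle:
    """Same gene structure, zero planted variants, zero errors, no duplicates."""
    spec = SimSpec(
        chrom_lengths={"chrT": 12000},
        transcripts=[
            Transcript("geneA", "chrT", "+",
                       ((1000, 1600), (2200, 2800), (3400, 4000)), depth=40),
            Transcript("geneB", "chrT", "-", ((6000, 6700), (7300, 8000)),
                       depth=25),
        ],
        seed=seed,
    )
    return simulate(spec, outdir)


def chimera_scenario(outdir: str, seed: int = 0) -> Bundle:
    """A fusion transcript joining gene A's third exon to gene B's fourth exon.

    Junction-spanning split reads carry an N gap from A.exon3.end to
    B.exon4.start; the realized count is in truth["junctions"].
    """
    exA = ((2000, 2400), (3000, 3400), (4000, 4400))
    exB = ((12000, 12400), (13000, 13400), (14000, 14400), (15000, 15400))
    spec = SimSpec(
        chrom_lengths={"chrT": 20000},
        transcripts=[
            Transcript("geneA", "chrT", "+", exA, depth=30),
            Transcript("geneB", "chrT", "+", exB, depth=30),
            Transcript("fusionAB", "chrT", "+", exA + (exB[3],), depth=20),
        ],
        seed=seed,
    )
    bundle = simulate(spec, outdir)
    bundle.truth["chimera_junction"] = f"chrT:{exA[2][1]}-{exB[3][0]}"
    bundle.truth["chimera_junction_reads"] = bundle.truth["junctions"].get(
        bundle.truth["chimera_junction"], 0)
    with open(bundle.truth_path, "w") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True)
    return bundle


def isoform_scenario(outdir: str, seed: int = 0, skip_fraction: float = 1 / 3) -> Bundle:
    """A five-exon gene with an isoform skipping the two middle exons.

    The skipping isoform gets ``skip_fraction`` of the locus depth, so about
    a third of junction reads jump from exon 2 straight to exon 5.  The
    realized skip fraction (skip junction reads over skip + inclusion
    junction reads at the shared donor) is recorded in the truth file.
    """
    exons = ((1000, 1400), (2000, 2400), (3000, 3400), (4000, 4400),
             (5000, 5400))
    total_depth = 45.0
    spec = SimSpec(
        chrom_lengths={"chrT": 8000},
        transcripts=[
            Transcript("isoFull", "chrT", "+", exons,
                       depth=total_depth * (1 - skip_fraction)),
            Transcript("isoSkip", "chrT", "+", (exons[0], exons[1], exons[4]),
                       depth=total_depth * skip_fraction),
        ],
        seed=seed,
    )
    bundle = simulate(spec, outdir)
    skip_key = f"chrT:{exons[1][1]}-{exons[4][0]}"
    incl_key = f"chrT:{exons[1][1]}-{exons[2][0]}"
    skip = bundle.truth["junctions"].get(skip_key, 0)
    incl = bundle.truth["junctions"].get(incl_key, 0)
    bundle.truth["skip_junction"] = skip_key
    bundle.truth["inclusion_junction"] = incl_key
    bundle.truth["skip_junction_reads"] = skip
    bundle.truth["inclusion_junction_reads"] = incl
    bundle.truth["target_skip_fraction"] = skip_fraction
    bundle.truth["realized_skip_fraction"] = (skip / (skip + incl)
                                              if skip + incl else 0.0)
    with open(bundle.truth_path, "w") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True)
    return bundle


def overlay_scenario(outdir: str, seed: int = 0, fold_change: float = 3.0) -> Bundle:
    """Two conditions over one locus: a minus-strand gene with a known fold
    change between conditions and an unchanged antisense transcript on the
    plus strand (the classic overlaid-wiggle differential-expression view)."""
    gene_exons = ((2000, 2600), (3200, 3800))
    anti_exons = ((2300, 3500),)
    base_depth = 12.0
    spec = SimSpec(
        chrom_lengths={"chrT": 6000},
        transcripts=[],
        seed=seed,
    )
    conditions = {
        "mock": [
            Transcript("geneC", "chrT", "-", gene_exons, depth=base_depth),
            Transcript("antiC", "chrT", "+", anti_exons, depth=15),
        ],
        "treated": [
            Transcript("geneC", "chrT", "-", gene_exons,
                       depth=base_depth * fold_change),
            Transcript("antiC", "chrT", "+", anti_exons, depth=15),
        ],
    }
    bundle = simulate(spec, outdir, conditions=conditions)
    mock = bundle.truth["conditions"]["mock"]["aligned_bases_by_transcript"]["geneC"]
    treated = bundle.truth["conditions"]["treated"]["aligned_bases_by_transcript"]["geneC"]
    bundle.truth["target_fold_change"] = fold_change
    bundle.truth["realized_fold_change"] = treated / mock if mock else 0.0
    bundle.truth["gene_region"] = ["chrT", gene_exons[0][0], gene_exons[-1][1]]
    with open(bundle.truth_path, "w") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True)
    return bundle


SCENARIOS = {
    "basic": basic_scenario,
    "null": null_scenario,
    "chimera": chimera_scenario,
    "isoform": isoform_scenario,
    "overlay": overlay_scenario,
}
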
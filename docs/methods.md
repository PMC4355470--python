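# Methods

## Coordinates and formats

All coordinates are 0-based half-open internally; the two parser boundaries
(BED/wiggle/XML input, TSV/CLI output) are the only conversion points, and
user-facing positions are printed 1-based inclusive in the UCSC habit. The
wiggle dialect is the 4-column `chrom start end value` form (bedGraph);
`fixedStep`/`variableStep` blocks are rejected with an explicit error rather
than silently misparsed. The sign of a wiggle value encodes transcript
strand. BED records carry score and RGB, but only the per-record RGB affects
rendering, and it wins over a track-level color.

Text tracks are served from a persisted linear binning index (fixed 16 kb
bins, one JSON sidecar per file, records registered in every bin they
overlap and de-duplicated at query time). Binning rather than a
tabix-compatible BGZF index keeps the sidecar human-readable while giving
the same touch-only-overlapping-bins property; queries are verified against
a brute-force linear scan in the tests. BAM files are required to arrive
coordinate-sorted with their standard index — region retrieval without an
index is an error, never a silent full scan.

## Alignment decoding

Mismatches are reconstructed from the MD tag alone (reference base from the
tag, read base and quality from the query after accounting for insertions
and soft clips), so no reference genome is needed for the reads track.
The MD walk covers aligned (M/=/X) and deleted (D) reference positions and
skips N gaps; a mismatch count always equals the MD mismatch-token count,
and an MD span that disagrees with the CIGAR reference span is a hard error
naming the read. Insertions come from CIGAR I ops; deleted sequences from
the MD `^`-runs (or `N` placeholders when the tag is absent).

Glyph geometry: reference blocks split only at N ops, so a small deletion
stays inside one drawn segment (annotated separately), while splice gaps
produce dashed connectors. Coverage, by contrast, counts only M/=/X bases —
deletions contribute no depth — matching common pileup semantics.

Transcript strand is a total function of the alignment flags and the stated
protocol (`unstranded`, `fr_secondstrand`: read 1 carries the transcript
orientation; `fr_firststrand`: the reverse). The protocol is a required
configuration value, never inferred from the data.

Exact-duplicate signatures cover chromosome, position, CIGAR, alignment
strand and the full base sequence — coordinates alone never merge two
different molecules — with pair mates canonicalized by (chromosome,
position) so either mate order yields the same key.

## SNP calling

Calling is per pileup column, quality-filtered at `min_base_qual` before
counting. The candidate alternate is the most frequent non-reference allele
(ties broken in fixed A<C<G<T order; multi-allelic columns report only the
top alternate, one colored line per position). The p-value is a one-sided
Fisher exact test of the observed ref/variant split against the split
expected from a null error rate `e`: table rows `(n_ref, n_var)` and
`(round(d·(1−e)), round(d·e))`, `p = P(X ≥ n_var)` under the hypergeometric
law with fixed margins. Defaults: `min_depth` 8, `min_var_reads` 2,
`min_vaf` 0.20, `min_base_qual` 15 (Phred), `max_p` 0.01, `error_rate`
0.01. Each criterion can be disabled by an extreme setting, and raising any
threshold can only remove calls (a property pinned by tests). Calling pools
both strands (no strand-bias filter); per-strand allele counts are retained
for display. Columns whose reference base is N are never called. The
p-value is per-position for the top alternate allele.

The implementation evaluates the hypergeometric tail with scipy and is
vectorized over columns; tests compare it against an independent
exact-integer enumeration of all tables consistent with the margins
(agreement to 1e-12 across every table with all margins ≤ 60).

## Layout

Mates are matched by read ID within the queried window; a mate outside the
window leaves a singleton annotated with the mate's location (chimeric
mates are likewise singletons with a location label — cross-window arcs are
out of scope). Pairs are single layout units, so mates always share a row.
Packing is first-fit per strand in (span start, span end, read ID) order,
which makes layouts deterministic under input shuffling; first-fit
guarantees no same-row overlap and uses at least as many rows as the
maximum interval overlap depth, but not necessarily the minimum. Row count
is unbounded in the layout; the renderer clips at a configurable limit
(default 50 rows per strand) and prints a "+k more rows" note instead of a
scrollbar. Glyph stroke thickness is `1 + floor(log2(multiplicity))`
display units capped at 5 — a monotone encoding of duplicate multiplicity;
the exact count is in the tooltip sidecar.

## Rendering

Every track lowers to one flat primitive list (lines, rectangles, polygons,
text); SVG, PDF and EPS writers serialize that same list, so the three
formats are views of a single scene graph. Output is byte-deterministic:
two-decimal float formatting, fixed attribute order, no timestamps — golden
outputs can be compared byte-for-byte. The PDF writer emits a single
flate-compressed content stream with ExtGState alpha entries; EPS is plain
PostScript, which has no transparency, so overlay members draw opaque
there. Overlay wiggles share one y transform (one positive and one negative
maximum over all members within the window) and draw at 50% opacity with
fixed per-member colors, so the overlap color emerges from compositing.
Degenerate all-empty overlays scale to (1, 1) to keep the axes finite.
Positions outside the window clip to its edge with a logged notice. Track
heights and fonts are documented constants in `render.py`.

Since static vector output has no hover, all mouse-over content (read IDs,
multiplicities, allele proportions, p-values, InDel sequences) is written to
a `.tooltips.json` sidecar keyed by element id.

## Synthetic data

The generator simulates an explicit haplotype per fragment — the
transcript's exon chain with the carried events applied — and derives each
read's CIGAR, MD tag and sequence from the haplotype-to-genome map, so the
three are mutually consistent by construction and `samtools calmd` agrees
with the emitted tags. Fragments are sampled uniformly along the spliced
transcript with Normal(180, 20) lengths clipped to [read length, transcript
length]; reads are 50 bp at constant Phred 30, error-free except planted
events (a uniform substitution-error mode exists for null-behavior tests).
Heterozygous SNPs are carried per fragment at the target VAF, indels at
their stated fraction; duplicates are literal record copies at the stated
rate; SAM flags encode the transcript strand under the chosen protocol
(default `fr_firststrand`). Each bundle records realized counts — variant
reads and depth at the SNP, per-event support, junction-spanning read
counts, per-strand aligned bases — in `truth.json`.

Default scenario conditions: the basic bundle plants one SNP at VAF 0.5 at
~40–60× depth (the regime where all five default criteria pass cleanly),
the fusion scenario joins the third exon of one gene to the fourth exon of
a second at 20× over two 30× parent genes, the isoform scenario gives the
exon-skipping transcript one third of a 45× locus, and the overlay scenario
applies a 3× fold change to a minus-strand gene while an overlapping
antisense transcript stays flat. These sizes keep every simulation under a
few seconds while leaving sampling noise well inside the tested bounds
(±10% on the fold change at these depths).

What the generator does not emulate: realistic error and quality models,
GC or positional bias, expression-level distributions, mapping ambiguity,
soft-clipped fusion evidence. Passing tests therefore demonstrate
correctness of the decoding/accounting/calling/layout machinery on
well-formed alignments, not robustness to aligner artifacts on real
libraries.

## Numerical and degenerate-input choices

- Fisher p clipped into (0, 1]; an all-zero table is p = 1 by convention.
- `round()` on the expected-row split follows banker's rounding (numpy
  `rint`); at default `e` = 0.01 this only matters below depth 50 and is
  pinned by tests.
- Empty read sets give all-zero coverage arrays; unknown chromosomes give
  empty query results (an unknown *index* is an error, an unknown *name* is
  not).
- All-clip CIGARs yield an empty block list and are treated as unaligned.
- Alt-allele ties and first-fit ties break on fixed lexicographic orders so
  every output is reproducible.

## Known limitations

- SNP calling has no strand-bias or read-position filters; on real data the
  five criteria alone will pass some systematic artifacts.
- InDels are not left-aligned/normalized; the same physical indel reported
  at different positions by the aligner stays distinct.
- The binning index loads a file's sidecar fully into memory; it targets
  track files up to millions of records, not whole-genome variant stores.
- EPS output ignores opacity (format limitation); PDF/SVG are the faithful
  renderings of overlays.
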
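# Methods

## Coordinate and counting conventions

All intervals are 0-based half-open internally; GTF (1-based inclusive) is
converted only at the I/O boundary, which keeps overlap arithmetic free of
off-by-one ambiguity. Introns are the gaps between consecutive exons of one
transcript, numbered 1..k in transcript orientation; their sequence is
extracted strand-aware so every intron reads `GT … AG`. Abutting exons are
treated as "no intron" (with a warning) rather than an error, because real
annotations contain them. Introns with identical genomic coordinates shared
by isoforms of one gene are deduplicated to a single record attached to the
transcript with the highest control-condition RPKM, to avoid double-counting
in group statistics; ties break lexicographically for determinism.

Only uniquely aligned fragments count (mapping quality / NH-tag convention
for SAM input). A fragment is **exonic** for a transcript when every aligned
block is contained in the transcript's exons *and* internal block boundaries
coincide with exon junctions; it is **intronic** for an intron when any
aligned base overlaps the intron. The asymmetry is deliberate: a single
intronic base is unambiguous evidence of retention, whereas exonic
assignment must respect splice structure. A fragment counts at most once per
feature; with a strand-specific library only same-strand fragments count
(configurable off). Interval joins are vectorized through pyranges.

## Retention index, filters, fold changes

RPKM = count × 10⁹ / (feature length × library size), with library size the
number of uniquely aligned fragments. The retention index is intron RPKM
over transcript exonic RPKM in the same sample. Replicates are combined by
the arithmetic mean of RPKM *before* the ratio — the simplest symmetric
choice when only the number of replicates, not their pairing, is known.

Filters: transcripts need mean control RPKM strictly > 10; introns need
RPKM > 10 % of the transcript RPKM in at least one replicate. The scope of
the 10 % rule ("any replicate of any sample") follows the literal reading of
the filter's definition and is configurable to control-only.

Fold change per knockdown is `(IR_kd + ε)/(IR_ctrl + ε)` with ε = 0.01. The
pseudo-count keeps fully spliced control introns finite; at typical index
magnitudes (0.01–1) it biases folds toward 1 only for indices comparable to
ε itself. "Affected" means any knockdown fold within [2, 10], a literal
two-sided window: enormous fold changes above 10 usually indicate a
near-zero control denominator rather than biology, but the cap is
configurable.

## Group statistics

Architecture labels (not mutually exclusive): FIRST (ordinal 1);
FIRST_BEFORE_LARGE_SECOND (ordinal 1 and downstream intron > 2 kb);
INTERNAL_AFTER/BEFORE_LARGE (internal intron whose immediate
upstream/downstream neighbor is > 2 kb); LARGE (> 2 kb itself);
IN_TRANSCRIPT_WITH_HUGE_INTRON (any intron of the transcript > 10 kb);
POOR_PY (no run of ≥ 7 consecutive pyrimidines within the last 50 nt).
Thresholds are strict (`> 2000`, `> 10000`). "All first introns" means every
ordinal-1 intron of an analyzed multi-exon transcript, whether or not a
second intron exists.

Each group is tested against **all analyzed introns outside the group** —
the complement is the natural symmetric comparison set when the question is
"does this class behave differently from the rest of the transcriptome".
The test is the two-sample Wilcoxon rank-sum / Mann-Whitney U: full
enumeration over all member assignments of the pooled values when pooled
n ≤ 8 (two-sided p = 2·min(P(U≤u), P(U≥u)) capped at 1, midranks for ties,
so identical values give p = 1), and the normal approximation with tie
correction above that. Default two-sided; one-sided alternatives are
available. Raw p-values are primary output; Benjamini–Hochberg across
labels is available but off by default, since the groups are few,
overlapping, and individually interpreted.

Transcript-level analysis bins each multi-intron transcript by its largest
intron with right-closed boundaries (0,0.5], (0.5,2], (2,10], (10,∞) kb —
a largest intron of exactly 2 kb falls in the second bin — and tests each
bin's steady-state RPKM fold changes (same ε rule) against all other
analyzed transcripts.

## Splice-competence rules

Parameters (all nucleotides, all configurable): `min_py_run = 7` within
`py_window = 50` from the intron 3′ end (the terminal AG is included in the
window; its G breaks any run, so the inclusion is inconsequential and keeps
the window definition simple); `autonomous_max_length = 90`, strict `<`, so
a 90-nt poor-pY intron is *not* autonomous; `ejc_offset = 24` upstream of a
flanking exon–exon junction; `rescue_distance = 250` with `≤` at the
boundary, because the distance itself is approximate.

All distances are measured on the pre-mRNA from the EJC deposition point to
the target intron's 3′ splice site. One geometric rule covers both sides:
for a downstream junction separated by an exon of length L the distance is
`L − 24`; for an upstream junction it is `24 + L + target intron length`,
which includes the unspliced target intron itself. A known tension: rescue
of a ~235-nt target intron by an upstream junction is geometrically tight
under a literal 250-nt threshold (24 + exon + 235 ≥ 259 even for a
vanishing exon). We keep the literal rule rather than tuning the threshold;
the upstream-rescue case is the model's least certain corner and is why
`rescue_distance` is exposed as a parameter.

## Synthetic data

The generator emulates a replicated two-condition, strand-specific bulk
RNA-seq design: by default 200 genes with 2–8 exons (uniform), exon lengths
100–400 nt (uniform), short intron lengths log-uniform 61–800 nt, a 6 % /
1.5 % chance per intron of being large (2–8 kb) or huge (10–16 kb), a 25 %
per-gene chance that the second intron is forced large (populating the
FIRST_BEFORE_LARGE_SECOND group), 30 % poor-pY introns, log-normal (σ = 1)
transcript abundances shared between conditions, per-intron retention
fractions r drawn uniformly from [0.02, 0.5] — spanning mostly-spliced to
half-retained — and an expected 10⁶ fragments per sample of length 100
(paired 50-mers collapsed to one fragment span). Noise is Poisson by
default; a gamma-mixed negative binomial (dispersion 0.1) is available to
stress the rank-sum test under overdispersion.

Good-pY introns carry an embedded 12-pyrimidine run inside the last 50 nt;
poor-pY introns are synthesized with every C/T run capped at 4, so scanner
outcomes are guaranteed by construction. Expected fragment counts are
abundance × exonic length for transcripts and abundance × r × intron length
for introns, so the estimated retention index is an asymptotically unbiased
estimator of r. Exonic fragments are spliced across junctions; intronic
fragments lie wholly inside the intron.

Deliberate simplifications: retention is modeled per intron independently
(not per pre-mRNA molecule), so exonic coverage is not depleted by
retention and no fragment spans an exon–intron boundary; there is no
sequencing error, no mappability structure, no positional bias, and genes
do not overlap. Passing recovery tests therefore demonstrates correctness
of the counting/normalization/testing machinery, not robustness to
alignment artifacts or isoform complexity in real libraries.

A count-level path (`simulate_counts`) draws per-feature counts from the
same expected-count model without read placement. It exists for calibration
studies that need hundreds of replicate simulations (group-test power and
null uniformity); read-level recovery is checked separately at full scale.

## Problem sizes and numerical choices

The retention-recovery check uses 200 genes, 2 conditions × 2 replicates at
10⁶ fragments per sample and requires the truth-vs-estimate regression
slope within 1 ± 0.1; with these sizes it lands at ≈ 1.00. Power and type-I
calibration of the group test use 250 genes (≈ 70 analyzed group members,
≈ 800 background introns), a 3× planted multiplier over 20 seeded runs, and
200 null replicates for the KS uniformity check — sizes at which a single
run takes tens of milliseconds on the count-level path. Relative error of
index estimates scales as depth^(−1/2), as expected for Poisson counting
noise; the test suite asserts the √2 improvement on depth doubling.

All randomness flows through `numpy.random.default_rng` seeded from the
configuration; a fixed seed yields byte-identical GTF/FASTA/TSV outputs.
Per-sample streams are derived from (seed, stage tag, condition index,
replicate), keeping samples independent but reproducible. Degenerate
inputs: zero library size, zero-length features, a missing control
condition, and a retention index over a zero transcript RPKM are hard
errors; empty groups in testing produce an explanatory status record rather
than an exception.

## Known limitations

Real-data caveats beyond the simulator's scope: no isoform deconvolution
(the retention index inherits whichever transcript model the intron is
attached to), no junction-level percent-spliced-in, no exon-skipping calls,
and alignment is consumed, not performed — multimapper handling is only as
good as the aligner's flags. The upstream-rescue geometry of the splice
rules is the least constrained part of the model, as discussed above.
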
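# Methods notes

## The read matrix

All metrics operate on a per-region binary matrix R built from PAT
records: each record expands to `count` identical rows; calls outside the
region are trimmed; region CpGs a read does not cover, and `.` calls,
become NA. Reads partially overlapping a region are included whenever
they observe at least `min_overlap` region CpGs (default 1); the original
tooling's inclusion rule is not documented, and requiring a single
observed call is the least biased choice. A region with no surviving
reads yields an empty matrix, and every metric returns NA on it. A
`max_reads` cap (off by default) takes a seeded uniform row subsample as
a memory/runtime guard, since MPCI's cost is quadratic in read depth.

Genomic coordinates enter through a CpG map: forward-strand CG
dinucleotides of a FASTA, numbered from 1 in genome order. Reverse-strand
CpGs are not separately indexed — PAT collapses each CpG unit to its
forward-strand cytosine. BED input is 0-based half-open; CpG-index
regions are 1-based inclusive.

## MPCI formulation choices

Two details of the published formula are underdetermined, and one is
internally inconsistent; the package resolves them as follows.

**Orientation-score denominator.** Dividing Σ W·S by Σ W makes an
all-unmethylated matrix score (−k)/(−k) = +1 and is unbounded when
Σ W ≈ 0, contradicting the metric's stated range and the meaning of
negative values. The package divides by the *number* of valid pairs
(= Σ|W|), which yields the documented [−1, +1] range, the −1 fixed point
for consistent unmethylation, and antisymmetry under 0↔1 complement.
No flag is offered for the inconsistent variant.

**Similarity denominator.** The literal formula divides the Manhattan
distance by the column count; with missing data this counts unobserved
positions as zero distance and inflates similarity for sparsely
overlapping pairs. The default divides by the number of jointly observed
positions (`similarity_denominator="joint"`); `"ncols"` offers the
literal behaviour for fidelity experiments. A pair with no jointly
observed position is NA under both.

**Pair set.** The double sum runs over all ordered pairs including
self-pairs (i = j), matching the literal summation limits; self-pairs
have S = 1 and anchor the score to the read's own majority.
`include_self_pairs=False` switches to unordered distinct pairs.

**Tie coins.** When a pair's pooled methylation fraction is exactly 1/2
its weight is a fair coin. Coins are drawn one per tie pair, in row-major
pair order, from a `numpy` Generator; each orientation gets a fresh
Generator built from the same seed. This makes `compute_mpci(R)` equal to
`compute_mpci(Rᵀ)` bit-for-bit even when both orientations contain ties
(the same pair receives the same coin either way) at the cost of coin
independence *across* orientations — a negligible concession, as
replicate studies put the tie-induced SD near 0.005 on real data, and
`mpci_replicates` lets users quantify it on their own matrices.
Row/column permutation invariance and complement antisymmetry hold
exactly on tie-free matrices; with ties they hold only distributionally,
because permutations reassign coins to different pairs.

Tie comparisons use exact integer arithmetic (2·#ones vs #observed), so
no floating-point threshold is involved.

## Haplotype load

MHL weights the fraction of fully methylated length-l substrings by
w_l = l (configurable); lengths with no observed substring drop out of
both sums. A `.` call splits a read into independent runs by default, so
substrings never span an unknown call; `split_on_missing=False` instead
compresses each read's observed calls. The upstream formulation's
treatment of interrupted reads is not restated in the sources we follow,
so the conservative run-splitting is the default and flagged. uMHL is
computed as MHL of the complemented matrix, which makes the mirror
identity MHL(1−R) = uMHL(R) exact by construction; dMHL = MHL − uMHL.

## Heterogeneity panel

ME and EP slide a window of b = 4 consecutive region CpGs (regions
shorter than b score NA) and use only reads observing the full window;
windows need ≥ 1 such read. PDR requires ≥ 4 observed CpGs per read.
FDRP/qFDRP sample up to 40 read pairs per CpG (seeded) and require ≥ 1
jointly observed CpG per pair. These caps follow the cited reference
implementations' published defaults where stated and minimal values
otherwise; all are keyword-configurable. Windows and pair distances are
defined in region CpG-index space rather than base pairs, because PAT
patterns carry no base-pair geometry — a deliberate adaptation.

## Synthetic data and spike-in

The generator emulates what the metrics consume, not sequencing physics:
reads of 3–8 CpGs (uniform; cfDNA-scale fragments span a handful of CpGs
at typical CpG densities), uniform start within the region, haplotype
class drawn from {fully methylated, fully unmethylated, per-CpG
Bernoulli(θ)} with weights π, and independent per-call dropout to `.`.
It does not model fragment length in bp, GC bias, bisulfite conversion
errors, or correlated (block-structured) partial methylation — so passing
benchmarks demonstrate correctness of the computational pipeline and
sensitivity under idealised epiallele mixtures, not performance on real
tissue.

Spike-in follows the liquid-biopsy construction: the healthy background
is downsampled to a target mean coverage (default 100 reads per CpG,
measured as mean observed calls per region CpG), then exactly
round(f·n) of its n reads are removed and replaced by target-tissue
reads (ties-to-even rounding), conserving the total read count. Cohort
simulation derives per-sample, per-region seeds from one master seed, so
cohorts are byte-reproducible.

## Benchmarking harness

Features are one metric across regions; features with >10% missing
values, then samples with >80% missing, are dropped (strict
inequalities), and remaining NAs are imputed with the feature median
(the sources are silent on imputation; median is robust and the flag
`impute=False` disables it). The classifier is a linear SVM with
Platt-scaled probabilities inside stratified nested CV (5 outer / 3
inner folds); C is tuned on a decade grid, 10⁻³–10 for spike-in-style
runs and 10⁻³–10³ for the wide grid. Pooled ROC aggregates probabilities
across outer folds; AUC is the trapezoid area, which equals the
Mann–Whitney rank statistic. Metric comparisons use the Wilcoxon
signed-rank test on fold-paired values (identical vectors return p = 1,
as a signed-rank test is undefined on all-zero differences) or the exact
two-sided rank-sum test unpaired, with Benjamini–Hochberg adjustment
across performance measures.

DMR scores are group-mean differences (missing ignored; NA if a group is
entirely missing); `scale_factor=2` maps an MHL differential (range 0–1)
onto the MPCI differential scale (0–2). Top-k ranking is stable under
ties (input order); quadrant partitions assign boundary points to the
low side.

## Region selection

Random regions are drawn per CpG-count bin (defaults: 100 regions each
of 3–7, 8–12, 13–17, 18–22 CpGs), rejected if they straddle a chromosome
boundary, and de-overlapped greedily (keep-first in sorted order).
Coverage filtering keeps regions with mean reads-per-CpG strictly greater
than 10 in all samples ("more than 10×"), while high-coverage discovery
requires ≥ 50 reads at every CpG ("at least 50") across runs of ≥ 5
consecutive CpGs, emitting maximal runs ranked by mean coverage with
genomic-order tie-breaks. The exact greedy variant used upstream is
unstated; maximal-run extension is the minimal rule satisfying the
stated thresholds, and all thresholds are parameters.

## Verification scale

The test suite checks analytic fixed points, exhaustive agreement with a
literal pair-enumeration oracle on every complete binary matrix up to
4×4 (with tie-pair outcomes verified by exact integer subset-sum over
coin assignments), 1000-matrix invariant fuzzing with up to 30% missing
calls, exact spike-in bookkeeping at f ∈ {1%, 5%, 10%}, and a
50 + 50-sample, 50-region synthetic cohort at 100× coverage where a 10%
spike-in must reach pooled AUC ≥ 0.95 and the zero-spike cohort must be
statistically null under label permutation. These sizes keep the whole
suite within a few minutes on one CPU while exercising every code path
at the study's stated operating points (100× backgrounds, 1–10%
fractions, 3–22-CpG regions).
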
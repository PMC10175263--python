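# Methods

`cdkp` re-implements, as a tested pipeline on synthetic data, the
computational core of a combinatorial CRISPR–Cas9 study of cyclin-dependent
kinases: dual-guide genetic-interaction scoring with imputed single-guide
fitness, a polar-coordinate cell-cycle embedding with circular statistics,
knockout transcriptome phenotyping, and a 5′ exon-coverage-bias analysis.
This note records the models, the parameters that matter, what the
synthetic-data generators do and do not emulate, and the design choices
made where the design was genuinely open.

## Dual-guide library and read counting

A library of n guides (by default 26 genes × 4 guides + 4 non-targeting +
4 AAVS1 safe-harbor controls = 112 guides) is paired into all n(n−1)
ordered constructs (12,432 at n = 112). Each synthesis oligo is the fixed
cassette scaffold with spacer 1, a 15-nt barcode, and spacer 2; the barcode
is a permutation of three 5-nt code words with pairwise Hamming distance
≥ 3. Barcode generation is greedy rejection over lexicographic order (a
"lexicode"), which attains the optimal 64-word code at length 5/distance 3;
the seed enters as a per-position alphabet permutation, a Hamming isometry,
so different seeds give different but equally valid codes. A requested
count beyond the Singleton bound 4^(L−d+1) is reported as a shortfall, not
an error.

Reads are assigned by windowed Levenshtein distance (via edlib, prefix
mode) between the read's spacer window and every spacer expected at that
cassette position; a mate pair is counted iff both reads match within
distance 2 unambiguously and the ordered pair exists in the design. This
replaces an aligner-plus-filter pipeline with a direct implementation of
the same distance-<3 acceptance rule. Ambiguous ties are rejected —
miscounting near-homologous kinase spacers is worse than losing a read.

Counts become log2 relative abundances x = log2((M+1)/Σ(M+1)) (pseudocount
1 keeps the log finite for dropouts), fold changes m = x_t − x_t0, and
fitness f = (m − μ)/σ z-standardized over all constructs of one
(timepoint, replicate) sample with the population standard deviation.

## Interaction scoring

The additive (log-scale multiplicative) model f_pair = f_g1 + f_g2 + π
defines the interaction π. Summing over all pairs containing a guide and
dropping the interaction sums (interactions are rare and centered on zero)
gives the linear system A·x = b with A = (N−2)I + J. Both cassette orders
enter as independent observations: each observed pair adds one count to
both of its guides' rows, so complete data doubles the canonical system
without changing its solution. The complete case is solved in closed form
(x = (b − 1·Σb/(2N−2))/(N−2)); incomplete matrices keep the per-row
construction with the observed degree on the diagonal and go through least
squares. Guide-level π values are averaged over all guide combinations and
both orders of a gene pair (32 values for the 4-guide design), z-scored
across gene pairs within each sample, and summarized as the median z over
samples.

Calls: the per-sample gene z-scores are only weakly correlated across
samples (sampling noise dominates under the null), so their median is
noticeably tighter than unit-normal; a fixed cut of ±2 on the raw median
would call almost nothing under the null. The final median is therefore
re-standardized across gene pairs (`final_z`) and the call threshold
(default |z| ≥ 2) applies there, where it retains its nominal normal-tail
meaning (~2.3% per tail under the null). Negative = synthetic-sick/lethal,
positive = synergistic. Residual attenuation of a planted interaction is
expected and observed (~10%): the imputation deliberately drops the
interaction sums, so part of a strong π leaks into the single-guide
estimates of its two genes.

## Screen simulator

Constructs grow exponentially: p(t) ∝ p(0)·2^((f1+f2+π)·t/τ) with τ = the
screen duration (so fitness is log2 change per screen), initial abundances
lognormal around uniform (sd 0.2, synthesis unevenness), and exactly
`depth` reads drawn multinomially per (timepoint, replicate). Defaults:
depth 10⁶, timepoints (0, 7, 14, 21) days, 2 replicates, gene-level
fitness ~ N(0,1) with guide-level jitter (sd 0.2) and neutral controls.
Not emulated: PCR amplification bias, UMI collisions, cell-to-cell growth
stochasticity beyond multinomial sampling — so recovery tests demonstrate
correctness of the estimator under its own model, not robustness to those
artifacts. The paired-read simulator emits the exact cassette layouts with
iid substitutions (indels off by default, keeping edit-distance
expectations analytic).

## Cell-cycle embedding

Five marker sets (phases M, M/G1, G1/S, S, G2/M) give per-cell phase means
E_ik, a pan-phase profile E_i, and a coarse label C_i = argmax_k E_ik (ties
break in canonical phase order). Cells are embedded by metric MDS (SMACOF,
seeded, n_init = 4) of the cosine distances 1 − cos(E_m, E_n) and converted
to polar coordinates. Because an MDS solution is arbitrary up to
rotation/reflection, the embedding is canonicalized: rotated so the
circular mean of M/G1-labeled cells sits at the canonical M/G1 arc center
and reflected so the phase sequence runs counter-clockwise. Angular bins
(default 60 bins = 6°) take the modal coarse label of their cells; empty
bins inherit the nearest label.

The canonical layout uses five equal arcs, and the simulator's marker
peak angles tile each arc on an even grid. Both choices are deliberate:
with unequal arcs or clumped random peaks, the crossing point of two
phase-score curves sits away from the planted boundary — a bias of the
synthetic design, not of the estimator — which would make boundary-recovery
tests unfalsifiable. The simulator draws control cells uniformly on the
circle, gives markers von Mises-bump mean profiles (baseline 0.3,
amplitude 4, κ = 4 — shallow-coverage counts of mean ~1–5) and
gamma-Poisson noise (dispersion 0.3); knockouts draw a weight fraction of
their cells from a von Mises at a target phase. Real cycling populations
are not uniform in phase and markers are noisier and partially redundant;
the recovery tests show estimator correctness under smooth periodic
structure, not performance on real 10x data.

Angle agreement is measured with the Fisher–Lee circular correlation
(pairwise sine products), which is invariant to rotations and well defined
for uniform marginals; mean-direction-based estimators are unstable there.

The two-sample Kuiper test uses V = max(F1−F2) + max(F2−F1) on the pooled
circular ECDFs — rotation-invariant, unlike Kolmogorov–Smirnov — with
Stephens' effective-sample-size correction of the asymptotic tail series
and a seeded permutation fallback below 20 cells per group. Measured
type-I error at p < 0.05 is ~4–5% at n = 200.

Cell-cycle signal removal smooths each phase score over θ with a periodic
local-linear (tricube) smoother, span 0.3, and residualizes every gene on
the five smoothed scores by OLS. OLS residuals are exactly orthogonal to
the regressors, so the operation is idempotent; on simulation the θ-explained
variance of markers drops from ~40% to < 1% while background genes keep
r > 0.99 with their pre-removal values.

Marker expansion scores each unannotated gene by its mean Pearson
correlation to each phase's markers and assigns a phase only when the top
score is positive, beats every other phase in a one-sided Welch t-test over
per-marker correlations (α = 0.05), and the variance of the five phase
scores exceeds the across-gene mean by 2 SD.

## Knockout transcriptome phenotyping

QC follows the standard single-cell thresholds (cells: 200–10,000 expressed
genes, ≤ 10% mitochondrial reads; genes: ≥ 3 cells; cell filters before the
gene filter), then total-count normalization and log1p via scanpy. A
knockout's profile is the per-transcript median log2 fold change versus the
median over AAVS1 control cells; differences of log1p-normalized values are
divided by ln 2, so the profile is a log2 fold change of pseudocounted
expression. Profiles and their bootstrap clouds embed jointly by MDS with
the control at the origin.

The bootstrap of the median is smoothed (Gaussian kernel, bandwidth 0.5 ×
Silverman per gene, `smooth=0` for the plain bootstrap): a plain resample
median can only land on observed order statistics, and its cloud
understates the estimator's sampling spread by several percent — pilot
calibration against a large-sample truth fixed the 0.5 factor at a unit
spread ratio. Confidence contours default to the bootstrap covariance
ellipse (χ² quantile); a KDE highest-density contour is available but
systematically undercovers for lattice-valued clouds. Measured coverage of
the true median by the 95% ellipse is ~95%.

Differential expression is a two-sided Mann–Whitney U per gene with
Benjamini–Hochberg correction (DE at q < 0.05); constant genes get p = 1.
The knockout-expression generator uses lognormal base means (μ = 2.5,
σ = 0.8 on the log scale — well-detected transcripts, since a shift planted
on an always-zero transcript is unobservable at any sample size),
gamma-Poisson noise, and rescales each knockout's mean vector to the
baseline total: the readout is compositional with unchanged library size,
which is exactly the regime where total-count normalization is valid. DE
benchmarks plant mass-balanced signatures (one third of DE genes doubled,
two thirds halved) so that unperturbed genes are genuinely null rather than
carrying a composition artifact; with one-sided signatures the measured
"false positives" are real compositional shifts, a known limitation of
relative abundance data rather than of the test.

Perturbation magnitude (profile norm by default, embedding distance
optionally) is correlated with the knockout's fitness effect by Pearson r.

## 5′ coverage bias

Exons are classified per gene, strand-aware: First = the 5′-most
transcript-initial exon, AlternativeFirst = other initial exons, Last = the
3′-most terminal exon, AlternativeLast = other terminal exons, Internal =
the rest; identical exons shared between transcripts are single records and
conflicts resolve First > Last > AlternativeFirst > AlternativeLast >
Internal. GTF coordinates are converted to 0-based half-open; a read counts
for every exon it overlaps by ≥ 1 bp. Genes under 10 assigned reads in a
sample are dropped from that sample; per-exon coverage is log2(RPM + 1)
(pseudocount 1), fold enrichment is against the mean of the non-targeting
control samples, and the 5′ bias is bias5 = lfc(First) − lfc(Last) — the
difference of log2 enrichments, i.e. the log2 of the linear enrichment
ratio, chosen because it is symmetric and finite. First-exon shift
significance is a Welch t-test of per-gene First-exon enrichments against a
reference sample (or against zero). Gene bias patterns across knockouts are
clustered by complete-linkage hierarchical clustering on Euclidean
distances, cut into 12 clusters by default, with a local Fisher-exact/BH
helper for gene-set enrichment of cluster members (GMT input).

The coverage simulator plants uniform expected per-exon coverage
(10⁴ reads per gene, Poisson) and multiplies the First exon by 2^bias for
chosen (knockout, gene) pairs; it emits single-transcript gene models
(multi-transcript classification is exercised by explicit worked examples).
Planted bias 2.0 is recovered within ±0.1 at that depth.

## Problem sizes and tolerances

Benchmarks run at the sizes the recovery claims refer to: 20 genes ×
4 guides at depth 10⁶ for screens (20 independent null screens for
calibration), 2,000 cells for the embedding, 1,000 null trials (n = 200)
for Kuiper calibration, 3 × 200 planted DE genes among 2,000 at 200 cells
per group, 500 bootstrap-coverage runs at 250 cells, 40 genes at 10⁴
reads per gene for coverage bias. Numerical tolerances: the closed-form
fitness solve matches a generic solver to 1e−10; exact-arithmetic checks
(pair counts, contig counts, error-free counting) have no tolerance.

## Known limitations

* The interaction model is additive in guides; polyclonal editing outcomes,
  partial knockouts and guide efficiency differences appear only as the
  simulator's guide-level fitness jitter.
* The cell-cycle simulator's markers are phase-exclusive and smoothly
  periodic; real marker sets overlap and include stress-response
  contamination.
* The Kuiper asymptotic p-value is slightly conservative at moderate n
  (measured 4–5% at nominal 5%); the permutation mode is exact but slower.
* The 15-nt barcode design assumes unique 5-mer code words; it does not
  model synthesis deletions inside barcodes.
* The coverage-bias statistic requires both a First and a Last exon with
  data; single-exon genes are excluded by construction.
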
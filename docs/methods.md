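# Methods

This note documents the models, parameter choices and numerical decisions
behind `endonet`, and what the synthetic-data tests do and do not show
about real data.

## Study design and data model

The pipeline targets a staged time-course bulk-transcriptome design: an
ordered set of stages (default D12 … D114 of pregnancy), a fixed number of
biological replicates per stage (default 3, so 18 samples), and one
baseline stage (default D12) that serves both as the differential-
expression reference and as the ΔΔCT calibrator. The central object is a
genes × samples matrix of log2-scale expression values with a sample →
stage map; all downstream stages consume it.

## Preprocessing

*Quantile normalization* forces every sample to the common reference
distribution formed by rank-wise means of the column-sorted values. Ties
are resolved by averaging the reference over the tied rank span, the
standard dialect; the procedure is idempotent. *Median polish* follows
Tukey's alternating row/column median sweeps (tolerance 1e-6 on the
residual change, at most 10 sweeps — conventional defaults), and a gene's
per-sample summary is the overall effect plus that sample's column
effect, so constant per-probe offsets are absorbed by the row effects.
Background correction is deliberately a no-op: inputs are assumed
background-free, and probe-level modelling beyond
normalize-summarize-log2 is out of scope.

## Differential expression

Each later stage is compared to the baseline with a per-gene unpaired
Welch t-test; the Welch–Satterthwaite degrees of freedom and a two-sided
p-value follow. BH adjustment is applied **within each comparison**, not
pooled across the five comparisons — this matches the per-contrast
convention of linear-model microarray pipelines and the way per-stage DEG
counts are usually reported. The degenerate both-variances-zero case
returns t = 0, p = 1 when the means agree (no evidence against the null)
and p = 0 otherwise. Direction is the sign of the stage-mean log2
difference. Moderated (empirical-Bayes) variance shrinkage is
intentionally not implemented: the stated decision criterion is the plain
Welch test at FDR < 0.05.

## Soft temporal clustering

Replicates are averaged within stage before standardization, because the
objects being clustered are six-point *time profiles*, not 18-sample
vectors. Each profile is standardized to mean 0 / sd 1 (population sd;
the choice of sd denominator, like the upstream log base, is irrelevant
after standardization). Constant profiles are dropped with a warning.

Fuzzy c-means uses Euclidean distance, membership update
`u_ik = 1 / Σ_j (d_ik/d_jk)^(2/(m−1))` computed in log space for
stability at small fuzzifiers, centroid update as the `u^m`-weighted
mean, and the objective `J = Σ u^m d²`, which is non-increasing across
iterations. Zero-distance profiles receive a one-hot membership on the
nearest centroid (lowest index on ties). Initialization is k-means++
seeding with a fixed seed and 3 restarts, keeping the lowest final J;
hard labels are argmax memberships with lowest-index tie-breaking, and
cluster identity is only defined up to permutation.

Because c and m are not known a priori they are estimated:

* **m** — the randomized-data criterion: each candidate fuzzifier is run
  on a structure-destroyed copy (every stage column permuted
  independently across genes) and the selected m is the smallest whose
  randomized-control mean maximal membership comes within 0.1 of the
  uniform value 1/c. Below that value FCM still reports confident
  clusters on structureless data; above it, any concentration seen on
  the real data reflects real structure.
* **c** — the minimum-centroid-distance collapse: for each candidate c
  the smallest pairwise centroid distance D(c) is recorded; once c
  exceeds the number of real clusters, extra centroids split existing
  clusters and D collapses. The selected c is the largest candidate
  before D first falls below 10% of its maximum over the range.

## Co-expression network

The adjacency implements the power law `a_ij = |r_ij²|^β` literally
(equivalent to `|r|^(2β)`); a conventional `|r|^β` dialect is available
behind the `adjacency_dialect="abs"` switch. The diagonal is zeroed so
connectivity `k_i = Σ_j a_ij` excludes self-edges. Constant genes have
undefined correlation and are excluded with a warning.

β is chosen by the scale-free topology criterion: connectivities are
binned into 10 equal-width bins, p(k) is the per-bin gene fraction, and
the chosen β is the smallest candidate whose log10 p(k) on log10 k
regression reaches R² ≥ 0.8 with negative slope. The default candidate
set is 1–6: in the squared dialect each candidate contributes exponent
2β, so this spans total exponents 2–12, the conventional range for
unsigned soft thresholds; pushing the exponent further drives the
within-module adjacency of a desk-scale network toward zero and
dissolves the very structure the network is meant to expose. When no
candidate reaches the target — common at desk scale, where a few planted
blocks cannot produce a clean power-law degree distribution — the
best-fitting candidate is used and a warning is logged.

The topological overlap is
`ω_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)` with
`l_ij = Σ_u a_iu a_uj`, unit diagonal, and dissimilarity 1 − ω. Modules
are branches of the average-linkage dendrogram that lie strictly below
the static height cut (default 0.94; a single fixed height, not a
dynamic tree cut) and contain at least `min_module_size` genes (default
30 — the smallest module such studies report is around 39 genes);
everything else is background. Modules are named by the canonical colour
sequence in decreasing size order, with size ties broken by the
lexicographically smallest member id, which also makes the assignment
invariant to gene input order.

Signed connectivity splits each gene's adjacency sum by the sign of the
underlying correlation (network-wide, per the connectivity definition)
and scales each sign by its maximum **within the gene's module** — the
only scaling under which every module's top gene shows scaled K = 1, as
hub tables in this literature display. A hub needs
max(scaled K⁺, scaled K⁻) > 0.9 and more than 10 connected partners;
"connected" on a weighted complete graph requires an explicit edge
threshold, default a_ij ≥ 0.02, configurable. Module eigengenes,
module–trait correlation and module merging are out of scope.

## qPCR validation

ΔCT normalizes the target CT to the arithmetic mean CT of the two
endogenous controls (equivalent to the geometric mean of their
abundances — standard multi-reference practice); ΔΔCT subtracts the mean
ΔCT over all baseline-stage samples rather than a single calibrator
sample, so the geometric mean of baseline relative expression is exactly
1. Relative expression is 2^(−ΔΔCT). The validation network computes
all-pairs Pearson correlations — by default on log2 relative expression,
the scale on which qPCR noise is closer to additive, with a switch for
the linear 2^-ΔΔCT scale — with p-values from the t transform
`t = r √((n−2)/(1−r²))`, BH adjustment jointly over all pairs, edges at
adjusted p < 0.05, and per-sample vectors by default (a per-stage-mean
option exists). Amplification-efficiency correction is out of scope.

## Synthetic data generator

The generator emulates an 18-array staged study on the log2 scale with
three planted gene classes and returns the full ground truth. Because no
public raw data accompany the design it emulates, its noise model and
effect sizes are the package's own choices, fixed once:

* Per-gene baselines ~ N(8, 1.5²) log2 units; residual noise Gaussian on
  the log2 scale (the standard post-summarization microarray
  assumption) with sd 0.25; temporal effect amplitude 1.0 log2 units.
* **Archetype genes** follow one of eight temporal archetypes — mid-
  gestation peak, monotone decline, post-mid-gestation drop, gradual
  rise with a terminal spike, high-at-baseline, and the mirrors of the
  first, third and fourth — standardized curves interpolated onto the
  stage axis. Eight shapes mirror the cluster count such time courses
  typically resolve, which is what makes cluster-number recovery a
  meaningful test.
* **Module genes** (five modules, default sizes 130/110/90/70/50) load
  on mutually orthogonal mean-zero stage contrasts, so expected cross-
  module correlation is zero and a sharp dissimilarity gap exists at the
  static cut. Loadings are ±√ρ with noise √(1−ρ), giving expected
  pairwise |r| equal to the target within-module correlation (0.8 by
  default); 30% of members load negatively to exercise the signed
  connectivity; each module's first member is the designated hub with
  4× lower idiosyncratic noise, which maximizes its expected
  connectivity without altering the module's correlation target.
* **Null genes** (half of the matrix) are i.i.d. noise around their
  baseline.

Probe-level expansion adds a fixed, median-centred per-probe offset
(median-centring makes median-polish summarization recover the gene row
exactly in the noiseless case) plus optional measurement noise. CT
tables are generated on the cycle scale, CT = 30 − expression + noise,
with reference genes constant in expectation.

What passing recovery tests on these data do **not** show: robustness to
heavy-tailed or intensity-dependent noise, to unbalanced designs or
missing samples, to correlated null genes (e.g. shared technical
factors), to module overlap or hub genes shared between modules, and to
the annotation ambiguities of real probe sets. The generator's planted
structure is deliberately clean so that failures indicate implementation
defects rather than statistical bad luck.

## Problem sizes and determinism

The shipped test suite and the acceptance script run the generator at
1,000 genes for network recovery (ten seeds) and 2,000 profiles for
cluster-number recovery (ten seeds) — sizes chosen so the planted
structure is comfortably detectable while a full run stays around a
minute on one core. One integer seed drives every stochastic stage;
identical configuration plus seed reproduces byte-identical outputs.
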
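# Methods

## Network construction

A subject's morphometric similarity network is built from a 68-region
(Desikan–Killiany) × k-feature table. Each feature is z-scored across regions
using the sample SD (n−1 denominator); the choice of denominator only
rescales columns uniformly and leaves the network unchanged (asserted by
test). The edge between two regions is the Pearson correlation of their
z-scored feature vectors; the diagonal is stored as exact zeros and excluded
from every statistic. Three nested feature models are supported: msn10
(CT, SA, GM, MC, GC, FI, CI, T1T2, FA, MD), msn8 = msn10 − {FA, MD}, and
msn7 = msn8 − {T1T2}. Because region-pair Pearson correlations with only two
features are degenerate (±1), at least three features are required.

## Density thresholding

Networks are compared at matched density d ∈ (0, 1]: the
k = round(d·n(n−1)/2) largest off-diagonal weights by **signed** value are
retained (the strongest similarities; ranking by |weight| is available as
`rank_by="magnitude"` for sensitivity analyses). k rounds half away from
zero, and ties at the cutoff break by ascending (i, j) edge index. Both
choices are fixed conventions rather than field standards; with them,
retained edge sets nest monotonically in d. The default grid is 0.05–0.40 in
steps of 0.05. Nodal strength is the plain row sum of retained weights (not
normalized by edge count, since compared networks share edge counts); graph
strength is its mean over nodes.

## Similarity statistics

* `edge_correlation(mode="all")` — Pearson over all n(n−1) off-diagonal
  elements.
* `edge_correlation(mode="nonzero")` — restricted to elements nonzero in
  *both* networks (union-zero exclusion; the stricter reading, and the one
  that keeps the statistic symmetric).
* `mantel_statistic` — Pearson over the strictly-lower triangles. On
  symmetric zero-diagonal matrices this equals the all-edge correlation
  exactly (duplicating both halves leaves Pearson r unchanged); both are
  reported because they are conventionally treated as distinct guards
  against duplicated-half inflation. A permutation p (simultaneous row/column
  permutation of one matrix, +1-smoothed) is available but off by default —
  the statistic is used descriptively.
* `replication_proportion` — for binary networks, Σ(xᵢ≠0 & yᵢ≠0)/Σ(xᵢ≠0)
  with x the fuller/reference model. At equal densities (equal edge counts)
  it is symmetric in its arguments.
* `paired_effect_size` — paired t over subjects with df = n−1 converted to
  r = √(t²/(t²+df)), the standard conversion; p values are not reported.

## Reliability analyses

Intermodel comparisons are hierarchical: msn10 is the reference and is
compared with msn8 and with msn7 only (never 8 vs 7). Test-retest compares
each subject's session-1 and retest networks of the same model. The group
network is the element-wise mean of the cohort's **thresholded** weighted
matrices at each density (averaging raw networks then thresholding is an
option — the alternative reading — and gives closely similar results); for
binary comparison the group mean is re-thresholded to density d. Subjects are
not excluded from the group mean (no leave-one-out); at realistic cohort
sizes the induced bias is negligible. Summaries report M ± SD with the n
actually analyzed after skip-with-warning exclusions.

## Cognition prediction

Nodal strength (or degree / normalized strength) at one model × density forms
a subjects × 68 predictor matrix. Age, sex, and age×sex are OLS-residualized
out of every node; the cognitive outcome is never residualized (assumed
already age-adjusted). Degree is implemented but, under exact equal-density
thresholding, barely varies across subjects (tie effects only) — flagged
here, retained for completeness.

PLS is univariate-response PLS1 via NIPALS deflation with standardized
predictors (documented, switchable via `scale=False`); one fit at c_max
yields nested coefficients for every smaller component count. Component
selection: per CV instance, a fresh seeded random 9-fold partition; for
c = 0…c_max (default c_max = 10, far below the 68-predictor rank limit)
out-of-fold predictions are pooled into a single Q²(c) = 1 − PRESS/TSS, with
TSS about the grand mean — the single-sum form of the formula, rather than
fold-averaged. c = 0 predicts each held-out fold with its training-fold mean,
making "retain zero components, build no model" a first-class outcome. The
retained count is the modal argmax over instances (ties to the smaller c).
The stratified variant discretizes the outcome into equal-count quartile bins
and builds each training set from equal-sized random per-bin samples (equal
count is the only construction feasible for every outcome distribution).
When a model is retained, predictor weights get BCa bootstrap intervals:
subjects resampled with replacement, each replicate's coefficient vector
sign-aligned to the point estimate by dot product, bias correction z₀ from
the bootstrap distribution and acceleration a from jackknife skewness; with
z₀ = a = 0 the interval reduces to the percentile interval (tested). The
executive-function summary is the first principal component of the three
subtests on the correlation scale, retained only if its eigenvalue exceeds 1
and all loadings share a sign (flipped positive); otherwise an error states
which rule failed.

## Synthetic cohort generator

The generator emulates the statistical structure the analyses assume — not
images, surfaces, or biological covariance, which real morphometry papers do
not characterize across modalities. Per cohort: a shared regional loading
matrix (68 × n_latent, default 6) times per-feature latent weights gives a
common structure, standardized per feature. Per subject: iid deviations
(subject_sd = 0.5) plus a per-modality regional noise component shared by all
features of that modality (SD 0.35 / 0.45 / 0.55 for T1w / T2w / DWI). The
shared-modality component is what makes dropping a modality remove
information, so the 10 > 8 > 7 similarity hierarchy is a property of the
generative model rather than an accident; the shared loading matrix produces
the high subject-to-group congruence regime. Features are then affinely
rescaled to raw units (GM ~10³, SA ~10², CT ~10⁰, curvatures ~10⁻¹,
MD ~10⁻³), the heterogeneity z-scoring must neutralize. All draws are
Gaussian, which reproduces the near-zero-centered, approximately normal MSN
edge distribution after z-scoring.

Retest sessions mix the subject's session-1 deviation with a fresh
structurally identical deviation as ρ·E₁ + √(1−ρ²)·E₂, giving every
(region, feature) cell an across-subject test-retest correlation of exactly
ρ in the population (default ρ = 0.85, a realistic reliability for
research-grade structural morphometry; recovered empirically to ±0.05 at
n = 500). Cognition is β times the standardized projection of each subject's
unthresholded nodal-strength profile onto a fixed random contrast (optionally
sparse, for signal-recovery studies) plus Gaussian noise; β = 0 makes
cognition independent of every network measure, the null regime. Age is
continuous uniform 22–36 (a numeric covariate is what confound regression
needs; age bins are a data-release artifact, not a method requirement); EF
subtests load 0.8 each on one latent factor, so their correlation matrix is
compound-symmetric with a first eigenvalue of 2.28.

What passing tests show — and do not. The generator reproduces the
*qualitative* regimes (model hierarchy, reliability monotonicity, strength
ordering, group congruence, PLS null and signal behavior) under known ground
truth; it does not claim biologically calibrated effect sizes, so numeric
similarity values on synthetic cohorts characterize the pipeline, not any
real population.

## Problem sizes and numerical choices

Analyses default to cohorts of 50–200 subjects at 68 regions, 100 (scripts)
or 25 (tests) CV instances, and a few hundred bootstrap replicates — sizes at
which every Monte-Carlo property asserted is stable across seeds. Degenerate
inputs raise informative errors rather than propagating: zero-variance
features or regions, constant outcomes (zero TSS), empty reference networks,
rank-deficient confound designs (e.g. single-sex cohorts), and fewer than
three usable element pairs in any correlation. All randomness flows from
explicit integer seeds; the pipeline splits its run seed into per-stage
sub-seeds with `numpy.random.SeedSequence(seed, spawn_key=(stage,))`, and
rerunning an identical config reproduces every output byte-for-byte.

## Known limitations

* MSN matrices are compared only at matched parcellation and ordering; no
  cross-atlas support.
* No graph metrics beyond strength/degree — MSN edges are similarities, not
  verified connections, so efficiency/clustering interpretations are
  deliberately avoided.
* ICC is not implemented; reliability is characterized by the edge-level
  statistics above.
* The wide (`aparcstats2table`) reader expects one measure per file with a
  consistent region-column convention per table.
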
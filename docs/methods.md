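# Methods

## The band-table model of gradients

The package's account of the horseshoe effect rests on one structural
model: along an environmental gradient, community tables are
(approximately) **band matrices**. Sort samples by gradient value and
features by niche optimum, and each sample's abundance concentrates in a
contiguous block of rows.

Two generators produce this structure.

**Idealized band table** (`band_table`). `n_samples` columns; column *j*
holds value `1/B` in rows `j·shift … j·shift + B − 1` and 0 elsewhere
(`B` = band size, default 10; shift default 1; defaults give a 39 × 30
table). The gradient is the sample index itself. This is the minimal,
noise-free object on which every saturation and ordination claim can be
verified in closed form: disjoint columns are Euclidean distance
`sqrt(2/B)` apart, adjacent columns `sqrt(2)/B`, and the earth-mover
distance between columns *i* and *j* over the row ordering is exactly
`|i − j|`.

**Gaussian-niche tables** (`niche_table`). Each feature *f* receives a
niche optimum μ_f drawn uniformly over the gradient range; the expected
count of *f* in sample *i* at gradient g_i is proportional to
`exp(−(g_i − μ_f)²/(2σ²))`, columns are scaled to an expected sequencing
depth, and counts are Poisson. Defaults: 50 samples evenly spaced on
(0, 10), 100 features, niche width σ = 1 gradient unit, depth 10⁴ counts
per sample. These were chosen as a plausible desk-scale cartoon of a
gradient survey (tens of samples, niche widths a modest fraction of the
gradient span, depths where Poisson noise is visible but not dominant).
The true optima are returned so parameter recovery can be measured; at the
defaults the mean-niche estimator recovers μ_f with RMSE ≈ 0.23 gradient
units (< σ/2).

What the generator deliberately does *not* emulate: overdispersion beyond
Poisson, taxon correlations, bimodal or skewed niche responses, uneven
sample spacing, and the long tail of very rare taxa in real surveys.
Tests passing on these tables therefore demonstrate the geometry of
saturation and its removal, not robustness to every property of real
sequencing data.

**Substitution saturation** (`substitution_saturation`). The sequence
analogue: under an equal-base-frequency substitution model two lineages
separated for time *t* at rate λ per site disagree at an expected fraction
`0.75·(1 − exp(−8λt/3))` of sites, plateauing at 0.75. (The plateau is
often quoted as "75% identity"; identity in fact saturates at 25% —
divergence at 75% — and the package computes divergence.) A Monte-Carlo
simulator of independent sites provides the stochastic cross-check.

## Distances

- **Euclidean** on sample columns; **chi-squared** is the CA-induced
  metric `d(i,j)² = Σ_k (P_ki/r_i − P_kj/r_j)²/c_k` with all-zero feature
  rows dropped (their mass `c_k = 0` makes the term undefined).
- **Unweighted UniFrac**: presence/absence; branch length present in
  exactly one sample over branch length present in at least one, computed
  by post-order aggregation of tip presence. The root's stem branch (when
  it has length) enters only when present in at least one of the pair,
  like any other branch. Bounded in [0, 1].
- **EMBAD**: requires explicit proportions (callers normalize with
  `to_proportions`; silent renormalization would hide the probability-mass
  interpretation) and an explicit `FeatureOrder` — the prior knowledge of
  the band ordering, in practice the niche-sorted feature order. Features
  sit at unit-spaced ranks; `d(i,j) = Σ_k |C_ik − C_jk|` on cumulative
  proportions, the 1-D Wasserstein-1 distance. A variant using real
  gradient positions per feature (`use_positions=True`) is provided; ranks
  are the default because they make the band-table identity `d = |i − j|`
  exact and are insensitive to gradient units.

**Saturation curves** list the distance from a reference sample to all
others in gradient order and estimate the plateau as the smallest rank
from which every later distance stays within a factor `1 − ε` of the
maximum. ε defaults to 0.01 because empirical curves (and UniFrac in
particular) approach their ceiling without exactly reaching it.

A finite-size caveat found while validating: on the idealized band table
the *chi-squared* curve is constant only over interior saturated ranks
(B … n − B). Features at the table's far edge occur in fewer samples, so
their small mass `c_k` inflates `1/c_k` and the distance rises again over
the last B ranks. Euclidean and star-tree UniFrac curves are exactly
constant everywhere beyond rank B.

## Niche estimation and sorting

`mean_niche_estimator` computes the abundance-weighted mean gradient per
feature, `ḡ_x = Σ_i g_i x_i / Σ_i x_i`, summing over samples. It is
scale-invariant per feature, always lies in the gradient's convex hull,
and is undefined for never-observed features — those are excluded and
reported rather than raised, and `niche_sort` appends them last in input
order. Sorting uses ascending gradient for samples and ascending ḡ_x for
features, with ties broken lexicographically by id so runs are
reproducible. Sorting is a pure permutation and is idempotent.

## Ordination

- **PCA**: column-centered SVD; coordinates `U·s`, eigenvalues
  `s²/(n−1)`.
- **PCoA**: eigendecomposition of the Gower-centered matrix
  `−½·J·D²·J`. Axes with negative eigenvalues are dropped and their
  magnitudes reported; no Cailliez/Lingoes correction is applied, since
  such corrections alter the distances whose behavior is the object of
  study. Explained proportions are taken over the positive eigenvalues.
- **CA**: SVD of standardized residuals
  `D_r^{−1/2}(P − r cᵀ)D_c^{−1/2}` with samples as rows; samples in
  principal coordinates, so full-dimension inter-sample distances equal
  chi-squared distances (verified to 1e-9 in the tests).
- Axis signs follow one convention everywhere: each axis is flipped so its
  largest-magnitude loading (PCA) or coordinate (PCoA/CA) is positive.
- Eigenvalues below 1e-10 of the spectral radius are treated as zero.

**Horseshoe diagnostics** (invented for testability; the literature
describes the shape but does not quantify it):

- *arch test*: fit `axis2 = a·axis1² + b·axis1 + c`; declare an arch when
  `|a|·range(axis1)²/range(axis2) > 0.5`, i.e. when the fitted parabola's
  rise is comparable to the observed axis-2 spread. The 0.5 threshold is a
  calibration choice; on the test suite's cases the statistic is ≈ 3 for
  genuine band-table arches and ≈ 0.2 for EMBAD embeddings, so the verdict
  is insensitive to the exact cutoff over a wide range.
- *sign test*: both gradient endpoints on one side of the axis-2 median
  and the gradient midpoint on the other.
- *single-axis gradient test*: |Spearman ρ| ≥ 0.99 between axis 1 and the
  gradient, with no arch — what a nonsaturating metric should achieve.

A finite-size observation: on the default 30-sample band table, PCA's
axis-1 rank correlation with the gradient is 0.87, not ≈ 1 — the
horseshoe's ends folding back caps rank monotonicity. The tests assert
the qualitative signature (sign test, arch, |ρ| ≥ 0.8) rather than a
near-perfect correlation.

## PERMANOVA and collinearity

One-way PERMANOVA uses Anderson's formulation:
`SS_total = Σ_{i<j} d²_ij/N`, `SS_within = Σ_g Σ_{i<j∈g} d²_ij/n_g`,
`pseudo-F = (SS_between/(a−1))/(SS_within/(N−a))`. Perfect separation
(`SS_within = 0`) returns +∞. The permutation p-value uses the +1/+1
convention; when the number of distinct relabelings is ≤ 10,000 the null
is enumerated exhaustively instead (p then includes the observed labeling
in both counts). Monte-Carlo permutations are seeded and bitwise
reproducible. Type-I error at nominal 0.05 on structureless data measures
0.06 over 200 replicates in the acceptance suite.

The collinearity bound `⌊2r/δ⌋ + 1` is the maximum number of points,
pairwise at least δ apart, that fit on a line inside a ball of radius r
(pigeonhole on a chord of length 2r). For the default band table,
δ = `sqrt(2)/10` (adjacent samples), r = `sqrt(2/10)` (the saturation
ball), bound = 7 < 30 samples — the gradient provably cannot be a straight
line in feature space. `is_collinear` checks the second singular value of
the centered coordinate matrix against a relative tolerance.

## Problem sizes and determinism

All simulations in the tests and acceptance script run at desk scale —
band tables up to 30 × 39, niche tables 50 × 100, 200 PERMANOVA replicates
of 20 samples with 199 permutations, 10,000 Monte-Carlo sites — sizes at
which every closed-form identity is still exact and the stochastic checks
have comfortable margins. Every stochastic component takes an explicit
seed (`numpy.random.default_rng`); hypothesis-based property tests run
derandomized.

## Known limitations

- EMBAD needs a feature ordering; with no gradient metadata (or a wrong
  ordering) it degrades to an arbitrary transport distance, and its
  nonsaturation guarantee applies to the ordering it was given. The
  ordering is estimated from the data (niche sort), so on very shallow or
  very noisy tables ordering error propagates into the metric.
- PERMANOVA is one-way only; no nested designs, no dispersion (PERMDISP)
  test, so a significant pseudo-F can still reflect dispersion
  differences.
- Chi-squared distance drops unobserved features; tables whose feature
  sets differ should be merged before comparison.
- The arch detector is a heuristic for a shape with no standard
  quantitative definition; treat its threshold as a diagnostic aid, not a
  hypothesis test.
- No distance correction analogous to Jukes–Cantor for community data is
  provided; EMBAD is the constructive alternative explored here.
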
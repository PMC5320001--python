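# horseshoe

Band tables, distance saturation, and the horseshoe effect in ecological
ordination.

## The problem

Ordination plots of microbiome surveys that span a strong environmental
gradient — soil pH, days of carcass decomposition, depth, season — very
often show the **horseshoe (Guttman) effect**: a perfectly linear gradient
appears as a curved, folded trajectory in the first two axes of PCA, PCoA,
or correspondence analysis. The usual reading is "dimensionality-reduction
artifact", and the usual remedy is detrending.

This package takes the other view: the horseshoe is a *property of the
distance metric*, and it carries ecological information. Taxa occupy
niches along the gradient, so a community table sorted by gradient and by
niche optimum is a **band table** — each sample occupies a contiguous block
of B features. Common dissimilarities (Euclidean, chi-squared, unweighted
UniFrac) **saturate** on such data: once two samples share no features the
distance stops growing, so all sufficiently distant pairs become
equidistant. A set of many mutually equidistant samples cannot lie on a
line (at most ⌊2r/δ⌋ + 1 points pairwise δ-separated fit on a chord of a
ball of radius r), so the gradient must bend — in the original
high-dimensional space, and therefore also in its low-dimensional shadow.

The package provides, for working through and testing this account:

- **simulators** — the idealized band table and a Gaussian-niche count
  generator with known optima (`band_table`, `niche_table`), plus the
  molecular-evolution analogue, where site divergence between two random
  sequences saturates at 75% (`substitution_saturation`);
- **distances** — Euclidean, chi-squared, unweighted UniFrac, and
  **EMBAD** (Earth Mover Band Aware Distance), a nonsaturating metric:
  the 1-D Wasserstein-1 distance between two samples' probability mass
  over a gradient-informed feature ordering,
  `d(i,j) = Σ_k |C_ik − C_jk|` on cumulative proportions `C`;
- **niche tools** — the abundance-weighted mean gradient per taxon
  `ḡ_x = Σ_i g_i x_i / Σ_i x_i` (`mean_niche_estimator`) and `niche_sort`,
  which re-reveals the band; the CLR transform
  `clr(x) = ln(x+1) − mean ln(x+1)` for depth-robust heat maps;
- **ordination** — PCA, PCoA (Gower double-centering, negative eigenvalues
  reported, never "corrected"), CA (SVD of standardized residuals), with
  arch/horseshoe diagnostics;
- **stats** — one-way PERMANOVA (Anderson's pseudo-F, permutation or
  exhaustive p), the collinearity bound, and a collinearity test;
- **workflows + CLI** — `run_band_demo` / `run_metric_comparison`, exposed
  as the `horseshoe` command (`simulate`, `niche-sort`, `distance`,
  `ordinate`, `permanova`, `demo-band`, `compare-metrics`).

## Worked example

`examples/distance_saturation.py` builds the 30-sample, band-size-10 table
and prints the distance from sample 0 to every other sample, in gradient
order:

```
theoretical saturation ball radius sqrt(2/B) = 0.4472
Euclidean plateau detected at gradient rank 10 (= band size 10)
EMBAD 'plateau' rank 29 (= last rank: the curve never stops growing)

rank   Euclidean   EMBAD
   1      0.1414      1.0
   5      0.3162      5.0
  10      0.4472     10.0
  20      0.4472     20.0
  29      0.4472     29.0
```

Euclidean distance grows until the bands stop overlapping (rank 10 = B)
and then freezes at √(2/B): sample 20 looks exactly as far from sample 0
as sample 10, although it is twice as far along the gradient. EMBAD keeps
the gradient metric structure (`d = |i − j|` exactly on the band table).

`examples/metric_comparison_permanova.py` runs the whole pipeline on a
simulated niche-gradient study (50 samples, 100 taxa, σ = 1, fixed seed)
and contrasts low- vs high-gradient sample groups:

```
metric     arch   |axis1 rho|  pseudo-F   p
euclidean  True   0.931        50.2       0.0010
chisq      True   1.000        47.9       0.0010
embad      False  1.000        888.1      0.0010
```

The saturating metrics show the arch; EMBAD lays the gradient on a single
axis and its PERMANOVA pseudo-F is an order of magnitude larger — the
between-group distances keep growing with gradient separation instead of
plateauing, so the same contrast registers as a far larger effect size.

The other examples (`band_table_horseshoe.py`, `niche_sorting.py`) show the
PCA horseshoe diagnostics and niche-optimum recovery (RMSE 0.23 gradient
units at sequencing depth 10⁴, i.e. well under σ/2).

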
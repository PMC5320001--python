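"""Compare saturating metrics with EMBAD on one synthetic gradient study.

Runs the full pipeline — niche-sort, distance matrices, PCoA, arch
diagnostics, and a PERMANOVA contrasting low- vs high-gradient samples —
for Euclidean, chi-squared, and EMBAD.  Saturating metrics show the arch
and a modest pseudo-F; EMBAD puts the gradient on axis 1 and yields a
far larger effect size, because between-group distances keep growing with
gradient separation instead of plateauing.
"""

import tempfile

import horseshoe as h

spec = h.NicheSpec(n_samples=50, n_features=100, sigma=1.0, depth=10_000, seed=0)
table, meta, _ = h.niche_table(spec)

out_dir = tempfile.mkdtemp(prefix="horseshoe_cmp_")
summary = h.run_metric_comparison(
    table, meta, out_dir, metrics=("euclidean", "chisq", "embad"),
    permutations=999, seed=0,
)

print(f"artifacts written to {out_dir}\n")
print(f"{'metric':<10} {'arch':<6} {'|axis1 rho|':<12} {'pseudo-F':<10} p")
for metric, row in summary["metrics"].items():
    print(f"{metric:<10} {str(row['arch_detected']):<6} "
          f"{abs(row['axis1_gradient_spearman']):<12.3f} "
          f"{row['pseudo_F']:<10.1f} {row['p_value']:.4f}")
# The pseudo-F gap (orders of magnitude) mirrors how a nonsaturating
# metric separates gradient extremes that saturating metrics see as
# merely "maximally distant".
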
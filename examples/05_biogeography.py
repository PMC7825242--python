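"""Alpha diversity and distance-decay of community similarity.

Richness and Shannon diversity per sample; then the slope of
ln(1 - Bray-Curtis) against ln(geographic distance) inside three spatial
windows — local (1-100 m), mesoscale (0.1-50 km), regional (100-3500 km).
"""

from methanocoexist import alpha_diversity, ddr_all_scales, simulate_dataset

ds = simulate_dataset(n_sites=6, samples_per_site=8, n_taxa=64, depth=2000,
                      n_common_pairs=8, endemic_pairs_per_site=2, seed=1)

alpha = alpha_diversity(ds.table)
print("alpha diversity (first 5 samples):")
print(alpha.head().to_string(float_format=lambda v: f"{v:.3f}"))
print(f"\nmean richness {alpha['richness'].mean():.1f}, "
      f"mean Shannon {alpha['shannon'].mean():.3f}")

print("\ndistance-decay relationships:")
for r in ddr_all_scales(ds.table, ds.metadata):
    if r.available:
        print(f"  {r.scale:9s} slope {r.slope:+.4f}  r2 {r.r_squared:.3f}  "
              f"({r.n_pairs} pairs)")
    else:
        print(f"  {r.scale:9s} unavailable ({r.n_pairs} pairs in window)")
print("\nA negative regional slope is the biogeographic signature:")
print("community similarity decays with distance because temperature")
print("filtering (and the planted endemic structure) differ across sites.")
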
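"""Partition community assembly into determinism vs stochasticity.

betaNTI compares each sample pair's abundance-weighted nearest-taxon
distance (betaMNTD) with a taxa-label-shuffling null; |z| beyond 2 reads
as deterministic assembly (environmental selection), values between -2
and 2 as stochastic.  Under temperature-filtered synthesis the commonly
coexisting taxa assemble more deterministically than the endemic ones;
under neutral synthesis every group is stochastic.
"""

from methanocoexist import PipelineConfig, group_assembly, simulate_dataset
from methanocoexist.classify import CoexistenceGroups, EdgeFrequency


def truth_groups(truth):
    g = CoexistenceGroups()
    g.edges["always_common"] = [
        EdgeFrequency(p, 6, [f"S{i}" for i in range(6)])
        for p in truth.common_pairs]
    g.edges["always_endemic"] = [
        EdgeFrequency(p, 1, [s])
        for s, ps in truth.endemic_pairs.items() for p in ps]
    return g


for label, kwargs in (
    ("temperature-filtered", dict(common_breadth=2.0, endemic_breadth=40.0,
                                  common_span="guilds", trait_signal=2.0)),
    ("neutral (drift-like)", dict(trait_signal=0.0, niche_breadth=50.0,
                                  pair_weight=0.0, module_weight=0.0,
                                  baseline_sd=0.0, noise_sd=1.5)),
):
    ds = simulate_dataset(n_sites=6, samples_per_site=8, n_taxa=64,
                          depth=800, n_common_pairs=10,
                          endemic_pairs_per_site=2, n_modules=0,
                          seed=1, **kwargs)
    res = group_assembly(ds.table, ds.phylogeny, truth_groups(ds.truth),
                         PipelineConfig(seed=1, n_null_phylo=499),
                         max_pairs=400)
    print(f"{label} synthesis:")
    for g in ("always_common", "always_endemic"):
        r = res[g]
        print(f"  {g:16s} determinism {r.fraction_determinism:5.1f}%  "
              f"stochasticity {r.fraction_stochasticity:5.1f}%  "
              f"({r.n_pairs} sample pairs)")
    print()
print("Selection on shared thermal niches pushes |betaNTI| beyond 2 for the")
print("common group; with no niche structure both groups stay within +-2.")
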
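"""Synthetic multi-site communities with known coexistence ground truth.

The generator emulates the statistical structure the downstream analysis
assumes about continental-scale paddy-soil methanogen data:

* a pure-birth (Yule) phylogeny over the OTU pool;
* sites spread over a latitudinal box with mean annual temperature (MAT)
  linear in latitude, 11-sample plots jittered within ~100 m;
* Gaussian niche filtering in log-abundance space — each OTU has a thermal
  optimum (evolving by Brownian motion on the tree, so communities carry
  phylogenetic signal) and a shared niche breadth;
* planted pairwise coexistence: designated OTU pairs share a latent
  log-normal factor either at every site (cross-site common links) or at a
  single site (endemic links), injected *before* multinomial sampling so
  the signal must survive compositional closure exactly as real
  associations must;
* a CH4 response built from per-site network complexity, diversity and MAT
  with known coefficients, and GeoChip-style functional-gene signals built
  from keystone abundances.

Every random draw flows from an explicit seed, and everything planted is
recorded in :class:`SyntheticTruth` so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .containers import CommunityTable, Phylogeny

__all__ = [
    "SyntheticTruth", "SimulatedDataset",
    "generate_phylogeny", "generate_metadata", "generate_communities",
    "generate_ch4", "generate_gene_signals", "simulate_dataset",
    "DEFAULT_CH4_COEFFICIENTS",
]

#: CH4 model: beta0, beta_network, beta_diversity, beta_mat, noise sd.
#: Network complexity dominates the realized variance (the network index is
#: roughly unit-scale, MAT spans ~22 degC, site-mean Shannon varies by a few
#: tenths), mirroring the predictor structure the analysis is meant to
#: recover: interactions first, then climate, then diversity.
DEFAULT_CH4_COEFFICIENTS = {
    "beta0": 10.0,
    "beta_network": 3.0,
    "beta_diversity": 1.5,
    "beta_mat": 0.2,
    "noise_sd": 1.0,
}


@dataclass
class SyntheticTruth:
    """Planted parameters of one synthetic dataset."""

    common_pairs: list = field(default_factory=list)
    endemic_pairs: dict = field(default_factory=dict)  # site -> list of pairs
    modules: list = field(default_factory=list)        # consortium OTU groups
    niche_optima: dict = field(default_factory=dict)   # OTU -> optimal MAT, degC
    niche_breadths: dict = field(default_factory=dict) # per-OTU sigma overrides
    baselines: dict = field(default_factory=dict)      # OTU -> log-abundance intercept
    baseline_sd: float = 1.5           # spread of background intercepts
    niche_breadth: float = 6.0                          # sigma, degC
    trait_signal: float = 1.0          # Brownian-motion variance on the tree
    abundance_noise_sd: float = 0.5    # lognormal noise in log space
    pair_weight: float = 1.5           # latent shared-factor loading
    module_weight: float = 1.2         # consortium shared-factor loading
    ch4_coefficients: dict = field(default_factory=lambda: dict(DEFAULT_CH4_COEFFICIENTS))
    degenerate_mat: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.common_pairs = [tuple(sorted(p)) for p in self.common_pairs]
        self.endemic_pairs = {
            s: [tuple(sorted(p)) for p in ps] for s, ps in self.endemic_pairs.items()
        }
        common = set(self.common_pairs)
        for site, pairs in self.endemic_pairs.items():
            clash = common & set(pairs)
            if clash:
                raise ValueError(f"pairs planted both common and endemic: {clash}")
        for a, b in self.all_planted_pairs():
            if a == b:
                raise ValueError("a planted pair cannot be a self-pair")
        if self.niche_breadth <= 0:
            raise ValueError("niche breadth sigma must be positive")

    def all_planted_pairs(self) -> list:
        out = list(self.common_pairs)
        for pairs in self.endemic_pairs.values():
            out.extend(pairs)
        return out

    def to_dict(self) -> dict:
        return {
            "common_pairs": [list(p) for p in self.common_pairs],
            "endemic_pairs": {s: [list(p) for p in ps]
                              for s, ps in self.endemic_pairs.items()},
            "modules": [list(m) for m in self.modules],
            "niche_optima": dict(self.niche_optima),
            "niche_breadths": dict(self.niche_breadths),
            "baselines": dict(self.baselines),
            "baseline_sd": self.baseline_sd,
            "niche_breadth": self.niche_breadth,
            "trait_signal": self.trait_signal,
            "abundance_noise_sd": self.abundance_noise_sd,
            "pair_weight": self.pair_weight,
            "module_weight": self.module_weight,
            "ch4_coefficients": dict(self.ch4_coefficients),
            "degenerate_mat": self.degenerate_mat,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(**d)


@dataclass
class SimulatedDataset:
    table: CommunityTable
    metadata: pd.DataFrame
    phylogeny: Phylogeny
    truth: SyntheticTruth


# ----------------------------------------------------------------------
# phylogeny
# ----------------------------------------------------------------------


def generate_phylogeny(n_taxa: int, birth_rate: float = 1.0,
                       seed: int = 0) -> Phylogeny:
    """Simulate an ultrametric pure-birth (Yule) tree.

    Lineages split at rate ``birth_rate`` each; the simulation stops at the
    n-th speciation and all extant branches are extended by one further
    exponential waiting time so that every tip sits at the same age.
    Tips are labeled OTU_1..OTU_n in birth order.
    """
    if n_taxa < 3:
        raise ValueError("a phylogeny needs at least 3 taxa")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)

    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    root = tree.seed_node
    birth_time = {root: 0.0}
    active = [root]
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        parent = active.pop(int(rng.integers(len(active))))
        for _ in range(2):
            child = dendropy.Node()
            parent.add_child(child)
            birth_time[child] = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / (birth_rate * len(active)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxon_ns.new_taxon(label=f"OTU_{i}")
    for node in tree.preorder_node_iter():
        if node is root:
            node.edge.length = None
            continue
        end = t_end if node.is_leaf() else min(
            birth_time[c] for c in node.child_nodes())
        node.edge.length = max(end - birth_time[node], 1e-9)
    return Phylogeny(tree)


# ----------------------------------------------------------------------
# sites and climate
# ----------------------------------------------------------------------

def _disjoint_clades(phylo: Phylogeny, available: set,
                     min_size: int = 4, max_size: int = 8) -> list:
    """Disjoint clades (postorder-greedy) whose tips are all available."""
    clades, used = [], set()
    for node in phylo.tree.postorder_internal_node_iter():
        tips = [l.taxon.label for l in node.leaf_iter()]
        if not (min_size <= len(tips) <= max_size):
            continue
        if any(t in used or t not in available for t in tips):
            continue
        clades.append(sorted(tips))
        used.update(tips)
    return clades


#: default sampling frame: the latitudinal/longitudinal box of a
#: continental rice-paddy transect (about 19.5-47 degN, 110-126.5 degE)
DEFAULT_GEO_BOX = ((19.5, 47.0), (110.0, 126.5))

#: within-plot jitter: samples sit inside a 100 m x 100 m plot
_PLOT_JITTER_DEG = 0.00045  # ~50 m of latitude


def generate_metadata(n_sites: int, samples_per_site: int,
                      mat_range: tuple[float, float] = (1.5, 23.8),
                      geo_box: tuple = DEFAULT_GEO_BOX,
                      seed: int = 0) -> pd.DataFrame:
    """Site-structured sample metadata.

    Site centers are uniform in ``geo_box``; MAT is linear in latitude,
    spanning ``mat_range`` from the warm southern edge to the cold
    northern edge, and constant within a site (climate covariates are
    site-level).  The 11-sample-style plots jitter coordinates by at most
    ~100 m around the center.  MAP and a few soil variables are drawn at
    site level as plausible covariates.
    """
    if n_sites < 2 or samples_per_site < 2:
        raise ValueError("need at least 2 sites and 2 samples per site")
    rng = np.random.default_rng(seed)
    (lat_lo, lat_hi), (lon_lo, lon_hi) = geo_box
    mat_lo, mat_hi = mat_range
    lats = rng.uniform(lat_lo, lat_hi, n_sites)
    lons = rng.uniform(lon_lo, lon_hi, n_sites)
    if lat_hi > lat_lo:
        mats = mat_hi - (lats - lat_lo) / (lat_hi - lat_lo) * (mat_hi - mat_lo)
    else:
        mats = np.full(n_sites, mat_lo)
    maps_mm = 400.0 + 60.0 * mats + rng.normal(0, 50, n_sites)
    ph = rng.uniform(5.0, 8.0, n_sites)
    toc = rng.uniform(5.0, 30.0, n_sites)
    tn = rng.uniform(0.5, 3.0, n_sites)
    tp = rng.uniform(0.3, 1.5, n_sites)
    rows = []
    for s in range(n_sites):
        site = f"S{s + 1:02d}"
        for k in range(samples_per_site):
            rows.append({
                "sample_id": f"{site}_{k + 1:02d}",
                "site_id": site,
                "latitude": lats[s] + rng.uniform(-_PLOT_JITTER_DEG,
                                                  _PLOT_JITTER_DEG),
                "longitude": lons[s] + rng.uniform(-_PLOT_JITTER_DEG,
                                                   _PLOT_JITTER_DEG),
                "mat": mats[s],
                "map": maps_mm[s],
                "pH": ph[s],
                "TOC": toc[s],
                "TN": tn[s],
                "TP": tp[s],
                "ch4_potential": np.nan,
            })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# communities
# ----------------------------------------------------------------------


def _brownian_optima(phylo: Phylogeny, trait_signal: float,
                     mat_range: tuple[float, float],
                     rng: np.random.Generator) -> dict:
    """Thermal optima by Brownian motion on the tree, mapped into MAT range.

    The BM realisation is standardized in shape (so the tree's covariance
    structure is preserved) and given an amplitude proportional to
    sqrt(trait_signal): at trait_signal = 1 the tip optima have standard
    deviation of a quarter of the MAT range (spanning it comfortably),
    larger signals spread and clip at the range bounds, and
    trait_signal -> 0 collapses every optimum to the mid-range value —
    no differential filtering, the neutral limit.  Keeping the amplitude
    tied to trait_signal is what makes the niche-determinism dial
    monotone; a fixed rescale to the range would cancel the parameter.
    """
    lo, hi = mat_range
    mid = (lo + hi) / 2.0
    tips = phylo.tip_labels
    if trait_signal <= 0:
        return {t: mid for t in tips}
    value = {phylo.tree.seed_node: 0.0}
    for node in phylo.tree.preorder_node_iter():
        if node is phylo.tree.seed_node:
            continue
        parent_val = value[node.parent_node]
        step = rng.normal(0.0, np.sqrt(node.edge.length))
        value[node] = parent_val + step
    raw = {leaf.taxon.label: value[leaf] for leaf in phylo.tree.leaf_node_iter()}
    vals = np.array(list(raw.values()))
    sd = vals.std()
    if sd == 0:
        return {t: mid for t in raw}
    amp = np.sqrt(trait_signal) * (hi - lo) / 4.0
    return {t: float(np.clip(mid + (v - vals.mean()) / sd * amp, lo, hi))
            for t, v in raw.items()}


def generate_communities(phylogeny: Phylogeny | None, metadata: pd.DataFrame,
                         truth: SyntheticTruth, depth: int = 5000,
                         seed: int | None = None) -> CommunityTable:
    """Multinomial community counts under niche filtering + planted pairs.

    Expected log-abundance of OTU i in sample j is
    ``-(MAT_j - o_i)^2 / (2 sigma^2)`` plus lognormal noise; each planted
    pair additionally shares a per-sample latent factor (loading
    ``truth.pair_weight``) at its designated sites, which induces positive
    within-site correlation.  Counts are multinomial per sample at the
    given depth, so each sample column sums exactly to ``depth``.

    If ``truth.niche_optima`` is empty, optima are first evolved on the
    phylogeny (Brownian motion with variance ``truth.trait_signal``) and
    recorded into the truth object.
    """
    if depth < 1:
        raise ValueError("sequencing depth must be positive")
    import warnings
    if depth < 100:
        warnings.warn("depth < 100: planted correlations are unlikely to be "
                      "recoverable", stacklevel=2)
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    mats = metadata["mat"].to_numpy(dtype=float)
    sites = metadata["site_id"].tolist()
    sample_ids = metadata["sample_id"].tolist()

    if not truth.niche_optima:
        if phylogeny is None:
            raise ValueError("need a phylogeny or explicit niche optima")
        lo, hi = float(mats.min()), float(mats.max())
        if lo == hi:
            truth.degenerate_mat = True
            hi = lo + 1.0
        truth.niche_optima = _brownian_optima(
            phylogeny, truth.trait_signal, (lo, hi), rng)
    otus = (phylogeny.tip_labels if phylogeny is not None
            else sorted(truth.niche_optima))
    missing = [o for p in truth.all_planted_pairs() for o in p if o not in set(otus)]
    if missing:
        raise ValueError(f"planted pair members outside OTU pool: {sorted(set(missing))}")

    if not truth.baselines:
        # stable background dominants: per-OTU log-abundance intercepts
        draws = rng.normal(0.0, truth.baseline_sd, len(otus))
        truth.baselines = {o: float(v) for o, v in zip(otus, draws)}
        # planted taxa stay minor community members so their latent-factor
        # swings cannot shake the compositional denominator
        planted = {o for p in truth.all_planted_pairs() for o in p}
        planted |= {o for m in truth.modules for o in m}
        for o in planted:
            truth.baselines[o] = -1.0

    opt = np.array([truth.niche_optima[o] for o in otus])
    base = np.array([truth.baselines[o] for o in otus])
    sigma = np.array([truth.niche_breadths.get(o, truth.niche_breadth)
                      for o in otus])
    n_o, n_s = len(otus), len(sample_ids)
    log_abund = base[:, None] - ((mats[None, :] - opt[:, None]) ** 2) / (
        2 * sigma[:, None] ** 2)
    if truth.abundance_noise_sd > 0:
        log_abund = log_abund + rng.normal(0, truth.abundance_noise_sd,
                                           size=(n_o, n_s))
    pos = {o: i for i, o in enumerate(otus)}
    w = truth.pair_weight
    site_arr = np.array(sites)
    for members in truth.modules:
        factor = rng.normal(0, 1, n_s)
        for m in members:
            log_abund[pos[m]] += truth.module_weight * factor
    for a, b in truth.common_pairs:
        factor = rng.normal(0, 1, n_s)
        log_abund[pos[a]] += w * factor
        log_abund[pos[b]] += w * factor
    for site, pairs in truth.endemic_pairs.items():
        mask = site_arr == site
        for a, b in pairs:
            factor = rng.normal(0, 1, int(mask.sum()))
            log_abund[pos[a], mask] += w * factor
            log_abund[pos[b], mask] += w * factor

    weights = np.exp(log_abund - log_abund.max(axis=0, keepdims=True))
    probs = weights / weights.sum(axis=0, keepdims=True)
    counts = np.empty((n_o, n_s), dtype=float)
    for j in range(n_s):
        counts[:, j] = rng.multinomial(depth, probs[:, j])
    return CommunityTable(otus, sample_ids, counts)


# ----------------------------------------------------------------------
# CH4 response and gene signals
# ----------------------------------------------------------------------


def generate_ch4(metadata: pd.DataFrame, network_index_by_site: dict,
                 diversity_by_site: dict, truth: SyntheticTruth,
                 seed: int | None = None) -> pd.DataFrame:
    """Per-site CH4 production from network complexity, diversity and MAT.

    ch4_s = beta0 + beta_network * x_net_s + beta_diversity * x_div_s
    + beta_mat * MAT_s + Normal(0, sd); the site value is written into
    every sample row's ``ch4_potential`` column of a copy of the metadata.
    """
    c = truth.ch4_coefficients
    for key in ("beta0", "beta_network", "beta_diversity", "beta_mat", "noise_sd"):
        if not np.isfinite(c[key]):
            raise ValueError(f"non-finite CH4 coefficient {key}")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    meta = metadata.copy()
    site_mat = meta.groupby("site_id")["mat"].first()
    values = {}
    for site, mat in site_mat.items():
        values[site] = (
            c["beta0"]
            + c["beta_network"] * float(network_index_by_site[site])
            + c["beta_diversity"] * float(diversity_by_site[site])
            + c["beta_mat"] * float(mat)
            + (rng.normal(0, c["noise_sd"]) if c["noise_sd"] > 0 else 0.0)
        )
    meta["ch4_potential"] = meta["site_id"].map(values)
    return meta


def generate_gene_signals(community: CommunityTable, keystones: list,
                          genes: list, weights: np.ndarray | None = None,
                          noise_sd: float = 0.05, seed: int = 0):
    """GeoChip-style gene signals driven by keystone OTU abundances.

    Each gene probe's per-sample signal is a nonnegative linear
    combination of the keystones' relative abundances plus Gaussian noise,
    clamped at zero.  ``weights`` is (n_genes x n_keystones); by default
    each gene loads on a random subset of keystones.
    """
    from .contribution import GeneTable

    if not genes:
        raise ValueError("gene list must not be empty")
    missing = sorted(set(keystones) - set(community.otu_ids))
    if missing:
        raise ValueError(f"keystones absent from community: {missing}")
    rng = np.random.default_rng(seed)
    rel = community.to_relative()
    k_idx = [rel.otu_ids.index(k) for k in keystones]
    k_rel = rel.counts[k_idx, :]  # keystones x samples
    if weights is None:
        weights = rng.uniform(0, 1, size=(len(genes), len(keystones)))
        weights *= rng.random(weights.shape) < 0.5  # sparse loadings
        # every gene loads on at least one keystone
        for g in range(len(genes)):
            if not weights[g].any():
                weights[g, rng.integers(len(keystones))] = 1.0
    weights = np.asarray(weights, dtype=float)
    signal = weights @ k_rel
    if noise_sd > 0:
        signal = signal + rng.normal(0, noise_sd, size=signal.shape)
    signal = np.clip(signal, 0.0, None)
    return GeneTable(
        probe_ids=[f"probe_{i + 1}_{g}" for i, g in enumerate(genes)],
        genes=list(genes),
        sample_ids=list(rel.sample_ids),
        signals=signal,
    )


# ----------------------------------------------------------------------
# one-call dataset
# ----------------------------------------------------------------------


def simulate_dataset(n_sites: int = 39, samples_per_site: int = 11,
                     n_taxa: int = 300, depth: int = 5000,
                     n_common_pairs: int = 15, endemic_pairs_per_site: int = 3,
                     n_modules: int = 4, module_size: int = 5,
                     mat_range: tuple[float, float] = (1.5, 23.8),
                     geo_box: tuple = DEFAULT_GEO_BOX,
                     niche_breadth: float = 6.0, trait_signal: float = 1.0,
                     noise_sd: float = 0.5, pair_weight: float = 1.5,
                     module_weight: float = 1.2,
                     common_breadth: float | None = None,
                     endemic_breadth: float | None = None,
                     common_span: str = "mid", baseline_sd: float = 1.5,
                     ch4_coefficients: dict | None = None,
                     birth_rate: float = 1.0, seed: int = 0) -> SimulatedDataset:
    """Generate a complete synthetic dataset with planted ground truth.

    The default scale mirrors the study design (39 sites x 11 samples);
    the OTUs backing the planted common pairs get mid-range thermal optima
    (broadly distributed taxa) while endemic-pair members are centred on
    their own site's MAT (locally filtered taxa), which is what makes the
    common/endemic distinction ecologically meaningful rather than a pure
    sampling artifact.  Beyond the focal pairs, ``n_modules`` consortium
    modules of ``module_size`` OTUs each share a global latent factor:
    real co-occurrence networks contain tens to hundreds of supported
    edges per site, and that bulk of genuine associations is what gives
    the multiple-testing step a realistic operating point.
    """
    rng = np.random.default_rng(seed)
    phylo = generate_phylogeny(n_taxa, birth_rate, seed=int(rng.integers(2**31 - 1)))
    meta = generate_metadata(n_sites, samples_per_site, mat_range, geo_box,
                             seed=int(rng.integers(2**31 - 1)))
    if 2 * (n_common_pairs + endemic_pairs_per_site * n_sites) \
            + n_modules * module_size > n_taxa:
        raise ValueError("not enough OTUs for the requested planted structure")
    lo, hi = mat_range
    mid = (lo + hi) / 2
    optima = _brownian_optima(phylo, trait_signal, mat_range,
                              np.random.default_rng(int(rng.integers(2**31 - 1))))

    # planted structure is selected conditional on the evolved traits (never
    # overriding them) so the phylogeny-trait association that the assembly
    # null models detect stays intact; ties are broken randomly because tip
    # labels follow tree traversal order and a lexicographic tie-break would
    # silently pick clades
    available = set(phylo.tip_labels)
    tie = {o: float(r) for o, r in
           zip(phylo.tip_labels, rng.random(len(phylo.tip_labels)))}

    def take_closest(target: float, k: int) -> list:
        picks = sorted(available,
                       key=lambda o: (abs(optima[o] - target), tie[o]))[:k]
        available.difference_update(picks)
        return sorted(picks, key=lambda o: (optima[o], tie[o]))

    def adjacent_pairs(tips: list) -> list:
        return [tuple(sorted((tips[2 * i], tips[2 * i + 1])))
                for i in range(len(tips) // 2)]

    if common_span == "mid":
        # broadly distributed partners: optima near the gradient centre
        common_tips = take_closest(mid, 2 * n_common_pairs)
    elif common_span == "guilds":
        # thermal guilds spread over the whole gradient, each guild a true
        # clade of the phylogeny (keystone families in the field are
        # lineages with distinct temperature optima).  Clades of 4-8 tips
        # are collected disjointly, ranked by their mean optimum, and
        # picked evenly across that ranking; each guild contributes
        # optima-adjacent pairs.
        n_guilds = max(1, n_common_pairs // 2)
        clades = _disjoint_clades(phylo, available, min_size=4, max_size=8)
        if len(clades) < n_guilds:
            raise ValueError("tree does not contain enough disjoint clades "
                             "for the requested guild structure")
        clades.sort(key=lambda c: np.mean([optima[o] for o in c]))
        chosen = [clades[i] for i in
                  np.linspace(0, len(clades) - 1, n_guilds).astype(int)]
        common_tips = []
        for clade in chosen:
            members = sorted(clade, key=lambda o: (optima[o], o))[:4]
            common_tips.extend(members)
            available.difference_update(members)
        common_tips = common_tips[: 2 * n_common_pairs]
    else:
        raise ValueError("common_span must be 'mid' or 'guilds'")
    common_pairs = adjacent_pairs(common_tips)
    site_mat = meta.groupby("site_id")["mat"].first().to_dict()
    endemic = {}
    for site in sorted(site_mat):
        endemic[site] = adjacent_pairs(
            take_closest(site_mat[site], 2 * endemic_pairs_per_site))
    modules = [take_closest(mid, module_size) for _ in range(n_modules)]

    truth = SyntheticTruth(
        common_pairs=common_pairs, endemic_pairs=endemic, modules=modules,
        niche_optima=dict(optima),
        niche_breadth=niche_breadth, trait_signal=trait_signal,
        abundance_noise_sd=noise_sd, pair_weight=pair_weight,
        module_weight=module_weight, baseline_sd=baseline_sd,
        ch4_coefficients=dict(ch4_coefficients or DEFAULT_CH4_COEFFICIENTS),
        degenerate_mat=(mat_range[0] == mat_range[1]),
        seed=int(rng.integers(2**31 - 1)),
    )
    for a, b in common_pairs:
        if common_breadth is not None:
            truth.niche_breadths[a] = truth.niche_breadths[b] = common_breadth
    for pairs in endemic.values():
        for a, b in pairs:
            if endemic_breadth is not None:
                truth.niche_breadths[a] = truth.niche_breadths[b] = endemic_breadth
    table = generate_communities(phylo, meta, truth, depth=depth)
    return SimulatedDataset(table=table, metadata=meta, phylogeny=phylo,
                            truth=truth)
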
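"""Linking coexistence structure and function to CH4 emission.

Random-forest contribution analysis (permutation importance as mean MSE
increase, response-permutation significance, normalized percentage
contributions), GeoChip-style functional-gene preprocessing, the
keystone-gene functional co-occurrence network with category-wise
edge-weight sums, and the regression of species-gene linkage weight on
CH4 emission.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .config import PipelineConfig
from .containers import CommunityTable

logger = logging.getLogger(__name__)

__all__ = [
    "GeneTable", "ContributionResult",
    "geochip_preprocess", "rf_importance", "importance_to_contribution",
    "group_abundance_features", "functional_network", "weight_ch4_regression",
]


@dataclass
class GeneTable:
    """Probe x sample functional-gene signal matrix (GeoChip-style)."""

    probe_ids: list
    genes: list
    sample_ids: list
    signals: np.ndarray
    snr: np.ndarray | None = None
    preprocessed: bool = False

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("duplicate probe ids")
        if self.signals.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError("signal matrix shape does not match ids")
        if len(self.genes) != len(self.probe_ids):
            raise ValueError("need one gene label per probe")
        if self.preprocessed and np.any(self.signals < 0):
            raise ValueError("preprocessed signals must be nonnegative")
        if self.snr is not None:
            self.snr = np.asarray(self.snr, dtype=float)
            if self.snr.shape != self.signals.shape:
                raise ValueError("SNR matrix must match the signal matrix")

    def subset_probes(self, keep: np.ndarray) -> "GeneTable":
        return GeneTable(
            [p for p, k in zip(self.probe_ids, keep) if k],
            [g for g, k in zip(self.genes, keep) if k],
            list(self.sample_ids),
            self.signals[keep, :],
            self.snr[keep, :] if self.snr is not None else None,
            self.preprocessed,
        )


def geochip_preprocess(raw: GeneTable, site_map: dict,
                       snr_min: float = 2.0, detection_min: int = 2,
                       constant: float = 1e6) -> GeneTable:
    """Standard GeoChip cleanup and normalization.

    (i) spots with signal-to-noise ratio below ``snr_min`` are zeroed
    (poor quality); (ii) per sample, each signal is divided by the
    sample's total detected intensity, multiplied by ``constant`` and
    natural-log transformed as ln(1 + x); (iii) within each site's
    replicate set, probes detected in at most ``detection_min`` samples
    are treated as not detected there, and probes left undetected
    everywhere are dropped.

    Applying the function twice with the same thresholds removes nothing
    further: the normalization step is skipped for an already
    ``preprocessed`` table.
    """
    signals = raw.signals.copy()
    if raw.snr is not None:
        signals[raw.snr < snr_min] = 0.0
    if not raw.preprocessed:
        totals = signals.sum(axis=0)
        if np.any(totals <= 0):
            j = int(np.flatnonzero(totals <= 0)[0])
            raise ValueError(
                f"sample {raw.sample_ids[j]!r} has zero total detected intensity")
        signals = np.log1p(signals / totals * constant)
    site_ids = [site_map[s] for s in raw.sample_ids]
    for site in sorted(set(site_ids)):
        cols = np.array([i for i, s in enumerate(site_ids) if s == site])
        detected = (signals[:, cols] > 0).sum(axis=1)
        weak = detected <= detection_min
        if weak.any():
            signals[np.ix_(weak, cols)] = 0.0
    keep = (signals > 0).any(axis=1)
    if not keep.all():
        logger.info("geochip_preprocess: dropped %d undetected probes",
                    int((~keep).sum()))
    out = GeneTable(raw.probe_ids, raw.genes, list(raw.sample_ids), signals,
                    raw.snr, preprocessed=True)
    return out.subset_probes(keep)


@dataclass
class ContributionResult:
    """Random-forest importance of CH4 predictors."""

    predictors: list
    importance: dict              # permutation importance, MSE-increase scale
    p_values: dict                # response-permutation significance
    var_explained_pct: float      # out-of-bag R^2, percent
    contributions: dict = field(default_factory=dict)


def rf_importance(X: pd.DataFrame, y, n_trees: int = 500, seed: int = 0,
                  n_perm_sig: int = 100) -> ContributionResult:
    """Random-forest regression importance of each predictor.

    Importance is permutation importance: the mean increase in MSE when
    one predictor's values are shuffled with everything else fixed.
    Significance comes from ``n_perm_sig`` refits on response-permuted
    data: a predictor's p-value is the rank of its observed importance
    within the null importances.  Model fit is reported as out-of-bag
    variance explained (%).  Predictors are standardized first.
    """
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=float)
    if len(X) < 10:
        raise ValueError("random forest contribution needs >= 10 observations")
    if np.std(y) == 0:
        raise ValueError("response is constant")
    std = X.std(axis=0, ddof=0).replace(0, 1.0)
    Xz = ((X - X.mean(axis=0)) / std).to_numpy()
    rng = np.random.default_rng(seed)
    n, p = Xz.shape
    n_repeats = 10

    def _perm_importance(rf, target, prng):
        """Mean MSE increase per shuffled predictor, one stacked predict."""
        stack = np.tile(Xz, (p * n_repeats + 1, 1))
        for j in range(p):
            for r in range(n_repeats):
                block = (j * n_repeats + r) * n
                stack[block: block + n, j] = Xz[prng.permutation(n), j]
        pred = rf.predict(stack)
        base_mse = np.mean((pred[-n:] - target) ** 2)
        mse = ((pred[: p * n_repeats * n].reshape(p, n_repeats, n)
                - target) ** 2).mean(axis=2)
        return mse.mean(axis=1) - base_mse

    def _fit_importance(target, rf_seed, oob):
        rf = RandomForestRegressor(n_estimators=n_trees, random_state=rf_seed,
                                   oob_score=oob, bootstrap=True, n_jobs=1)
        rf.fit(Xz, target)
        imp = _perm_importance(rf, target,
                               np.random.default_rng(rf_seed))
        return rf, imp

    rf, obs_imp = _fit_importance(y, int(rng.integers(2**31 - 1)), True)
    null_imp = np.empty((n_perm_sig, p))
    for b in range(n_perm_sig):
        y_perm = rng.permutation(y)
        _, null_imp[b] = _fit_importance(y_perm, int(rng.integers(2**31 - 1)),
                                         False)
    p = (1.0 + (null_imp >= obs_imp[None, :]).sum(axis=0)) / (n_perm_sig + 1.0)
    return ContributionResult(
        predictors=list(X.columns),
        importance=dict(zip(X.columns, obs_imp.tolist())),
        p_values=dict(zip(X.columns, p.tolist())),
        var_explained_pct=float(rf.oob_score_ * 100.0),
    )


def importance_to_contribution(result: ContributionResult,
                               subset: list | None = None) -> dict:
    """Normalize importances to percentage contributions over a subset.

    Negative importances (sampling noise) are clipped to zero before
    normalizing; the returned percentages sum to 100 exactly.
    """
    subset = list(subset) if subset is not None else list(result.predictors)
    missing = [s for s in subset if s not in result.importance]
    if missing:
        raise KeyError(f"predictors not in result: {missing}")
    vals = np.array([result.importance[s] for s in subset], dtype=float)
    if (vals < 0).any():
        logger.info("importance_to_contribution: clipping %d negative importances",
                    int((vals < 0).sum()))
        vals = np.clip(vals, 0.0, None)
    total = vals.sum()
    if total <= 0:
        raise ValueError("all importances are zero after clipping")
    contrib = dict(zip(subset, (100.0 * vals / total).tolist()))
    result.contributions = contrib
    return contrib


def group_abundance_features(table: CommunityTable, groups) -> pd.DataFrame:
    """Per-sample summed relative abundance of each coexistence group.

    The feature encoding behind the group-contribution model: each group
    contributes one predictor, the total relative abundance of its
    related OTUs in each sample.
    """
    from .classify import GROUP_NAMES

    rel = table.to_relative()
    frame = {}
    table_otus = set(rel.otu_ids)
    for g in GROUP_NAMES:
        otus = sorted(groups.related_otus(g) & table_otus)
        if otus:
            sub = rel.subset_otus(otus)
            frame[g] = sub.counts.sum(axis=0)
        else:
            frame[g] = np.zeros(rel.n_samples)
    return pd.DataFrame(frame, index=pd.Index(rel.sample_ids, name="sample_id"))


def functional_network(keystone_table: CommunityTable, gene_table: GeneTable,
                       config: PipelineConfig | None = None,
                       rng=None):
    """Co-occurrence network over keystone OTUs and functional-gene probes.

    Keystone abundances and gene signals over the shared samples are
    stacked into one composite table and fed through the same ensemble
    inference as the community networks.  The keystone block is used as
    given — pass abundances relative to the *whole* community when the
    data are compositional; re-closing a small keystone subset to sum 1
    would replace each taxon's abundance with its share of the keystone
    total and decouple it from the gene signals.  Each retained edge gets
    weight |mean of the Pearson and Spearman scores|, and the weights are
    summed within three categories: gene-gene, species-gene and
    species-species.

    Returns ``(network, category_sums)`` where category_sums is a dict
    with those three keys plus node/edge counts.
    """
    from .network import infer_network

    config = config or PipelineConfig()
    shared = [s for s in keystone_table.sample_ids if s in set(gene_table.sample_ids)]
    if len(shared) < 4:
        raise ValueError("functional network needs at least 4 shared samples")
    k_sub = keystone_table.subset_samples(shared)
    g_idx = [gene_table.sample_ids.index(s) for s in shared]
    gene_rows = gene_table.signals[:, g_idx]
    clash = set(k_sub.otu_ids) & set(gene_table.probe_ids)
    if clash:
        raise ValueError(f"probe ids collide with OTU ids: {sorted(clash)}")
    combined = CommunityTable(
        list(k_sub.otu_ids) + list(gene_table.probe_ids),
        shared,
        np.vstack([k_sub.counts, gene_rows]),
    )
    net = infer_network(combined, "functional", config, rng=rng)
    sums = category_weight_sums(net.edges, set(k_sub.otu_ids))
    return net, sums


def category_weight_sums(edges, species: set) -> dict:
    """Sum edge weights within gene-gene, species-gene and species-species.

    An edge's weight is the absolute mean of its Pearson and Spearman
    scores; an endpoint is a species when it belongs to ``species``,
    otherwise a gene probe.
    """
    sums = {"gene_gene": 0.0, "species_gene": 0.0, "species_species": 0.0}
    for e in edges:
        w = abs((e.scores["pearson"] + e.scores["spearman"]) / 2.0)
        a_sp, b_sp = e.otu_a in species, e.otu_b in species
        if a_sp and b_sp:
            sums["species_species"] += w
        elif a_sp or b_sp:
            sums["species_gene"] += w
        else:
            sums["gene_gene"] += w
    sums["n_nodes"] = float(len({n for e in edges for n in (e.otu_a, e.otu_b)}))
    sums["n_edges"] = float(len(edges))
    return sums


def weight_ch4_regression(weights, ch4):
    """Regression of per-site species-gene linkage weight on CH4 emission.

    Returns ``(slope, p)`` where the slope is OLS and the p-value is the
    two-sided Spearman rank-correlation p.  Needs at least 5 sites;
    constant weights make the relationship unavailable (NaN, NaN).
    """
    w = np.asarray(weights, dtype=float)
    c = np.asarray(ch4, dtype=float)
    if w.size < 5:
        raise ValueError("need at least 5 sites")
    if np.std(w) == 0:
        logger.warning("weight_ch4_regression: constant weights")
        return float("nan"), float("nan")
    slope = float(stats.linregress(w, c).slope)
    rho = stats.spearmanr(w, c)
    return slope, float(rho.pvalue)
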
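"""Ensemble co-occurrence network inference.

Re-implements the CoNet-style ensemble procedure: pairwise association by
four measures (Pearson, Spearman, Bray-Curtis, Kullback-Leibler), initial
score thresholds retrieving a fixed number of positive and negative
candidate edges per measure, ReBoot significance (renormalized permutation
null plus a bootstrap direction-stability veto), Brown's method to merge
the four dependent measure-specific p-values, Benjamini-Hochberg control
over each network's candidate edges, and retention only of edges supported
by all four measures with a consistent direction.

The permutation null permutes each OTU's abundances across samples
independently and then re-closes every sample to sum 1 ("renormalization"),
which is the step that counteracts compositionality bias: a spurious
correlation induced purely by closure survives in the null and therefore
does not look significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy import stats
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .containers import CommunityTable

logger = logging.getLogger(__name__)

__all__ = [
    "MEASURES", "CORRELATION_MEASURES", "DISSIMILARITY_MEASURES",
    "EdgeRecord", "LocalNetwork",
    "pairwise_scores", "initial_thresholds", "intersect_measures",
    "reboot_scores", "reboot_pvalue", "brown_merge", "bh_filter",
    "infer_network", "topology_metrics", "network_index",
    "TOPOLOGY_ATTRIBUTES",
]

MEASURES = ("pearson", "spearman", "braycurtis", "kl")
CORRELATION_MEASURES = ("pearson", "spearman")
DISSIMILARITY_MEASURES = ("braycurtis", "kl")

TOPOLOGY_ATTRIBUTES = (
    "node_number", "edge_number", "modularity",
    "positive_count", "negative_count",
    "avg_clustering", "diameter", "char_path_length",
)


@dataclass
class EdgeRecord:
    """A signed, p-valued pairwise association in one local network."""

    otu_a: str
    otu_b: str
    sign: str  # '+' or '-'
    scores: dict
    measure_p: dict
    merged_p: float
    q_value: float = float("nan")
    network_id: str = ""

    def __post_init__(self) -> None:
        if self.otu_a == self.otu_b:
            raise ValueError("self-association is not an edge")
        if self.sign not in ("+", "-"):
            raise ValueError(f"sign must be '+' or '-', got {self.sign!r}")

    def canonical(self) -> "EdgeRecord":
        """Endpoints in lexicographic order (edge identity is unordered)."""
        if self.otu_a <= self.otu_b:
            return self
        return replace(self, otu_a=self.otu_b, otu_b=self.otu_a)

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.otu_a, self.otu_b)))

    def to_row(self) -> list:
        return [
            self.otu_a, self.otu_b, self.sign,
            *(self.scores.get(m, float("nan")) for m in MEASURES),
            *(self.measure_p.get(m, float("nan")) for m in MEASURES),
            self.merged_p, self.q_value, self.network_id,
        ]


@dataclass
class LocalNetwork:
    """A per-site co-occurrence graph plus its eight topology attributes."""

    network_id: str
    nodes: set
    edges: list
    topology: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for e in self.edges:
            if e.otu_a not in self.nodes or e.otu_b not in self.nodes:
                raise ValueError(f"edge endpoint outside node set: {e.pair}")

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.otu_a, e.otu_b, sign=e.sign)
        return g


# ----------------------------------------------------------------------
# pairwise scores
# ----------------------------------------------------------------------


def _kl_pseudocount(rel: np.ndarray, override: float | None) -> float:
    if override is not None:
        return float(override)
    nz = rel[rel > 0]
    if nz.size == 0:
        raise ValueError("table has no nonzero abundances")
    return float(nz.min() / 2.0)


def _rowwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of matched rows of two (m, n) arrays."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.clip(r, -1.0, 1.0)


def _rowwise_measure(x: np.ndarray, y: np.ndarray, measure: str,
                     pseudocount: float) -> np.ndarray:
    """Score matched rows of x and y under one ensemble measure."""
    if measure == "pearson":
        return _rowwise_pearson(x, y)
    if measure == "spearman":
        return _rowwise_pearson(rankdata(x, axis=1), rankdata(y, axis=1))
    if measure == "braycurtis":
        num = np.abs(x - y).sum(axis=1)
        den = (x + y).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / den, np.nan)
    if measure == "kl":
        p = np.where(x > 0, x, pseudocount)
        q = np.where(y > 0, y, pseudocount)
        p = p / p.sum(axis=1, keepdims=True)
        q = q / q.sum(axis=1, keepdims=True)
        return 0.5 * ((p * np.log(p / q)).sum(axis=1)
                      + (q * np.log(q / p)).sum(axis=1))
    raise ValueError(f"unknown measure {measure!r}")


def pairwise_scores(table: CommunityTable, measure: str,
                    kl_pseudocount: float | None = None) -> np.ndarray:
    """Symmetric OTU x OTU score matrix for one measure.

    The table is closed to relative abundance first.  Entries involving a
    constant OTU profile are NaN for the correlation measures (score
    undefined); the diagonal is NaN for every measure.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    if table.n_samples < 4:
        raise ValueError("pairwise scores need at least 4 samples")
    rel = table.to_relative().counts
    n = rel.shape[0]
    p0 = _kl_pseudocount(rel, kl_pseudocount)
    out = np.full((n, n), np.nan)
    iu, ju = np.triu_indices(n, k=1)
    vals = _rowwise_measure(rel[iu], rel[ju], measure, p0)
    if measure in CORRELATION_MEASURES:
        const = rel.std(axis=1) == 0
        if const.any():
            logger.info("%s: %d constant OTU profiles skipped",
                        measure, int(const.sum()))
            vals = np.where(const[iu] | const[ju], np.nan, vals)
    out[iu, ju] = vals
    out[ju, iu] = vals
    return out


# ----------------------------------------------------------------------
# initial thresholds and measure intersection
# ----------------------------------------------------------------------


def initial_thresholds(score_matrix: np.ndarray, measure: str,
                       n_pos: int = 1000, n_neg: int = 1000) -> dict:
    """Candidate edges for one measure: strongest positives and negatives.

    Correlations: positive candidates are the ``n_pos`` largest positive r,
    negative candidates the ``n_neg`` most negative r.  Dissimilarities
    carry no intrinsic sign, so the smallest values are the strongest
    positive (co-presence) candidates and the largest the strongest
    negative ones; a pair falling inside both windows (possible when the
    windows overlap on a small instance) is assigned the side on which its
    rank is stronger and dropped on an exact tie.  Ties at the cutoff rank
    are all kept.

    Returns a dict mapping canonical index pairs ``(i, j)`` with i < j to
    direction '+' or '-'.
    """
    n = score_matrix.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = score_matrix[iu, ju]
    ok = np.isfinite(vals)
    pairs = list(zip(iu[ok].tolist(), ju[ok].tolist()))
    vals = vals[ok]
    out: dict[tuple[int, int], str] = {}
    if measure in CORRELATION_MEASURES:
        for direction, mask, strength in (
            ("+", vals > 0, vals),
            ("-", vals < 0, -vals),
        ):
            idx = np.nonzero(mask)[0]
            limit = n_pos if direction == "+" else n_neg
            for k in _top_with_ties(strength[idx], limit):
                out[pairs[idx[k]]] = direction
        return out
    # dissimilarity: rank from both ends
    pos_rank = rankdata(vals, method="min")            # small = strong '+'
    neg_rank = rankdata(-vals, method="min")           # large = strong '-'
    pos_cut = _tie_cutoff(pos_rank, n_pos)
    neg_cut = _tie_cutoff(neg_rank, n_neg)
    n_conflict = 0
    for k in range(len(vals)):
        in_pos = pos_rank[k] <= pos_cut
        in_neg = neg_rank[k] <= neg_cut
        if in_pos and in_neg:
            if pos_rank[k] < neg_rank[k]:
                out[pairs[k]] = "+"
            elif neg_rank[k] < pos_rank[k]:
                out[pairs[k]] = "-"
            else:
                n_conflict += 1
        elif in_pos:
            out[pairs[k]] = "+"
        elif in_neg:
            out[pairs[k]] = "-"
    if n_conflict:
        logger.info("initial thresholds: %d ambiguous dissimilarity pairs dropped",
                    n_conflict)
    return out


def _top_with_ties(strength: np.ndarray, limit: int) -> np.ndarray:
    """Indices of the ``limit`` largest values, keeping ties at the cutoff."""
    if strength.size == 0:
        return np.array([], dtype=int)
    if strength.size <= limit:
        return np.arange(strength.size)
    order = np.argsort(-strength, kind="stable")
    cutoff = strength[order[limit - 1]]
    return np.nonzero(strength >= cutoff)[0]


def _tie_cutoff(ranks: np.ndarray, limit: int) -> int:
    """Largest admitted min-rank so that >= limit entries pass, tie-safe."""
    if ranks.size <= limit:
        return int(ranks.max()) if ranks.size else 0
    return int(np.sort(ranks)[limit - 1])


def intersect_measures(candidates: dict) -> dict:
    """Edges supported by all four measures with one consistent direction.

    ``candidates`` maps measure name to a dict of pair -> direction.  An
    edge supported by fewer than four measures, or with conflicting
    directions among them, is dropped (conflicts are counted in the log).
    """
    missing = [m for m in MEASURES if m not in candidates]
    if missing:
        raise ValueError(f"candidate sets missing for measures: {missing}")
    sets = [set(candidates[m]) for m in MEASURES]
    shared = set.intersection(*sets)
    out: dict[tuple, str] = {}
    n_conflict = 0
    for pair in shared:
        dirs = {candidates[m][pair] for m in MEASURES}
        if len(dirs) == 1:
            out[pair] = dirs.pop()
        else:
            n_conflict += 1
    if n_conflict:
        logger.info("intersect_measures: %d direction-conflicting edges dropped",
                    n_conflict)
    return out


# ----------------------------------------------------------------------
# ReBoot: renormalized permutation null + bootstrap stability
# ----------------------------------------------------------------------


def _renormalized_pair_null(rel: np.ndarray, i: int, j: int, n_perm: int,
                            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Permuted-and-renormalized profiles for one OTU pair.

    Each permutation shuffles OTU i's and OTU j's relative abundances across
    samples independently, then re-closes every sample to sum 1.  Only the
    pair's own renormalized profiles are needed to re-score the pair, so the
    remaining OTUs enter through the closure denominator alone.
    """
    ra, rb = rel[i], rel[j]
    n_s = ra.size
    idx_a = np.argsort(rng.random((n_perm, n_s)), axis=1)
    idx_b = np.argsort(rng.random((n_perm, n_s)), axis=1)
    pa, pb = ra[idx_a], rb[idx_b]
    denom = 1.0 - ra - rb + pa + pb
    denom = np.where(denom <= 0, np.nan, denom)
    return pa / denom, pb / denom


def reboot_scores(table: CommunityTable, pair: tuple[int, int], measure: str,
                  n_perm: int, n_boot: int, rng: np.random.Generator,
                  kl_pseudocount: float | None = None,
                  _shared: dict | None = None):
    """Observed score, permutation-null scores and bootstrap scores.

    ``_shared`` lets the caller reuse one set of permutation and bootstrap
    index draws across the four measures of the ensemble, which is what
    makes the null p-value matrices comparable for Brown's method.
    """
    rel = table.to_relative().counts
    p0 = _kl_pseudocount(rel, kl_pseudocount)
    i, j = pair
    if _shared is not None and "null_a" in _shared:
        na, nb = _shared["null_a"], _shared["null_b"]
        boot_idx = _shared["boot_idx"]
    else:
        na, nb = _renormalized_pair_null(rel, i, j, n_perm, rng)
        boot_idx = rng.integers(0, rel.shape[1], size=(n_boot, rel.shape[1]))
        if _shared is not None:
            _shared.update(null_a=na, null_b=nb, boot_idx=boot_idx)
    obs = float(_rowwise_measure(rel[[i]], rel[[j]], measure, p0)[0])
    null = _rowwise_measure(na, nb, measure, p0)
    boot = _rowwise_measure(rel[i][boot_idx], rel[j][boot_idx], measure, p0)
    return obs, null, boot


def _support(score, measure: str, direction: str):
    """Orient a score so that larger always means stronger evidence for
    the candidate direction."""
    s = np.asarray(score, dtype=float)
    if measure in CORRELATION_MEASURES:
        return s if direction == "+" else -s
    return -s if direction == "+" else s


def reboot_pvalue(obs: float, null: np.ndarray, boot: np.ndarray,
                  measure: str, direction: str, n_perm: int,
                  veto_fraction: float = 0.95) -> float:
    """One-sided permutation p-value with a bootstrap stability veto.

    p = (1 + #{null scores at least as extreme as the observed score, in
    the observed direction}) / (n_perm + 1).  The edge is additionally
    discarded (p forced to 1) unless at least ``veto_fraction`` of the
    bootstrap scores fall on the observed side of the null mean.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives too coarse a p-value resolution")
    v_obs = _support(obs, measure, direction)
    v_null = _support(null, measure, direction)
    v_null = v_null[np.isfinite(v_null)]
    if v_null.size == 0:
        return 1.0
    p = (1.0 + np.sum(v_null >= v_obs)) / (n_perm + 1.0)
    v_boot = _support(boot, measure, direction)
    v_boot = v_boot[np.isfinite(v_boot)]
    null_center = v_null.mean()
    if v_boot.size == 0 or np.mean(v_boot > null_center) < veto_fraction:
        return 1.0
    return float(p)


def null_pvalue_matrix(nulls: dict, measure_dirs: dict, n_perm: int) -> np.ndarray:
    """Per-measure null p-values from shared permutations (n_perm x 4).

    For each measure, every null score is converted to its own one-sided
    p-value within the null distribution; the columns inherit the
    between-measure dependence of the shared permutation draws, which is
    exactly the dependence Brown's method needs to estimate.
    """
    cols = []
    for m in MEASURES:
        v = _support(nulls[m], m, measure_dirs[m])
        v = np.where(np.isfinite(v), v, -np.inf)
        # count of null scores >= each null score, tie-inclusive
        greater_eq = v.size - rankdata(v, method="min") + 1
        cols.append((1.0 + greater_eq) / (n_perm + 1.0))
    return np.column_stack(cols)


# ----------------------------------------------------------------------
# Brown's method and BH
# ----------------------------------------------------------------------


def brown_merge(p_values, null_p_matrix: np.ndarray | None = None) -> float:
    """Combine k dependent p-values with Brown's method.

    T = sum(-2 ln p_i) is referred to a scaled chi-square: E[T] = 2k,
    Var[T] = 4k + 2 * sum_{i<j} cov(-2 ln P_i, -2 ln P_j), with the
    covariances estimated from the null p-value matrix generated under the
    same permutations.  c = Var/(2E) and f = 2E^2/Var give
    merged_p = P(chi2_f > T/c).  Without a null matrix (or when the
    estimated variance is degenerate) the method reduces to Fisher's.
    """
    p = np.asarray(list(p_values), dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    k = p.size
    t = float(np.sum(-2.0 * np.log(p)))
    expected = 2.0 * k
    var = 4.0 * k
    if null_p_matrix is not None:
        w = -2.0 * np.log(np.clip(np.asarray(null_p_matrix, dtype=float),
                                  1e-300, 1.0))
        if w.shape[1] != k:
            raise ValueError("null p-value matrix has wrong number of columns")
        cov = np.cov(w, rowvar=False)
        var = 4.0 * k + 2.0 * float(np.triu(cov, k=1).sum())
    if not np.isfinite(var) or var <= 0:
        logger.info("brown_merge: degenerate variance, falling back to Fisher")
        var = 4.0 * k
    c = var / (2.0 * expected)
    f = 2.0 * expected**2 / var
    return float(stats.chi2.sf(t / c, f))


def bh_filter(edges: list, alpha: float = 0.05) -> list:
    """Benjamini-Hochberg step-up over one network's candidate edges.

    Attaches q-values and returns the edges with q < alpha.
    """
    if not edges:
        return []
    p = np.array([e.merged_p for e in edges])
    _, q, _, _ = multipletests(p, method="fdr_bh")
    kept = []
    for e, qv in zip(edges, q):
        e.q_value = float(qv)
        if qv < alpha:
            kept.append(e)
    return kept


# ----------------------------------------------------------------------
# full per-site inference
# ----------------------------------------------------------------------


def infer_network(table: CommunityTable, network_id: str,
                  config: PipelineConfig | None = None,
                  rng: np.random.Generator | None = None) -> LocalNetwork:
    """Run the whole ensemble procedure on one site's community table."""
    config = config or PipelineConfig()
    table.require_analysable()
    if rng is None:
        rng = config.rng(f"network:{network_id}")
    rel = table.to_relative()
    p0 = config.kl_pseudocount

    cand = {}
    for m in MEASURES:
        scores = pairwise_scores(table, m, kl_pseudocount=p0)
        cand[m] = initial_thresholds(scores, m, config.n_pos_edges,
                                     config.n_neg_edges)
    final = intersect_measures(cand)

    edges = []
    for pair in sorted(final):
        direction = final[pair]
        shared: dict = {}
        p_by_measure, nulls, obs_scores = {}, {}, {}
        for m in MEASURES:
            obs, null, boot = reboot_scores(
                rel, pair, m, config.n_perm, config.n_boot, rng,
                kl_pseudocount=p0, _shared=shared,
            )
            obs_scores[m] = obs
            nulls[m] = null
            p_by_measure[m] = reboot_pvalue(
                obs, null, boot, m, direction, config.n_perm,
                veto_fraction=config.bootstrap_veto,
            )
        npm = null_pvalue_matrix(nulls, {m: direction for m in MEASURES},
                                 config.n_perm)
        merged = brown_merge([p_by_measure[m] for m in MEASURES], npm)
        i, j = pair
        edges.append(EdgeRecord(
            otu_a=table.otu_ids[i], otu_b=table.otu_ids[j], sign=direction,
            scores=obs_scores, measure_p=p_by_measure,
            merged_p=merged, network_id=network_id,
        ).canonical())

    kept = bh_filter(edges, config.alpha)
    net = LocalNetwork(network_id=network_id, nodes=set(table.otu_ids),
                       edges=kept)
    net.topology = topology_metrics(net)
    logger.info("network %s: %d candidates -> %d edges", network_id,
                len(edges), len(kept))
    return net


# ----------------------------------------------------------------------
# topology
# ----------------------------------------------------------------------


def topology_metrics(network: LocalNetwork | nx.Graph) -> dict:
    """The eight topological attributes of one co-occurrence network.

    Modularity comes from deterministic greedy modularity maximisation on
    the unsigned graph; the clustering coefficient is averaged over all
    nodes (degree < 2 contributing 0); diameter and characteristic path
    length are computed on the largest connected component.  Isolated
    nodes are not part of the graph: the node set is the set of edge
    endpoints.
    """
    if isinstance(network, LocalNetwork):
        signs = [e.sign for e in network.edges]
        g = nx.Graph()
        for e in network.edges:
            g.add_edge(e.otu_a, e.otu_b)
    else:
        g = nx.Graph(network)
        signs = [d.get("sign", "+") for _, _, d in g.edges(data=True)]

    out = dict.fromkeys(TOPOLOGY_ATTRIBUTES, 0.0)
    if g.number_of_edges() == 0:
        logger.warning("topology_metrics: empty network, all attributes 0")
        return out
    out["node_number"] = float(g.number_of_nodes())
    out["edge_number"] = float(g.number_of_edges())
    out["positive_count"] = float(sum(1 for s in signs if s == "+"))
    out["negative_count"] = float(sum(1 for s in signs if s == "-"))
    communities = nx.community.greedy_modularity_communities(g)
    out["modularity"] = float(nx.community.modularity(g, communities))
    out["avg_clustering"] = float(nx.average_clustering(g))
    giant = g.subgraph(max(nx.connected_components(g), key=len))
    out["diameter"] = float(nx.diameter(giant))
    if giant.number_of_nodes() > 1:
        out["char_path_length"] = float(nx.average_shortest_path_length(giant))
    return out


def network_index(networks: list) -> tuple[np.ndarray, float]:
    """First-principal-component summary of the eight topology attributes.

    Attributes are z-scored across networks (constant columns dropped);
    the PC1 score vector is sign-fixed to correlate positively with edge
    number.  Returns ``(scores, explained_variance_fraction)``.
    """
    if len(networks) < 3:
        raise ValueError("network index needs at least 3 networks")
    mat = np.array([[n.topology[a] for a in TOPOLOGY_ATTRIBUTES]
                    for n in networks], dtype=float)
    keep = mat.std(axis=0) > 0
    if not keep.all():
        dropped = [a for a, k in zip(TOPOLOGY_ATTRIBUTES, keep) if not k]
        logger.info("network_index: dropping constant attributes %s", dropped)
    mat = mat[:, keep]
    if mat.shape[1] == 0:
        raise ValueError("all topology attributes are constant across networks")
    z = (mat - mat.mean(axis=0)) / mat.std(axis=0)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u[:, 0] * s[0]
    explained = float(s[0] ** 2 / np.sum(s**2))
    edge_col = np.array([n.topology["edge_number"] for n in networks])
    if edge_col.std() > 0 and np.corrcoef(scores, edge_col)[0, 1] < 0:
        scores = -scores
    return scores, explained
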
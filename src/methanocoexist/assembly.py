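"""Phylogenetic null models of community assembly.

Nearest-taxon statistics on the cophenetic matrix: MNTD (mean distance
from each taxon in a community to its closest relative in the same
community), its null-standardized effect size ses.MNTD (= -NTI), the
between-community analogue betaMNTD (abundance-weighted mean distance to
the closest relative in the other community), and betaNTI, the z-score of
betaMNTD against a taxa-label-shuffling null.  |betaNTI| beyond 2 is read
as deterministic assembly (environmental selection), values between -2
and 2 as stochastic assembly.

The null model shuffles tip labels across the phylogeny: taxon identities
are randomly re-assigned to tree positions while abundances stay fixed,
which preserves the multiset of cophenetic distances and community
structure but destroys any phylogenetic signal in who co-occurs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .containers import CommunityTable, Phylogeny

logger = logging.getLogger(__name__)

__all__ = [
    "AssemblyResult", "mntd", "ses_mntd", "beta_mntd", "beta_nti",
    "beta_nti_matrix", "assembly_fractions", "group_assembly",
]


@dataclass
class AssemblyResult:
    """Per-group betaNTI distribution and its determinism partition."""

    group: str
    beta_nti_values: np.ndarray
    fraction_determinism: float
    fraction_stochasticity: float
    n_pairs: int
    n_skipped: int = 0
    available: bool = True
    ses_mntd_values: np.ndarray | None = field(default=None, repr=False)


def _present(abundances: np.ndarray) -> np.ndarray:
    return np.nonzero(np.asarray(abundances, dtype=float) > 0)[0]


def mntd(abundances, dist: np.ndarray, weighted: bool = False) -> float:
    """Mean nearest taxon distance within one community.

    ``abundances`` indexes into the rows of the cophenetic submatrix
    ``dist``; only taxa with positive abundance are considered, and each
    contributes its distance to the closest *other* present taxon, either
    equally weighted or weighted by relative abundance.
    """
    idx = _present(abundances)
    if idx.size < 2:
        raise ValueError("MNTD needs at least 2 taxa with positive abundance")
    sub = dist[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    nearest = sub.min(axis=1)
    if weighted:
        w = np.asarray(abundances, dtype=float)[idx]
        return float(np.sum(nearest * w) / np.sum(w))
    return float(nearest.mean())


def ses_mntd(abundances, dist: np.ndarray, n_null: int = 999,
             weighted: bool = False,
             rng: np.random.Generator | None = None) -> float:
    """Standardized effect size of MNTD under taxa-label shuffling.

    z = (MNTD_obs - mean(MNTD_null)) / sd(MNTD_null); NTI is -z.  The
    null re-assigns the community's taxa to random positions in the tip
    pool spanned by ``dist``.  Returns NaN when the null distribution is
    degenerate (e.g. the community saturates the pool).
    """
    rng = rng or np.random.default_rng()
    abundances = np.asarray(abundances, dtype=float)
    idx = _present(abundances)
    if idx.size < 2:
        raise ValueError("ses.MNTD needs at least 2 taxa with positive abundance")
    obs = mntd(abundances, dist, weighted=weighted)
    n_pool, k = dist.shape[0], idx.size
    w = abundances[idx]
    positions = np.argsort(rng.random((n_null, n_pool)), axis=1)[:, :k]
    sub = dist[positions[:, :, None], positions[:, None, :]]
    sub[:, np.arange(k), np.arange(k)] = np.inf
    nearest = sub.min(axis=2)
    if weighted:
        nulls = (nearest * w).sum(axis=1) / w.sum()
    else:
        nulls = nearest.mean(axis=1)
    sd = nulls.std(ddof=1)
    if _degenerate(sd, nulls):
        logger.warning("ses.MNTD: degenerate null distribution (sd = 0)")
        return float("nan")
    return float((obs - nulls.mean()) / sd)


def _degenerate(sd: float, nulls: np.ndarray) -> bool:
    """A null spread indistinguishable from accumulated rounding error."""
    return sd <= 1e-12 * max(1.0, float(np.abs(nulls).max()))


def _beta_mntd_from_cross(cross: np.ndarray, w_i: np.ndarray,
                          w_j: np.ndarray) -> float:
    """betaMNTD from the cross-community distance block (rows = community i)."""
    term_i = float(np.sum(cross.min(axis=1) * w_i))
    term_j = float(np.sum(cross.min(axis=0) * w_j))
    return 0.5 * (term_i + term_j)


def _weights(abundances: np.ndarray, idx: np.ndarray) -> np.ndarray:
    w = abundances[idx]
    return w / w.sum()


def beta_mntd(abund_i, abund_j, dist: np.ndarray,
              weighted: bool = True) -> float:
    """Between-community mean nearest taxon distance.

    For every taxon present in community i, the cophenetic distance to its
    closest relative present in community j (zero if the taxon itself is
    shared), averaged with the taxon's relative abundance in i; symmetrized
    by averaging the two directions.
    """
    abund_i = np.asarray(abund_i, dtype=float)
    abund_j = np.asarray(abund_j, dtype=float)
    idx_i, idx_j = _present(abund_i), _present(abund_j)
    if idx_i.size == 0 or idx_j.size == 0:
        raise ValueError("betaMNTD needs both communities non-empty")
    if weighted:
        w_i, w_j = _weights(abund_i, idx_i), _weights(abund_j, idx_j)
    else:
        w_i = np.full(idx_i.size, 1.0 / idx_i.size)
        w_j = np.full(idx_j.size, 1.0 / idx_j.size)
    cross = dist[np.ix_(idx_i, idx_j)]
    return _beta_mntd_from_cross(cross, w_i, w_j)


def beta_nti(abund_i, abund_j, dist: np.ndarray, n_null: int = 999,
             weighted: bool = True,
             rng: np.random.Generator | None = None) -> float:
    """betaNTI: z-score of betaMNTD against the taxa-label-shuffle null.

    One permutation of the tip pool per null draw relocates both
    communities' taxa simultaneously, abundances fixed.  Returns NaN when
    the null has zero spread (e.g. identical communities, whose shared
    taxa keep betaMNTD at 0 under every relabeling).
    """
    rng = rng or np.random.default_rng()
    abund_i = np.asarray(abund_i, dtype=float)
    abund_j = np.asarray(abund_j, dtype=float)
    idx_i, idx_j = _present(abund_i), _present(abund_j)
    if idx_i.size == 0 or idx_j.size == 0:
        raise ValueError("betaNTI needs both communities non-empty")
    obs = beta_mntd(abund_i, abund_j, dist, weighted=weighted)
    if weighted:
        w_i, w_j = _weights(abund_i, idx_i), _weights(abund_j, idx_j)
    else:
        w_i = np.full(idx_i.size, 1.0 / idx_i.size)
        w_j = np.full(idx_j.size, 1.0 / idx_j.size)
    n_pool = dist.shape[0]
    perms = np.argsort(rng.random((n_null, n_pool)), axis=1)
    pos_i, pos_j = perms[:, idx_i], perms[:, idx_j]
    cross = dist[pos_i[:, :, None], pos_j[:, None, :]]
    term_i = (cross.min(axis=2) * w_i).sum(axis=1)
    term_j = (cross.min(axis=1) * w_j).sum(axis=1)
    nulls = 0.5 * (term_i + term_j)
    sd = nulls.std(ddof=1)
    if _degenerate(sd, nulls):
        logger.debug("betaNTI: degenerate null distribution (sd = 0)")
        return float("nan")
    return float((obs - nulls.mean()) / sd)


def beta_nti_matrix(table: CommunityTable, phylo: Phylogeny,
                    n_null: int = 999, weighted: bool = True,
                    rng: np.random.Generator | None = None,
                    max_pairs: int | None = None,
                    pool_dist: np.ndarray | None = None) -> tuple[np.ndarray, int]:
    """betaNTI over sample pairs of one community table.

    ``pool_dist`` optionally supplies a cophenetic matrix over a wider tip
    pool whose leading rows/columns correspond to the table's OTUs; by
    default the pool is the table's own OTU set.  Pairs where either
    sample is empty after subsetting are skipped and counted.  When
    ``max_pairs`` is given, a random subset of sample pairs of that size
    is evaluated (statistically sufficient for the determinism fractions
    and much cheaper on large tables).

    Returns ``(values, n_skipped)``.
    """
    rng = rng or np.random.default_rng()
    if pool_dist is None:
        pool_dist = phylo.distance_submatrix(table.otu_ids)
    counts = table.counts
    n_s = table.n_samples
    pairs = [(a, b) for a in range(n_s) for b in range(a + 1, n_s)]
    if max_pairs is not None and len(pairs) > max_pairs:
        chosen = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[int(c)] for c in sorted(chosen)]
    values, skipped = [], 0
    for a, b in pairs:
        x, y = counts[:, a], counts[:, b]
        if (x > 0).sum() == 0 or (y > 0).sum() == 0:
            skipped += 1
            continue
        z = beta_nti(x, y, pool_dist, n_null=n_null, weighted=weighted, rng=rng)
        if np.isfinite(z):
            values.append(z)
        else:
            skipped += 1
    return np.asarray(values), skipped


def assembly_fractions(beta_nti_values, cutoff: float = 2.0,
                       symmetric: bool = False) -> tuple[float, float]:
    """Percent determinism / stochasticity from a betaNTI vector.

    Literal rule: z > cutoff or z <= -cutoff counts as deterministic (a
    value exactly at -cutoff is deterministic, exactly at +cutoff is
    stochastic); ``symmetric=True`` switches to |z| >= cutoff.
    """
    z = np.asarray(beta_nti_values, dtype=float)
    z = z[np.isfinite(z)]
    if z.size == 0:
        raise ValueError("no usable betaNTI values")
    if symmetric:
        det = np.abs(z) >= cutoff
    else:
        det = (z > cutoff) | (z <= -cutoff)
    determinism = 100.0 * det.mean()
    return determinism, 100.0 - determinism


def group_assembly(table: CommunityTable, phylo: Phylogeny, groups,
                   config: PipelineConfig | None = None,
                   max_pairs: int | None = None,
                   rng: np.random.Generator | None = None) -> dict:
    """Determinism/stochasticity partition for each coexistence group.

    Each group's community is the table restricted to the group's related
    OTUs (those on the tree); betaNTI is computed over sample pairs of
    that sub-community and partitioned into determinism/stochasticity at
    the configured cutoff.  By default the null shuffles taxa labels over
    the group's own tip pool (the tree pruned to the sub-community, which
    is what handing a subset table to the standard phylogenetic tooling
    does) so the statistic conditions on group composition and measures
    how the group's taxa assemble, not whether the group itself is a
    clustered set; ``config.assembly_pool = "table"`` switches to
    shuffling across all of the table's tips.  Groups with fewer than 2
    usable OTUs come back flagged unavailable.
    """
    from .classify import GROUP_NAMES

    config = config or PipelineConfig()
    if rng is None:
        rng = config.rng("assembly")
    tree_tips = set(phylo.tip_labels)
    pool = sorted(set(table.otu_ids) & tree_tips)
    results: dict[str, AssemblyResult] = {}
    for name in GROUP_NAMES:
        otus = sorted(groups.related_otus(name) & set(table.otu_ids) & tree_tips)
        if len(otus) < 2:
            results[name] = AssemblyResult(name, np.array([]), float("nan"),
                                           float("nan"), 0, available=False)
            continue
        sub = table.subset_otus(otus)
        if config.assembly_pool == "group":
            pool_dist = phylo.distance_submatrix(otus)
        else:
            # cophenetic pool with the group's OTUs as the leading block
            ordered = otus + [o for o in pool if o not in set(otus)]
            pool_dist = phylo.distance_submatrix(ordered)
        values, skipped = beta_nti_matrix(
            sub, phylo, n_null=config.n_null_phylo, rng=rng,
            max_pairs=max_pairs, pool_dist=pool_dist,
        )
        if values.size == 0:
            results[name] = AssemblyResult(name, values, float("nan"),
                                           float("nan"), 0, skipped, False)
            continue
        det, sto = assembly_fractions(values, config.beta_nti_cutoff,
                                      config.symmetric_cutoff)
        results[name] = AssemblyResult(name, values, det, sto,
                                       values.size, skipped)
    return results
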
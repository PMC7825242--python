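"""Diversity, geographic distance and distance-decay relationships.

Alpha diversity (richness and natural-log Shannon), Bray-Curtis
beta-diversity between samples, great-circle distances, and the
distance-decay relationship (DDR): the ordinary-least-squares slope of
ln(community similarity) on ln(geographic distance), fitted separately
inside three spatial windows — local (1-100 m), mesoscale (0.1-50 km)
and regional (100-3500 km).  Also provides the CH4 production-potential
slope from incubation time series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .containers import CommunityTable

logger = logging.getLogger(__name__)

__all__ = [
    "DdrResult", "alpha_diversity", "bray_curtis_matrix", "haversine_km",
    "geographic_distance_matrix", "ddr_slope", "ddr_all_scales",
    "ch4_potential_slope",
]

EARTH_RADIUS_KM = 6371.0

#: half-open [min, max) distance windows in km for the three DDR scales
DEFAULT_DDR_WINDOWS = {
    "local": (0.001, 0.1),
    "meso": (0.1, 50.0),
    "regional": (100.0, 3500.0),
}


@dataclass
class DdrResult:
    scale: str
    window_km: tuple[float, float]
    slope: float
    intercept: float
    r_squared: float
    n_pairs: int
    n_dropped: int = 0
    available: bool = True


def alpha_diversity(table: CommunityTable) -> pd.DataFrame:
    """Per-sample richness and Shannon index (natural log).

    Richness counts OTUs with positive abundance; H = -sum(p ln p) over
    present OTUs with p the within-sample relative abundance.  Empty
    samples get richness 0 and H 0 with a warning.
    """
    counts = table.counts
    richness = (counts > 0).sum(axis=0)
    shannon = np.zeros(table.n_samples)
    for j in range(table.n_samples):
        col = counts[:, j]
        total = col.sum()
        if total <= 0:
            logger.warning("alpha_diversity: sample %s is empty",
                           table.sample_ids[j])
            continue
        p = col[col > 0] / total
        shannon[j] = float(-(p * np.log(p)).sum())
    return pd.DataFrame(
        {"richness": richness.astype(int), "shannon": shannon},
        index=pd.Index(table.sample_ids, name="sample_id"),
    )


def bray_curtis_matrix(table: CommunityTable, relative: bool = True) -> pd.DataFrame:
    """Sample x sample Bray-Curtis dissimilarity.

    BC(i, j) = sum|x_i - x_j| / sum(x_i + x_j) over OTUs, on per-sample
    relative abundances by default (raw counts when ``relative=False``).
    A pair of all-zero samples has no defined dissimilarity and is NaN.
    """
    counts = table.counts.T  # samples x OTUs
    if relative:
        sums = counts.sum(axis=1, keepdims=True)
        empty = sums[:, 0] <= 0
        safe = np.where(sums > 0, sums, 1.0)
        counts = counts / safe
    else:
        empty = counts.sum(axis=1) <= 0
    d = squareform(pdist(counts, metric="braycurtis"))
    if empty.any():
        d[empty, :] = np.nan
        d[:, empty] = np.nan
    np.fill_diagonal(d, 0.0)
    d[np.ix_(empty, empty)] = np.nan
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km (Earth radius 6371 km)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def geographic_distance_matrix(meta: pd.DataFrame) -> pd.DataFrame:
    """Pairwise great-circle distances (km) between metadata samples."""
    lat = np.radians(meta["latitude"].to_numpy(dtype=float))
    lon = np.radians(meta["longitude"].to_numpy(dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = (np.sin(dlat / 2) ** 2
         + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    ids = meta["sample_id"].tolist()
    return pd.DataFrame(d, index=ids, columns=ids)


def ddr_slope(similarity: pd.DataFrame | np.ndarray,
              distance_km: pd.DataFrame | np.ndarray,
              window_km: tuple[float, float],
              scale: str = "window") -> DdrResult:
    """Distance-decay slope inside one spatial window.

    OLS of ln(similarity) on ln(distance) over unordered sample pairs
    whose distance falls in the half-open window [min, max) km; pairs with
    zero similarity or zero distance cannot enter the log-log fit and are
    dropped (their count is reported).  Fewer than 3 qualifying pairs
    yields an unavailable result.
    """
    sim = np.asarray(similarity, dtype=float)
    dist = np.asarray(distance_km, dtype=float)
    lo, hi = window_km
    if not (0 < lo < hi):
        raise ValueError("window bounds must be positive with min < max")
    iu, ju = np.triu_indices(sim.shape[0], k=1)
    s, d = sim[iu, ju], dist[iu, ju]
    in_window = (d >= lo) & (d < hi) & np.isfinite(s) & np.isfinite(d)
    usable = in_window & (s > 0) & (d > 0)
    n_dropped = int(in_window.sum() - usable.sum())
    if usable.sum() < 3:
        return DdrResult(scale, window_km, float("nan"), float("nan"),
                         float("nan"), int(usable.sum()), n_dropped, False)
    res = stats.linregress(np.log(d[usable]), np.log(s[usable]))
    return DdrResult(scale, window_km, float(res.slope), float(res.intercept),
                     float(res.rvalue**2), int(usable.sum()), n_dropped)


def ddr_all_scales(table: CommunityTable, meta: pd.DataFrame,
                   windows: dict | None = None) -> list[DdrResult]:
    """DDR fits at the local, meso and regional scales.

    Similarity is 1 - Bray-Curtis; all sample pairs are used, filtered
    only by each scale's distance window.
    """
    windows = windows or DEFAULT_DDR_WINDOWS
    meta = meta.set_index("sample_id").loc[table.sample_ids].reset_index()
    bc = bray_curtis_matrix(table).to_numpy()
    sim = 1.0 - bc
    dist = geographic_distance_matrix(meta).to_numpy()
    return [ddr_slope(sim, dist, tuple(win), scale)
            for scale, win in windows.items()]


def ch4_potential_slope(times_h, concentrations) -> float:
    """CH4 production potential from an incubation time series.

    OLS slope of concentration (ug CH4 / g) on time (hours), converted to
    ug CH4 per gram per day.  A negative slope (net consumption) is
    returned as-is with a warning.
    """
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.size < 2:
        raise ValueError("CH4 potential needs at least 2 time points")
    res = stats.linregress(t, c)
    per_day = float(res.slope * 24.0)
    if per_day < 0:
        logger.warning("CH4 potential negative: consumption exceeds production")
    return per_day
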
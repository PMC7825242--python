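"""Core in-memory containers shared by every pipeline stage.

``CommunityTable`` is the universal community input (OTUs in rows, samples
in columns), ``Phylogeny`` wraps a dendropy tree with a cached cophenetic
distance matrix, and sample metadata travels as a validated pandas
DataFrame (see :func:`validate_metadata`).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = ["CommunityTable", "Phylogeny", "validate_metadata", "METADATA_REQUIRED"]

#: columns every metadata table must carry; soil chemistry columns are optional
#: and may contain missing values (never encoded as zero).
METADATA_REQUIRED = ("sample_id", "site_id", "latitude", "longitude", "mat")


@dataclass
class CommunityTable:
    """An OTU x sample abundance matrix with identifiers.

    Parameters
    ----------
    otu_ids, sample_ids
        Unique row / column identifiers.
    counts
        Non-negative matrix of shape ``(n_otus, n_samples)``.
    is_relative
        When True every sample column sums to 1 (within 1e-9).
    """

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    is_relative: bool = False

    def __post_init__(self) -> None:
        self.otu_ids = [str(o) for o in self.otu_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.counts = np.asarray(self.counts, dtype=float)
        if len(set(self.otu_ids)) != len(self.otu_ids):
            dup = _first_duplicate(self.otu_ids)
            raise ValueError(f"duplicate OTU id {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise ValueError(f"duplicate sample id {dup!r}")
        if self.counts.ndim != 2 or self.counts.shape != (
            len(self.otu_ids),
            len(self.sample_ids),
        ):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts contain non-finite values")
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative abundance at OTU {self.otu_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if self.is_relative:
            sums = self.counts.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("relative table columns must sum to 1")

    # -- basic properties ----------------------------------------------

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, is_relative: bool = False) -> "CommunityTable":
        return cls(
            otu_ids=list(map(str, frame.index)),
            sample_ids=list(map(str, frame.columns)),
            counts=frame.to_numpy(dtype=float),
            is_relative=is_relative,
        )

    # -- transformations ------------------------------------------------

    def to_relative(self) -> "CommunityTable":
        """Close each sample column to sum 1 (compositional normalisation)."""
        if self.is_relative:
            return self
        sums = self.counts.sum(axis=0)
        if np.any(sums <= 0):
            j = int(np.flatnonzero(sums <= 0)[0])
            raise ValueError(f"sample {self.sample_ids[j]!r} has zero total abundance")
        return CommunityTable(self.otu_ids, self.sample_ids, self.counts / sums, True)

    def filter_rare(self, min_total_reads: int = 2) -> "CommunityTable":
        """Drop OTUs whose total read count is <= ``min_total_reads``."""
        keep = self.counts.sum(axis=1) > min_total_reads
        return self.subset_otus([o for o, k in zip(self.otu_ids, keep) if k])

    def subset_otus(self, otus) -> "CommunityTable":
        # a row subset of a closed table keeps whole-community fractions
        # but its columns no longer sum to 1, so the flag is dropped
        idx = self._rows(otus)
        return CommunityTable(
            [self.otu_ids[i] for i in idx],
            list(self.sample_ids),
            self.counts[idx, :],
            False,
        )

    def subset_samples(self, samples) -> "CommunityTable":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in pos]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        idx = [pos[s] for s in samples]
        return CommunityTable(
            list(self.otu_ids), [self.sample_ids[j] for j in idx],
            self.counts[:, idx], self.is_relative,
        )

    def _rows(self, otus) -> list[int]:
        pos = {o: i for i, o in enumerate(self.otu_ids)}
        missing = [o for o in otus if o not in pos]
        if missing:
            raise KeyError(f"OTUs not in table: {missing}")
        return [pos[o] for o in otus]

    def require_analysable(self) -> None:
        if self.n_otus < 2 or self.n_samples < 2:
            raise ValueError("analysis requires at least 2 OTUs and 2 samples")


def _first_duplicate(items):
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


@dataclass
class Phylogeny:
    """A phylogenetic tree over OTUs, backed by dendropy.

    Caches the cophenetic (patristic) distance matrix, which is the only
    quantity the nearest-taxon statistics need.
    """

    tree: dendropy.Tree
    _labels: list[str] = field(default=None, repr=False)
    _dist: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        tips = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(tips) < 3:
            raise ValueError("phylogeny must have at least 3 tips")
        if len(set(tips)) != len(tips):
            raise ValueError("duplicate tip labels in phylogeny")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError("phylogeny has an edge without branch length")

    @property
    def tip_labels(self) -> list[str]:
        if self._labels is None:
            self._compute_distances()
        return list(self._labels)

    def cophenetic(self) -> tuple[np.ndarray, list[str]]:
        """Full patristic distance matrix and its tip-label order."""
        if self._dist is None:
            self._compute_distances()
        return self._dist, list(self._labels)

    def _compute_distances(self) -> None:
        pdm = self.tree.phylogenetic_distance_matrix()
        taxa = sorted(pdm.taxon_iter(), key=lambda t: t.label)
        n = len(taxa)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
        self._labels = [t.label for t in taxa]
        self._dist = d

    def distance_submatrix(self, otus) -> np.ndarray:
        d, labels = self.cophenetic()
        pos = {l: i for i, l in enumerate(labels)}
        missing = [o for o in otus if o not in pos]
        if missing:
            raise KeyError(f"OTUs missing from phylogeny: {missing}")
        idx = np.array([pos[o] for o in otus])
        return d[np.ix_(idx, idx)]

    def check_covers(self, otus) -> None:
        tips = set(self.tip_labels)
        missing = sorted(set(otus) - tips)
        if missing:
            raise ValueError(f"phylogeny lacks tips for OTUs: {missing}")

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    @classmethod
    def from_newick_string(cls, s: str) -> "Phylogeny":
        tree = dendropy.Tree.get(
            data=s, schema="newick", suppress_internal_node_taxa=True
        )
        return cls(tree)


def validate_metadata(meta: pd.DataFrame, table: CommunityTable | None = None) -> pd.DataFrame:
    """Validate a sample metadata table.

    Requires the columns in :data:`METADATA_REQUIRED`; checks coordinate
    ranges and, when a community table is supplied, that every sample id is
    present in it.  Missing soil variables stay missing (NaN) — they are
    never imputed to zero.
    """
    missing_cols = [c for c in METADATA_REQUIRED if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata lacks required columns: {missing_cols}")
    meta = meta.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    meta["site_id"] = meta["site_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r} in metadata")
    lat, lon = meta["latitude"].astype(float), meta["longitude"].astype(float)
    if (lat.abs() > 90).any():
        raise ValueError("latitude outside [-90, 90]")
    if (lon.abs() > 180).any():
        raise ValueError("longitude outside [-180, 180]")
    if table is not None:
        unknown = sorted(set(meta["sample_id"]) - set(table.sample_ids))
        if unknown:
            raise ValueError(f"metadata samples absent from community table: {unknown}")
    return meta
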
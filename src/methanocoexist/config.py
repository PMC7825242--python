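"""Pipeline configuration and seeded randomness.

All tunables of the pipeline live in one dataclass so that a run is fully
described by a YAML file plus a master seed.  Every stage derives its own
random generator from the master seed through a named substream, so re-running
a single stage in isolation reproduces exactly the draws it saw inside a full
run.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = ["PipelineConfig", "substream_seed", "substream_rng"]


def substream_seed(master_seed: int, name: str) -> int:
    """Derive a stage-specific child seed from the master seed.

    The child is a deterministic function of ``(master_seed, name)`` and is
    always below 2**31 so it can be handed to any RNG API.
    """
    return (int(master_seed) ^ zlib.crc32(name.encode("utf-8"))) % (2**31 - 1)


def substream_rng(master_seed: int, name: str) -> np.random.Generator:
    """A :class:`numpy.random.Generator` for the named pipeline stage."""
    return np.random.default_rng(substream_seed(master_seed, name))


@dataclass
class PipelineConfig:
    """All tunables of the coexistence pipeline, with field defaults.

    The defaults reproduce the analysis settings of the study design this
    package implements: 1000 positive / 1000 negative initial edges per
    similarity measure, 1000 renormalized permutations and 1000 bootstraps
    per edge, Benjamini-Hochberg control at alpha = 0.05, 999 phylogenetic
    randomizations, a |betaNTI| cutoff of 2 and the frequency thresholds
    (1, 3, 10, 20) separating the five coexistence groups.
    """

    # network inference
    n_pos_edges: int = 1000
    n_neg_edges: int = 1000
    n_perm: int = 1000
    n_boot: int = 1000
    alpha: float = 0.05
    bootstrap_veto: float = 0.95
    kl_pseudocount: float | None = None  # None -> half smallest nonzero rel.ab.

    # phylogenetic null models
    n_null_phylo: int = 999
    beta_nti_cutoff: float = 2.0
    symmetric_cutoff: bool = False  # True: |z| >= cutoff; False: z > c or z <= -c
    # label-shuffle pool for per-group assembly: the group's own tips
    # (pruned-tree convention) or all tips of the table
    assembly_pool: str = "group"

    # edge classification
    group_thresholds: tuple[int, int, int, int] = (1, 3, 10, 20)

    # OTU table sparsity filter: drop OTUs whose total reads are <= this
    min_total_reads: int = 2
    # within a site, OTUs present in fewer samples than this are not scored
    site_min_prevalence: int = 3

    # distance-decay windows, km
    ddr_windows: dict = field(
        default_factory=lambda: {
            "local": (0.001, 0.1),
            "meso": (0.1, 50.0),
            "regional": (100.0, 3500.0),
        }
    )

    # GeoChip preprocessing
    snr_min: float = 2.0
    geochip_constant: float = 1e6
    detection_min: int = 2

    # random forest
    n_trees: int = 500
    n_perm_sig: int = 100

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pos_edges", "n_neg_edges", "n_perm", "n_boot",
                     "n_null_phylo", "n_trees", "n_perm_sig"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        t = tuple(self.group_thresholds)
        if list(t) != sorted(t) or len(set(t)) != len(t):
            raise ValueError("group thresholds must be strictly increasing")
        self.group_thresholds = t

    @classmethod
    def scaled(cls, seed: int = 0, **overrides) -> "PipelineConfig":
        """Settings for the reduced test scale (6 sites x 8 samples).

        The full-scale defaults assume tables with tens of thousands of
        OTU pairs, where 1000-edge candidate windows per measure are
        selective.  A 6 x 8-sample instance has ~2000 pairs, so the
        windows scale to 300 edges (the same few-percent admission rate)
        and the within-site prevalence filter tightens to 5 of 8 samples
        (correlations over sparser profiles are not interpretable at
        n = 8).  Everything else keeps the full-scale defaults.
        """
        params = dict(n_pos_edges=300, n_neg_edges=300,
                      site_min_prevalence=5, seed=seed)
        params.update(overrides)
        return cls(**params)

    def rng(self, stage: str) -> np.random.Generator:
        """Seeded generator for a named stage of this configured run."""
        return substream_rng(self.seed, stage)

    def child_seed(self, stage: str) -> int:
        return substream_seed(self.seed, stage)

    # -- serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["group_thresholds"] = list(self.group_thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "group_thresholds" in d:
            d["group_thresholds"] = tuple(d["group_thresholds"])
        if "ddr_windows" in d:
            d["ddr_windows"] = {k: tuple(v) for k, v in d["ddr_windows"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
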
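"""Cross-network edge classification into coexistence groups.

Edges recovered in many local networks represent common coexistence,
edges confined to one or a few sites endemic coexistence.  Edge identity
is the unordered OTU pair, ignoring sign (a pair positive at one site and
negative at another still counts as one coexistence link); the frequency
of a link is the number of local networks that contain it.  Frequencies
are binned into five groups — always endemic (1 network), conditionally
endemic (2-3), moderate (4-10), conditionally common (11-20) and always
common (>20) — and the OTUs participating in the two common groups form
the candidate keystone set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

__all__ = [
    "GROUP_NAMES", "EdgeFrequency", "CoexistenceGroups",
    "canonical_edge_id", "edge_frequencies", "classify_edges",
    "group_proportions", "related_otus", "keystone_set",
]

GROUP_NAMES = (
    "always_endemic",
    "conditionally_endemic",
    "moderate",
    "conditionally_common",
    "always_common",
)


def canonical_edge_id(otu_a: str, otu_b: str) -> tuple[str, str]:
    """Unordered pair identity: lexicographically sorted, sign-free."""
    if otu_a == otu_b:
        raise ValueError(f"self-pair {otu_a!r} is not an edge")
    return (otu_a, otu_b) if otu_a < otu_b else (otu_b, otu_a)


@dataclass
class EdgeFrequency:
    edge_id: tuple[str, str]
    frequency: int
    networks: list[str]

    def __post_init__(self) -> None:
        if self.frequency != len(self.networks):
            raise ValueError("frequency must equal the number of networks")
        if self.frequency < 1:
            raise ValueError("an observed edge has frequency >= 1")


@dataclass
class CoexistenceGroups:
    """The five frequency-defined coexistence groups.

    ``edges`` maps group name to its list of :class:`EdgeFrequency`
    records; the groups partition all distinct cross-network edges.
    """

    edges: dict = field(default_factory=dict)
    thresholds: tuple = (1, 3, 10, 20)

    def __post_init__(self) -> None:
        for name in GROUP_NAMES:
            self.edges.setdefault(name, [])

    @property
    def counts(self) -> dict:
        return {g: len(self.edges[g]) for g in GROUP_NAMES}

    @property
    def total_edges(self) -> int:
        return sum(self.counts.values())

    def related_otus(self, group: str) -> set:
        return related_otus(self.edges[group])

    @property
    def keystones(self) -> set:
        return keystone_set(self)

    def summary_rows(self) -> list[dict]:
        """Summary rows: group, edge count, proportion %, related OTUs."""
        props = group_proportions(self)
        return [
            {
                "group": g,
                "edge_count": self.counts[g],
                "relative_proportion_pct": props[g],
                "related_otu_count": len(self.related_otus(g)),
            }
            for g in GROUP_NAMES
        ]


def edge_frequencies(networks: list) -> list[EdgeFrequency]:
    """Occurrence frequency of every distinct edge across local networks.

    An edge counts at most once per network even if a network's edge list
    duplicates it.
    """
    if len(networks) < 2:
        raise ValueError("edge matching needs at least 2 networks")
    seen: dict[tuple, list[str]] = {}
    for net in networks:
        in_this = set()
        for e in net.edges:
            eid = canonical_edge_id(e.otu_a, e.otu_b)
            if eid in in_this:
                logger.warning("network %s lists edge %s more than once",
                               net.network_id, eid)
                continue
            in_this.add(eid)
            seen.setdefault(eid, []).append(net.network_id)
    return [EdgeFrequency(eid, len(nets), nets)
            for eid, nets in sorted(seen.items())]


def classify_edges(frequencies: list[EdgeFrequency],
                   thresholds: tuple = (1, 3, 10, 20),
                   n_networks: int | None = None) -> CoexistenceGroups:
    """Bin edges by frequency into the five coexistence groups.

    With thresholds (t1, t2, t3, t4): frequency == t1 -> always endemic,
    (t1, t2] -> conditionally endemic, (t2, t3] -> moderate,
    (t3, t4] -> conditionally common, > t4 -> always common.
    """
    t1, t2, t3, t4 = thresholds
    if not (t1 < t2 < t3 < t4):
        raise ValueError("thresholds must be strictly increasing")
    groups = CoexistenceGroups(thresholds=tuple(thresholds))
    for rec in frequencies:
        f = rec.frequency
        if f < 1:
            raise ValueError("frequency below 1 is impossible")
        if n_networks is not None and f > n_networks:
            raise ValueError(f"frequency {f} exceeds network count {n_networks}")
        if f <= t1:
            name = "always_endemic"
        elif f <= t2:
            name = "conditionally_endemic"
        elif f <= t3:
            name = "moderate"
        elif f <= t4:
            name = "conditionally_common"
        else:
            name = "always_common"
        groups.edges[name].append(rec)
    return groups


def group_proportions(groups_or_counts) -> dict:
    """Relative proportion (%) of each group's edge count, to 2 decimals."""
    if isinstance(groups_or_counts, CoexistenceGroups):
        counts = groups_or_counts.counts
    else:
        counts = dict(zip(GROUP_NAMES, groups_or_counts))
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("no edges to apportion")
    return {g: round(100.0 * counts[g] / total, 2) for g in GROUP_NAMES}


def related_otus(edges: list[EdgeFrequency]) -> set:
    """Union of the endpoints of a group's edges."""
    out: set[str] = set()
    for rec in edges:
        out.update(rec.edge_id)
    return out


def keystone_set(groups: CoexistenceGroups) -> set:
    """OTUs participating in the conditionally or always common links.

    The union is de-duplicated: an OTU present in both common groups is
    one keystone.
    """
    return (groups.related_otus("conditionally_common")
            | groups.related_otus("always_common"))
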
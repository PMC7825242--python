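"""Shared fixtures: toy trees, small tables, and one scaled synthetic run.

The scaled run (6 sites x 8 samples, 64 OTUs) is session-scoped because the
per-site ensemble inference is the expensive step; several test modules
reuse its networks and coexistence groups.
"""

import numpy as np
import pandas as pd
import pytest

from methanocoexist import (CommunityTable, Phylogeny, PipelineConfig,
                            edge_frequencies, infer_network, simulate_dataset)
from methanocoexist.classify import classify_edges
from methanocoexist.pipeline import site_tables

#: frequency thresholds used for 6-network scaled runs (full-scale default
#: is the (1, 3, 10, 20) binning over 39 networks)
SCALED_THRESHOLDS = (1, 2, 3, 4)


@pytest.fixture(scope="session")
def toy_tree() -> Phylogeny:
    """Three tips: A and B are sisters at distance 2, C is 4 from both."""
    return Phylogeny.from_newick_string("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def two_clade_tree() -> Phylogeny:
    """Two clades of four tips each, separated by a deep split."""
    nwk = ("(((A1:1,A2:1):1,(A3:1,A4:1):1):5,"
           "((B1:1,B2:1):1,(B3:1,B4:1):1):5);")
    return Phylogeny.from_newick_string(nwk)


@pytest.fixture
def small_table() -> CommunityTable:
    rng = np.random.default_rng(0)
    counts = rng.multinomial(500, rng.dirichlet(np.ones(6)), size=10).T.astype(float)
    return CommunityTable([f"OTU_{i}" for i in range(1, 7)],
                          [f"s{j}" for j in range(1, 11)], counts)


@pytest.fixture(scope="session")
def scaled_dataset():
    return simulate_dataset(n_sites=6, samples_per_site=8, n_taxa=64,
                            depth=2000, n_common_pairs=8,
                            endemic_pairs_per_site=2, seed=1)


@pytest.fixture(scope="session")
def scaled_networks(scaled_dataset):
    cfg = PipelineConfig.scaled(seed=1)
    tables = site_tables(scaled_dataset.table, scaled_dataset.metadata, cfg)
    return {site: infer_network(t, site, cfg)
            for site, t in sorted(tables.items())}


@pytest.fixture(scope="session")
def scaled_groups(scaled_networks):
    freqs = edge_frequencies(list(scaled_networks.values()))
    return classify_edges(freqs, SCALED_THRESHOLDS,
                          n_networks=len(scaled_networks))


@pytest.fixture
def simple_metadata() -> pd.DataFrame:
    rows = []
    for s, lat in (("S01", 30.0), ("S02", 31.0)):
        for k in range(3):
            rows.append({"sample_id": f"{s}_{k}", "site_id": s,
                         "latitude": lat, "longitude": 115.0 + 0.001 * k,
                         "mat": 20.0 - (lat - 30.0) * 5, "map": 1200.0,
                         "pH": 6.5, "TOC": 12.0, "TN": 1.1, "TP": 0.6,
                         "ch4_potential": np.nan})
    return pd.DataFrame(rows)
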
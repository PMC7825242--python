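"""Readers and writers for the pipeline's on-disk formats.

Community tables are tab-separated with OTUs in rows (first column the OTU
id, header row the sample ids) following the classic QIIME-era orientation;
BIOM is accepted as an alternative input.  Phylogenies are Newick, edge
lists are TSV or GraphML, sample metadata is CSV with empty cells or "NA"
for genuinely missing soil variables, and synthetic ground truth is JSON.

Every writer/reader pair round-trips losslessly (ids exactly, numeric
values to 1e-12); numeric cells are written with 6 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import CommunityTable, Phylogeny, validate_metadata

__all__ = [
    "read_community_table", "write_community_table",
    "read_metadata", "write_metadata",
    "read_newick", "write_newick",
    "read_edge_list", "write_edge_list",
    "read_gene_table", "write_gene_table",
    "read_truth_json", "write_truth_json",
]

_FLOAT_FMT = "%.6g"

_EDGE_COLUMNS = [
    "otu_a", "otu_b", "sign",
    "score_pearson", "score_spearman", "score_braycurtis", "score_kl",
    "p_pearson", "p_spearman", "p_braycurtis", "p_kl",
    "merged_p", "q_value", "network_id",
]


def read_community_table(path, format: str = "tsv") -> CommunityTable:
    """Read an OTU x sample abundance table.

    ``tsv``: first column OTU ids, header row sample ids, tab-separated
    numeric cells.  ``biom``: a BIOM-format table (HDF5 or JSON).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "biom":
        return _read_biom(path)
    if format != "tsv":
        raise ValueError(f"unknown community table format {format!r}")
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty community table file")
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if frame.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found")
    ids = list(map(str, frame.index))
    if len(set(ids)) != len(ids):
        seen, dup = set(), None
        for o in ids:
            if o in seen:
                dup = o
                break
            seen.add(o)
        raise ValueError(f"{path}: duplicate OTU id {dup!r}")
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        try:
            values[:, j] = pd.to_numeric(frame[col], errors="raise")
        except (ValueError, TypeError):
            bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()][0]
            raise ValueError(
                f"{path}: non-numeric abundance at OTU {bad!r}, sample {col!r}"
            ) from None
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path}: negative abundance at OTU {ids[i]!r}, "
            f"sample {frame.columns[j]!r}"
        )
    return CommunityTable(ids, list(map(str, frame.columns)), values)


def _read_biom(path) -> CommunityTable:
    import biom  # ships with scikit-bio

    bt = biom.load_table(str(path))
    dense = np.asarray(bt.matrix_data.todense(), dtype=float)
    return CommunityTable(list(bt.ids("observation")), list(bt.ids("sample")), dense)


def write_community_table(table: CommunityTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index_label="#OTU_ID",
                            float_format=_FLOAT_FMT)


def read_metadata(path, table: CommunityTable | None = None) -> pd.DataFrame:
    meta = pd.read_csv(path, na_values=["NA", ""], keep_default_na=True)
    return validate_metadata(meta, table)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index=False, na_rep="NA", float_format=_FLOAT_FMT)


def read_newick(path, required_otus=None) -> Phylogeny:
    """Read a single Newick tree with branch lengths.

    When ``required_otus`` is given, the tip labels must cover them all;
    missing ids are listed in the error.
    """
    with open(path) as fh:
        text = fh.read()
    try:
        phylo = Phylogeny.from_newick_string(text)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"{path}: could not parse Newick tree: {exc}") from exc
    if required_otus is not None:
        phylo.check_covers(required_otus)
    return phylo


def write_newick(phylo: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(phylo.newick() + "\n")


# -- edge lists ---------------------------------------------------------


def write_edge_list(edges, path, format: str = "tsv") -> None:
    """Write canonicalized edges as TSV or GraphML.

    TSV columns: otu_a, otu_b, sign, the four per-measure scores, the four
    per-measure p-values, merged_p, q_value and network_id.  Edges whose
    endpoints arrive in non-canonical order are written canonically.
    """
    rows = [e.canonical().to_row() for e in edges]
    frame = pd.DataFrame(rows, columns=_EDGE_COLUMNS)
    if format == "tsv":
        frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    elif format == "graphml":
        g = nx.Graph()
        for row in rows:
            attrs = {k: v for k, v in zip(_EDGE_COLUMNS[2:], row[2:])}
            g.add_edge(row[0], row[1], **attrs)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown edge list format {format!r}")


def read_edge_list(path, format: str = "tsv"):
    from .network import EdgeRecord

    if format == "tsv":
        frame = pd.read_csv(path, sep="\t", dtype={"otu_a": str, "otu_b": str,
                                                   "network_id": str})
        rows = frame.to_dict("records")
    elif format == "graphml":
        g = nx.read_graphml(path)
        rows = []
        for a, b, data in g.edges(data=True):
            row = {"otu_a": a, "otu_b": b}
            row.update(data)
            rows.append(row)
    else:
        raise ValueError(f"unknown edge list format {format!r}")
    edges = []
    for row in rows:
        edges.append(
            EdgeRecord(
                otu_a=str(row["otu_a"]), otu_b=str(row["otu_b"]),
                sign=str(row["sign"]),
                scores={m: float(row[f"score_{m}"]) for m in
                        ("pearson", "spearman", "braycurtis", "kl")},
                measure_p={m: float(row[f"p_{m}"]) for m in
                           ("pearson", "spearman", "braycurtis", "kl")},
                merged_p=float(row["merged_p"]),
                q_value=float(row["q_value"]),
                network_id=str(row["network_id"]),
            ).canonical()
        )
    return edges


# -- gene signal tables --------------------------------------------------


def read_gene_table(path):
    """Read a GeoChip-style probe x sample signal TSV.

    Expected columns: ``probe_id``, ``gene`` and one column per sample;
    optionally per-sample SNR columns named ``snr_<sample>``.
    """
    from .contribution import GeneTable

    frame = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene": str})
    if "probe_id" not in frame.columns or "gene" not in frame.columns:
        raise ValueError(f"{path}: gene table needs 'probe_id' and 'gene' columns")
    snr_cols = [c for c in frame.columns if c.startswith("snr_")]
    sample_cols = [c for c in frame.columns
                   if c not in ("probe_id", "gene") and not c.startswith("snr_")]
    signals = frame[sample_cols].to_numpy(dtype=float)
    snr = None
    if snr_cols:
        expected = [f"snr_{s}" for s in sample_cols]
        if snr_cols != expected:
            raise ValueError(f"{path}: SNR columns must mirror sample columns")
        snr = frame[snr_cols].to_numpy(dtype=float)
    return GeneTable(
        probe_ids=list(frame["probe_id"]),
        genes=list(frame["gene"]),
        sample_ids=sample_cols,
        signals=signals,
        snr=snr,
    )


def write_gene_table(gene_table, path) -> None:
    frame = pd.DataFrame(gene_table.signals, columns=gene_table.sample_ids)
    frame.insert(0, "gene", gene_table.genes)
    frame.insert(0, "probe_id", gene_table.probe_ids)
    if gene_table.snr is not None:
        for j, s in enumerate(gene_table.sample_ids):
            frame[f"snr_{s}"] = gene_table.snr[:, j]
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# -- synthetic truth -----------------------------------------------------


def write_truth_json(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)


def read_truth_json(path):
    from .synthetic import SyntheticTruth

    with open(path) as fh:
        return SyntheticTruth.from_dict(json.load(fh))
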
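"""Stage orchestration: chains the analysis modules over a run directory.

Each stage takes in-memory objects, writes its outputs under the run
directory in plain-text formats, and returns what the next stage needs.
The CLI wraps these functions; library users can call them directly or
ignore them and use the per-module APIs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .assembly import group_assembly
from .biogeography import alpha_diversity, ddr_all_scales
from .classify import (GROUP_NAMES, CoexistenceGroups, EdgeFrequency,
                       classify_edges, edge_frequencies)
from .config import PipelineConfig
from .containers import CommunityTable, Phylogeny
from .contribution import (functional_network, group_abundance_features,
                           importance_to_contribution, rf_importance)
from .network import LocalNetwork, infer_network, network_index, TOPOLOGY_ATTRIBUTES
from .synthetic import generate_ch4, generate_gene_signals, simulate_dataset

logger = logging.getLogger(__name__)

_FMT = "%.6g"

#: methanogenesis genes emulated by the synthetic gene-signal generator
DEFAULT_GENES = ["mcrA", "fwdB", "mtbA", "mtbC", "mcrB", "fwdA", "mtaB", "mttB"]


def stage_simulate(outdir, config: PipelineConfig, n_sites=6,
                   samples_per_site=8, n_taxa=48, depth=2000,
                   n_common_pairs=8, endemic_pairs_per_site=2,
                   n_modules=2, module_size=4):
    """Generate a synthetic dataset and write it under the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(
        n_sites=n_sites, samples_per_site=samples_per_site, n_taxa=n_taxa,
        depth=depth, n_common_pairs=n_common_pairs,
        endemic_pairs_per_site=endemic_pairs_per_site,
        n_modules=n_modules, module_size=module_size,
        seed=config.child_seed("simulate"),
    )
    mio.write_community_table(ds.table, outdir / "community.tsv")
    mio.write_metadata(ds.metadata, outdir / "metadata.csv")
    mio.write_newick(ds.phylogeny, outdir / "tree.nwk")
    mio.write_truth_json(ds.truth, outdir / "truth.json")
    logger.info("simulate: %d OTUs x %d samples at %d sites (seed %d)",
                ds.table.n_otus, ds.table.n_samples, n_sites, config.seed)
    return ds


def site_tables(table: CommunityTable, metadata: pd.DataFrame,
                config: PipelineConfig) -> dict:
    """Split a community table into per-site tables ready for inference.

    OTUs with total reads at or below the sparsity cutoff are removed
    globally; within each site, OTUs present in fewer than
    ``site_min_prevalence`` samples are dropped (too sparse to score).
    """
    table = table.filter_rare(config.min_total_reads)
    out = {}
    for site, sub in metadata.groupby("site_id"):
        t = table.subset_samples(sub["sample_id"].tolist())
        prevalent = (t.counts > 0).sum(axis=1) >= config.site_min_prevalence
        t = t.subset_otus([o for o, k in zip(t.otu_ids, prevalent) if k])
        out[str(site)] = t
    return out


def stage_network(table: CommunityTable, metadata: pd.DataFrame,
                  config: PipelineConfig, outdir) -> dict:
    """Infer one co-occurrence network per site; write edges and topology."""
    outdir = Path(outdir)
    netdir = outdir / "networks"
    netdir.mkdir(parents=True, exist_ok=True)
    networks = {}
    for site, t in sorted(site_tables(table, metadata, config).items()):
        if t.n_otus < 2:
            logger.warning("site %s: fewer than 2 usable OTUs, skipped", site)
            continue
        net = infer_network(t, site, config)
        networks[site] = net
        mio.write_edge_list(net.edges, netdir / f"{site}_edges.tsv")
        mio.write_edge_list(net.edges, netdir / f"{site}.graphml",
                            format="graphml")
    topo = pd.DataFrame(
        [{"network_id": s, **networks[s].topology} for s in sorted(networks)]
    )
    if len(networks) >= 3:
        try:
            scores, explained = network_index(
                [networks[s] for s in sorted(networks)])
        except ValueError as exc:
            logger.warning("network index unavailable: %s", exc)
        else:
            topo["network_index"] = scores
            with open(outdir / "network_index.json", "w") as fh:
                json.dump({"pc1_explained_fraction": explained,
                           "index": dict(zip(sorted(networks),
                                             map(float, scores)))},
                          fh, indent=1, sort_keys=True)
    topo.to_csv(outdir / "topology.csv", index=False, float_format=_FMT)
    return networks


def stage_classify(networks: dict, config: PipelineConfig, outdir) -> CoexistenceGroups:
    """Cross-network edge frequencies, five groups, keystones; write tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    freqs = edge_frequencies(list(networks.values()))
    groups = classify_edges(freqs, config.group_thresholds,
                            n_networks=len(networks))
    pd.DataFrame(groups.summary_rows()).to_csv(
        outdir / "coexistence_groups.csv", index=False, float_format=_FMT)
    for g in GROUP_NAMES:
        rows = [{"otu_a": r.edge_id[0], "otu_b": r.edge_id[1],
                 "frequency": r.frequency, "networks": ";".join(r.networks)}
                for r in groups.edges[g]]
        pd.DataFrame(rows, columns=["otu_a", "otu_b", "frequency", "networks"]
                     ).to_csv(outdir / f"group_{g}.tsv", sep="\t", index=False)
    with open(outdir / "keystones.tsv", "w") as fh:
        fh.write("otu_id\n")
        for otu in sorted(groups.keystones):
            fh.write(otu + "\n")
    return groups


def load_groups(outdir) -> CoexistenceGroups:
    """Re-read the per-group edge TSVs written by :func:`stage_classify`."""
    outdir = Path(outdir)
    groups = CoexistenceGroups()
    for g in GROUP_NAMES:
        path = outdir / f"group_{g}.tsv"
        if not path.exists():
            raise FileNotFoundError(path)
        frame = pd.read_csv(path, sep="\t", dtype=str)
        for _, row in frame.iterrows():
            nets = row["networks"].split(";") if row["networks"] else []
            groups.edges[g].append(
                EdgeFrequency((row["otu_a"], row["otu_b"]),
                              int(row["frequency"]), nets))
    return groups


def stage_ch4(metadata: pd.DataFrame, networks: dict, table: CommunityTable,
              truth, config: PipelineConfig, outdir) -> pd.DataFrame:
    """Fill CH4 production potential from the synthetic response model."""
    sites = sorted(networks)
    if len(sites) >= 3:
        scores, _ = network_index([networks[s] for s in sites])
        net_idx = dict(zip(sites, scores))
    else:
        net_idx = {s: float(len(networks[s].edges)) for s in sites}
    alpha = alpha_diversity(table)
    meta_idx = metadata.set_index("sample_id")
    shannon_site = alpha.join(meta_idx["site_id"]).groupby("site_id")["shannon"].mean()
    div = shannon_site.to_dict()
    for s in sites:
        div.setdefault(s, float(shannon_site.mean()))
    meta = generate_ch4(metadata, net_idx, div, truth,
                        seed=config.child_seed("ch4"))
    mio.write_metadata(meta, Path(outdir) / "metadata.csv")
    return meta


def stage_assembly(table: CommunityTable, phylo: Phylogeny,
                   groups: CoexistenceGroups, config: PipelineConfig,
                   outdir, max_pairs: int | None = None) -> dict:
    """Per-group betaNTI distributions and determinism fractions."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results = group_assembly(table, phylo, groups, config, max_pairs=max_pairs)
    rows = []
    for g in GROUP_NAMES:
        r = results[g]
        rows.append({
            "group": g, "available": r.available,
            "determinism_pct": r.fraction_determinism,
            "stochasticity_pct": r.fraction_stochasticity,
            "n_pairs": r.n_pairs, "n_skipped": r.n_skipped,
        })
        if r.available:
            pd.DataFrame({"beta_nti": r.beta_nti_values}).to_csv(
                outdir / f"beta_nti_{g}.tsv", sep="\t", index=False,
                float_format=_FMT)
    pd.DataFrame(rows).to_csv(outdir / "assembly_fractions.csv", index=False,
                              float_format=_FMT)
    return results


def stage_ddr(table: CommunityTable, metadata: pd.DataFrame,
              config: PipelineConfig, outdir) -> list:
    """Alpha diversity and distance-decay slopes at the three scales."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    alpha_diversity(table).to_csv(outdir / "alpha_diversity.csv",
                                  float_format=_FMT)
    results = ddr_all_scales(table, metadata, config.ddr_windows)
    pd.DataFrame([{
        "scale": r.scale, "window_min_km": r.window_km[0],
        "window_max_km": r.window_km[1], "slope": r.slope,
        "intercept": r.intercept, "r_squared": r.r_squared,
        "n_pairs": r.n_pairs, "n_dropped": r.n_dropped,
        "available": r.available,
    } for r in results]).to_csv(outdir / "ddr.csv", index=False,
                                float_format=_FMT)
    return results


def stage_contribute(table: CommunityTable, metadata: pd.DataFrame,
                     groups: CoexistenceGroups, networks: dict,
                     config: PipelineConfig, outdir) -> dict:
    """Random-forest contribution of predictors and coexistence groups."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict = {}
    meta_idx = metadata.set_index("sample_id")
    ch4 = meta_idx["ch4_potential"]

    # group-level model: per-sample group abundances vs per-sample CH4
    feats = group_abundance_features(table, groups)
    usable = ch4.reindex(feats.index).notna()
    if usable.sum() >= 10:
        res = rf_importance(feats.loc[usable], ch4.reindex(feats.index)[usable],
                            n_trees=config.n_trees,
                            seed=config.child_seed("rf-groups"),
                            n_perm_sig=config.n_perm_sig)
        contrib = importance_to_contribution(res)
        out["group_model"] = {
            "importance": res.importance, "p_values": res.p_values,
            "var_explained_pct": res.var_explained_pct,
            "contribution_pct": contrib,
        }
    else:
        logger.warning("contribute: too few CH4 observations for the group model")

    # site-level model: climate + soil + network index + diversity
    sites = sorted(networks)
    if len(sites) >= 10:
        scores, _ = network_index([networks[s] for s in sites])
        alpha = alpha_diversity(table)
        shannon_site = alpha.join(meta_idx["site_id"]).groupby("site_id")["shannon"].mean()
        site_meta = metadata.groupby("site_id").first()
        X = pd.DataFrame({
            "MAT": site_meta["mat"], "MAP": site_meta["map"],
            "TOC": site_meta["TOC"], "TN": site_meta["TN"],
            "TP": site_meta["TP"], "pH": site_meta["pH"],
            "network_index": pd.Series(dict(zip(sites, scores))),
            "shannon": shannon_site,
        }).loc[sites]
        y = metadata.groupby("site_id")["ch4_potential"].first().loc[sites]
        res = rf_importance(X, y, n_trees=config.n_trees,
                            seed=config.child_seed("rf-sites"),
                            n_perm_sig=config.n_perm_sig)
        out["site_model"] = {
            "importance": res.importance, "p_values": res.p_values,
            "var_explained_pct": res.var_explained_pct,
            "contribution_pct": importance_to_contribution(res),
        }
    else:
        logger.warning("contribute: %d sites < 10, site-level model skipped",
                       len(sites))
    with open(outdir / "contribution.json", "w") as fh:
        json.dump(out, fh, indent=1, sort_keys=True)
    return out


def stage_functional(table: CommunityTable, groups: CoexistenceGroups,
                     metadata: pd.DataFrame, config: PipelineConfig, outdir,
                     gene_table=None) -> dict:
    """Keystone-gene functional network and category edge-weight sums."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    keystones = sorted(groups.keystones & set(table.otu_ids))
    if len(keystones) < 2:
        logger.warning("functional: fewer than 2 keystones, stage skipped")
        return {}
    if gene_table is None:
        gene_table = generate_gene_signals(
            table, keystones, DEFAULT_GENES,
            seed=config.child_seed("genes"))
        mio.write_gene_table(gene_table, outdir / "gene_signals.tsv")
    # keystone abundances relative to the whole community, not the subset
    ktable = table.to_relative().subset_otus(keystones)
    net, sums = functional_network(ktable, gene_table, config,
                                   rng=config.rng("functional"))
    mio.write_edge_list(net.edges, outdir / "functional_edges.tsv")
    with open(outdir / "functional_sums.json", "w") as fh:
        json.dump(sums, fh, indent=1, sort_keys=True)
    return sums


def run_all(outdir, config: PipelineConfig, n_sites=6, samples_per_site=8,
            n_taxa=48, depth=2000, n_common_pairs=8,
            endemic_pairs_per_site=2, n_modules=2, module_size=4,
            assembly_max_pairs=60) -> dict:
    """Full synthetic-to-summary pipeline in one call.

    Returns a manifest of the files written.  Deterministic given the
    config seed: identical seeds give byte-identical numeric outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    ds = stage_simulate(outdir, config, n_sites, samples_per_site, n_taxa,
                        depth, n_common_pairs, endemic_pairs_per_site,
                        n_modules, module_size)
    networks = stage_network(ds.table, ds.metadata, config, outdir)
    groups = stage_classify(networks, config, outdir)
    meta = stage_ch4(ds.metadata, networks, ds.table, ds.truth, config, outdir)
    stage_assembly(ds.table, ds.phylogeny, groups, config, outdir,
                   max_pairs=assembly_max_pairs)
    stage_ddr(ds.table, meta, config, outdir)
    stage_contribute(ds.table, meta, groups, networks, config, outdir)
    stage_functional(ds.table, groups, meta, config, outdir)
    manifest = sorted(str(p.relative_to(outdir))
                      for p in outdir.rglob("*") if p.is_file())
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return {"outdir": str(outdir), "files": manifest}
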
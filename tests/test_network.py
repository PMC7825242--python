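"""Ensemble inference: measures, thresholds, ReBoot, Brown, BH, topology."""

import numpy as np
import pytest
from scipy import stats

from methanocoexist import (CommunityTable, PipelineConfig, bh_filter,
                            brown_merge, infer_network, initial_thresholds,
                            intersect_measures, network_index,
                            pairwise_scores, topology_metrics)
from methanocoexist.network import (MEASURES, EdgeRecord, LocalNetwork,
                                    null_pvalue_matrix, reboot_pvalue,
                                    reboot_scores)


def _table(rows, otus=None, samples=None):
    rows = np.asarray(rows, dtype=float)
    otus = otus or [f"O{i}" for i in range(rows.shape[0])]
    samples = samples or [f"s{j}" for j in range(rows.shape[1])]
    return CommunityTable(otus, samples, rows)


class TestPairwiseScores:
    def test_collinear_profiles(self):
        t = _table([[1, 2, 3, 4], [2, 4, 6, 8], [5, 5, 5, 9]])
        for m in ("pearson", "spearman"):
            s = pairwise_scores(t, m)
            assert s[0, 1] == pytest.approx(1.0)

    def test_reversed_profiles_anticorrelate(self):
        # two-taxon community: closure leaves the reversal exact
        t = _table([[1, 2, 3, 4], [4, 3, 2, 1]])
        s = pairwise_scores(t, "pearson")
        assert s[0, 1] == pytest.approx(-1.0)

    def test_identical_relative_profiles_zero_dissimilarity(self):
        # identical across samples after closure
        t = _table([[1, 2, 3, 4], [1, 2, 3, 4], [8, 6, 4, 2]])
        bc = pairwise_scores(t, "braycurtis")
        kl = pairwise_scores(t, "kl")
        assert bc[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert kl[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_constant_profile_skipped_for_correlations(self):
        # row0 keeps a constant share of every sample -> zero variance
        # after closure -> the pair's correlation score is undefined
        t = _table([[5, 10, 15, 20], [1, 2, 3, 4], [4, 8, 12, 16]])
        s = pairwise_scores(t, "pearson")
        assert np.isnan(s).all()
        assert np.isnan(np.diag(s)).all()

    def test_symmetry(self, small_table):
        for m in MEASURES:
            s = pairwise_scores(small_table, m)
            iu = np.triu_indices_from(s, k=1)
            np.testing.assert_allclose(s[iu], s.T[iu], atol=1e-12)


class TestInitialThresholds:
    def _corr_matrix(self, vals):
        n = len(vals)
        # embed pair scores on an (n+1)-node star: pair (0, i+1) gets vals[i]
        m = np.full((n + 1, n + 1), np.nan)
        for i, v in enumerate(vals):
            m[0, i + 1] = m[i + 1, 0] = v
        return m

    def test_top_n_selected(self):
        vals = np.linspace(0.1, 0.9, 15)
        cand = initial_thresholds(self._corr_matrix(vals), "pearson",
                                  n_pos=10, n_neg=10)
        kept = sorted(v for (a, b), d in cand.items()
                      for v in [vals[b - 1]])
        assert len(cand) == 10
        assert min(kept) == pytest.approx(vals[5])  # top 10 of 15

    def test_fewer_available_all_kept(self):
        vals = [0.5, 0.2, -0.3]
        cand = initial_thresholds(self._corr_matrix(vals), "pearson",
                                  n_pos=10, n_neg=10)
        assert len(cand) == 3
        assert cand[(0, 3)] == "-"

    def test_ties_at_cutoff_all_kept(self):
        vals = [0.9, 0.8, 0.5, 0.5, 0.5, 0.1]
        cand = initial_thresholds(self._corr_matrix(vals), "pearson",
                                  n_pos=4, n_neg=0)
        # rank-4 score is 0.5; all three ties enter
        assert len(cand) == 5

    def test_dissimilarity_direction_convention(self):
        vals = [0.1, 0.2, 0.8, 0.9]
        cand = initial_thresholds(self._corr_matrix(vals), "braycurtis",
                                  n_pos=2, n_neg=2)
        assert cand[(0, 1)] == "+" and cand[(0, 2)] == "+"
        assert cand[(0, 3)] == "-" and cand[(0, 4)] == "-"


class TestIntersectMeasures:
    def test_full_support_consistent_direction_kept(self):
        cand = {m: {(0, 1): "+"} for m in MEASURES}
        assert intersect_measures(cand) == {(0, 1): "+"}

    def test_three_of_four_dropped(self):
        cand = {m: {(0, 1): "+"} for m in MEASURES}
        cand["kl"] = {}
        assert intersect_measures(cand) == {}

    def test_direction_conflict_dropped(self):
        cand = {m: {(0, 1): "+"} for m in MEASURES}
        cand["braycurtis"] = {(0, 1): "-"}
        assert intersect_measures(cand) == {}


class TestReboot:
    def test_pvalue_floor_is_pseudocount(self):
        rng = np.random.default_rng(0)
        n = 40
        shared = rng.normal(0, 1, n)
        a = np.exp(shared + rng.normal(0, 0.1, n)) * 50
        b = np.exp(shared + rng.normal(0, 0.1, n)) * 50
        back = np.exp(rng.normal(0, 0.3, (4, n))) * 30
        t = _table(np.vstack([a, b, back]))
        obs, null, boot = reboot_scores(t, (0, 1), "pearson", 1000, 200, rng)
        p = reboot_pvalue(obs, null, boot, "pearson", "+", 1000)
        assert p == pytest.approx(1.0 / 1001.0)

    def test_low_n_perm_rejected(self):
        with pytest.raises(ValueError):
            reboot_pvalue(0.5, np.zeros(50), np.zeros(50), "pearson", "+", 50)

    def test_planted_pair_detected_in_most_replicates(self):
        rng = np.random.default_rng(3)
        hits = 0
        for rep in range(10):
            n = 40
            shared = rng.normal(0, 1, n)
            a = np.exp(2.2 * shared + rng.normal(0, 1, n)) * 20
            b = np.exp(2.2 * shared + rng.normal(0, 1, n)) * 20
            back = np.exp(rng.normal(0, 1, (6, n))) * 20
            t = _table(np.vstack([a, b, back]))
            obs, null, boot = reboot_scores(t, (0, 1), "spearman", 500, 200, rng)
            p = reboot_pvalue(obs, null, boot, "spearman", "+", 500)
            hits += p <= 0.01
        assert hits >= 9

    def test_null_pvalues_uniform(self):
        """Permutation p for an independent pair is U(0,1) (KS at 0.01)."""
        rng = np.random.default_rng(42)
        ps = []
        for rep in range(200):
            counts = rng.multinomial(
                2000, rng.dirichlet(np.ones(20)), size=12).T.astype(float)
            t = _table(counts)
            obs, null, boot = reboot_scores(t, (0, 1), "pearson", 200, 200, rng)
            ps.append(reboot_pvalue(obs, null, boot, "pearson", "+", 200,
                                    veto_fraction=0.0))
        ks = stats.kstest(np.asarray(ps), "uniform")
        assert ks.pvalue > 0.01

    def test_bootstrap_veto_is_conservative(self):
        """With the veto on, null pairs are rejected at most at ~2*alpha
        even when the direction is chosen from the observed sign."""
        rng = np.random.default_rng(7)
        rej = 0
        for rep in range(100):
            counts = rng.multinomial(
                2000, rng.dirichlet(np.ones(20)), size=12).T.astype(float)
            t = _table(counts)
            obs, null, boot = reboot_scores(t, (0, 1), "pearson", 200, 200, rng)
            d = "+" if obs >= 0 else "-"
            p = reboot_pvalue(obs, null, boot, "pearson", d, 200)
            rej += p <= 0.05
        assert rej <= 15


class TestBrownMerge:
    def test_independent_limit_matches_fisher(self):
        p = brown_merge([0.05] * 4, None)
        t = -2 * 4 * np.log(0.05)
        assert p == pytest.approx(stats.chi2.sf(t, 8), rel=1e-12)
        assert p == pytest.approx(0.00234, abs=1e-4)

    def test_all_ones_merge_to_one(self):
        assert brown_merge([1.0] * 4, None) == pytest.approx(1.0)

    def test_perfect_dependence_recovers_common_p(self):
        # identical null p columns -> effective df 2 -> merged approaches
        # the common p as the covariance estimate converges
        rng = np.random.default_rng(0)
        col = rng.uniform(1e-9, 1, 40000)
        npm = np.column_stack([col] * 4)
        for p in (0.01, 0.2, 0.6):
            merged = brown_merge([p] * 4, npm)
            assert merged == pytest.approx(p, rel=0.1)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            brown_merge([0.0, 0.1, 0.1, 0.1], None)

    def test_estimated_covariance_between_fisher_and_identity(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(size=500)
        npm = np.column_stack([np.clip(base + rng.uniform(-0.1, 0.1, 500),
                                       1e-6, 1) for _ in range(4)])
        merged = brown_merge([0.05] * 4, npm)
        fisher = brown_merge([0.05] * 4, None)
        # dependence pulls the merged p away from the Fisher value toward
        # the neighbourhood of the common p
        assert fisher < merged
        assert 0.01 < merged < 0.15


class TestBhFilter:
    def _edges(self, ps):
        return [EdgeRecord("A", f"B{i}", "+", {}, {}, merged_p=p)
                for i, p in enumerate(ps)]

    def test_worked_example(self):
        edges = self._edges([0.01, 0.02, 0.03, 0.04])
        kept = bh_filter(edges, alpha=0.05)
        assert len(kept) == 4
        assert all(e.q_value == pytest.approx(0.04) for e in kept)

    def test_large_ps_rejected(self):
        assert bh_filter(self._edges([0.5, 0.9]), alpha=0.05) == []

    def test_single_p_identity(self):
        kept = bh_filter(self._edges([0.04]), alpha=0.05)
        assert len(kept) == 1 and kept[0].q_value == pytest.approx(0.04)

    def test_empty_input(self):
        assert bh_filter([], alpha=0.05) == []


def _net(edges, net_id="N"):
    nodes = {n for a, b, *_ in edges for n in (a, b)}
    recs = [EdgeRecord(a, b, s[0] if s else "+", {}, {}, 0.01)
            for a, b, *s in edges]
    n = LocalNetwork(net_id, nodes, recs)
    n.topology = topology_metrics(n)
    return n


class TestTopology:
    def test_triangle(self):
        n = _net([("a", "b"), ("b", "c"), ("a", "c")])
        t = n.topology
        assert t["avg_clustering"] == pytest.approx(1.0)
        assert t["diameter"] == 1.0
        assert t["char_path_length"] == pytest.approx(1.0)
        assert t["edge_number"] == 3.0 and t["node_number"] == 3.0

    def test_path_graph(self):
        t = _net([("a", "b"), ("b", "c")]).topology
        assert t["avg_clustering"] == 0.0
        assert t["diameter"] == 2.0
        assert t["char_path_length"] == pytest.approx(4.0 / 3.0)

    def test_two_disjoint_triangles(self):
        t = _net([("a", "b"), ("b", "c"), ("a", "c"),
                  ("x", "y"), ("y", "z"), ("x", "z")]).topology
        assert t["diameter"] == 1.0  # largest component only
        assert t["modularity"] == pytest.approx(0.5)  # 2*(3/6 - (6/12)^2)

    def test_sign_counts(self):
        t = _net([("a", "b", "+"), ("b", "c", "-"), ("c", "d", "-")]).topology
        assert t["positive_count"] == 1.0 and t["negative_count"] == 2.0

    def test_empty_network_all_zero(self):
        n = LocalNetwork("E", set(), [])
        assert all(v == 0.0 for v in topology_metrics(n).values())

    def test_relabeling_invariance(self):
        edges = [("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")]
        t1 = _net(edges).topology
        ren = {"a": "w", "b": "x", "c": "y", "d": "z"}
        t2 = _net([(ren[a], ren[b]) for a, b in edges]).topology
        assert t1 == t2


class TestNetworkIndex:
    def _nets_with_edges(self, edge_counts):
        nets = []
        for k, m in enumerate(edge_counts):
            edges = [(f"n{i}", f"n{i+1}") for i in range(m)]
            nets.append(_net(edges, f"N{k}"))
        return nets

    def test_rank_order_follows_edge_number(self):
        nets = self._nets_with_edges([2, 8, 4, 6])
        scores, _ = network_index(nets)
        assert list(np.argsort(scores)) == [0, 2, 3, 1]

    def test_identical_networks_identical_index(self):
        nets = self._nets_with_edges([4, 4, 4]) + self._nets_with_edges([7])
        scores, _ = network_index(nets)
        assert scores[0] == pytest.approx(scores[1], abs=1e-9)
        assert scores[0] == pytest.approx(scores[2], abs=1e-9)

    def test_needs_three_networks(self):
        with pytest.raises(ValueError):
            network_index(self._nets_with_edges([3, 4]))


class TestInferNetwork:
    def test_oracle_equivalence_small_instance(self):
        """Brute-force enumeration over all 15 pairs of a 6-OTU table
        reproduces the pipeline's retained edge set at the same seed."""
        rng = np.random.default_rng(5)
        shared = rng.normal(0, 1, 10)
        rows = [np.exp(2.0 * shared + rng.normal(0, 0.4, 10)) * 30,
                np.exp(2.0 * shared + rng.normal(0, 0.4, 10)) * 30]
        rows += [np.exp(rng.normal(0, 0.8, 10)) * 30 for _ in range(4)]
        t = _table(np.vstack(rows))
        cfg = PipelineConfig(n_perm=200, n_boot=200, n_pos_edges=1000,
                             n_neg_edges=1000, seed=11)

        net = infer_network(t, "X", cfg)

        # independent re-derivation: direct sorting for thresholds, explicit
        # direction/intersection rules, hand-written BH step-up
        cand = {}
        for m in MEASURES:
            s = pairwise_scores(t, m)
            cand[m] = initial_thresholds(s, m, 1000, 1000)
        final = {}
        for pair in set.intersection(*(set(c) for c in cand.values())):
            dirs = {cand[m][pair] for m in MEASURES}
            if len(dirs) == 1:
                final[pair] = dirs.pop()
        rng2 = cfg.rng("network:X")
        rel = t.to_relative()
        merged = {}
        for pair in sorted(final):
            shared_draws = {}
            pvals, nulls = {}, {}
            for m in MEASURES:
                obs, null, boot = reboot_scores(rel, pair, m, 200, 200, rng2,
                                                _shared=shared_draws)
                nulls[m] = null
                pvals[m] = reboot_pvalue(obs, null, boot, m, final[pair], 200)
            npm = null_pvalue_matrix(nulls, {m: final[pair] for m in MEASURES},
                                     200)
            merged[pair] = brown_merge([pvals[m] for m in MEASURES], npm)
        # BH step-up by hand
        items = sorted(merged.items(), key=lambda kv: kv[1])
        m_tot = len(items)
        cut = 0
        for k, (pair, p) in enumerate(items, start=1):
            if p <= 0.05 * k / m_tot:
                cut = k
        expected = {tuple(sorted((t.otu_ids[i], t.otu_ids[j])))
                    for (i, j), _ in items[:cut]}
        got = {e.pair for e in net.edges}
        assert got == expected
        assert ("O0", "O1") in got  # the planted association survives

    def test_independent_data_yields_few_edges(self):
        rng = np.random.default_rng(9)
        counts = rng.multinomial(3000, rng.dirichlet(np.ones(15)),
                                 size=10).T.astype(float)
        t = _table(counts)
        cfg = PipelineConfig(n_perm=300, n_boot=300, seed=2)
        net = infer_network(t, "null", cfg)
        assert len(net.edges) <= 3  # ~alpha-level leakage on 105 pairs

    def test_seed_determinism(self, small_table):
        cfg = PipelineConfig(n_perm=200, n_boot=200, seed=4)
        n1 = infer_network(small_table, "S", cfg)
        n2 = infer_network(small_table, "S", cfg)
        assert [e.pair for e in n1.edges] == [e.pair for e in n2.edges]
        assert [e.merged_p for e in n1.edges] == [e.merged_p for e in n2.edges]


class TestMonotonicity:
    def test_stronger_pair_weight_never_hurts_detection(self):
        """Raising the planted latent weight does not lower the per-site
        detection rate of the planted pair (aggregate over seeds)."""
        from methanocoexist import simulate_dataset
        from methanocoexist.pipeline import site_tables

        rates = []
        for w in (0.8, 1.8):
            det = tot = 0
            for seed in (1, 2, 3):
                ds = simulate_dataset(n_sites=2, samples_per_site=10,
                                      n_taxa=24, depth=2000,
                                      n_common_pairs=2,
                                      endemic_pairs_per_site=0, n_modules=1,
                                      pair_weight=w, seed=seed)
                cfg = PipelineConfig.scaled(seed=seed, n_pos_edges=60,
                                            n_neg_edges=60, n_perm=300,
                                            n_boot=300)
                for site, tab in site_tables(ds.table, ds.metadata, cfg).items():
                    net = infer_network(tab, site, cfg)
                    pairs = {e.pair for e in net.edges}
                    for p in ds.truth.common_pairs:
                        tot += 1
                        det += p in pairs
            rates.append(det / tot)
        assert rates[1] >= rates[0]
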
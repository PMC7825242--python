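"""Nearest-taxon statistics and the determinism/stochasticity partition."""

import numpy as np
import pytest

from methanocoexist import (CommunityTable, PipelineConfig,
                            assembly_fractions, beta_mntd, beta_nti,
                            beta_nti_matrix, group_assembly, mntd, ses_mntd,
                            simulate_dataset)
from methanocoexist.classify import CoexistenceGroups, EdgeFrequency


@pytest.fixture
def toy_dist(toy_tree):
    return toy_tree.distance_submatrix(["A", "B", "C"])


class TestMntd:
    def test_two_sister_taxa(self, toy_dist):
        assert mntd([1, 1, 0], toy_dist) == pytest.approx(2.0)

    def test_three_taxa_mean_of_nearest(self, toy_dist):
        # A->B 2, B->A 2, C->A 4 : mean 8/3
        assert mntd([1, 1, 1], toy_dist) == pytest.approx(8.0 / 3.0)

    def test_abundance_weighting(self, toy_dist):
        # weights (1,1,2)/4 over nearest distances (2,2,4)
        assert mntd([1, 1, 2], toy_dist, weighted=True) == pytest.approx(3.0)

    def test_single_taxon_rejected(self, toy_dist):
        with pytest.raises(ValueError):
            mntd([0, 5, 0], toy_dist)

    def test_brute_force_oracle(self):
        """mntd matches exhaustive cophenetic enumeration to 1e-12."""
        from methanocoexist import generate_phylogeny

        phy = generate_phylogeny(8, 1.0, seed=6)
        d = phy.distance_submatrix(phy.tip_labels)
        rng = np.random.default_rng(0)
        for _ in range(20):
            ab = (rng.random(8) < 0.6) * rng.exponential(1, 8)
            if (ab > 0).sum() < 2:
                continue
            idx = np.nonzero(ab > 0)[0]
            nearest = [min(d[i, j] for j in idx if j != i) for i in idx]
            assert mntd(ab, d) == pytest.approx(np.mean(nearest), abs=1e-12)
            w = ab[idx] / ab[idx].sum()
            assert mntd(ab, d, weighted=True) == pytest.approx(
                float(np.dot(nearest, w)), abs=1e-12)


class TestSesMntd:
    def test_saturated_community_degenerate(self, toy_dist):
        z = ses_mntd([1, 1, 1], toy_dist, n_null=99,
                     rng=np.random.default_rng(0))
        assert np.isnan(z)

    def test_null_self_calibration(self):
        from methanocoexist import generate_phylogeny

        phy = generate_phylogeny(30, 1.0, seed=1)
        d = phy.distance_submatrix(phy.tip_labels)
        rng = np.random.default_rng(2)
        zs = []
        for _ in range(200):
            ab = (rng.random(30) < 0.4) * rng.exponential(1, 30)
            if (ab > 0).sum() >= 2:
                zs.append(ses_mntd(ab, d, n_null=199, rng=rng))
        assert abs(np.nanmean(zs)) < 0.3

    def test_clade_confined_community_is_clustered(self, two_clade_tree):
        labels = two_clade_tree.tip_labels
        d = two_clade_tree.distance_submatrix(labels)
        ab = np.array([1.0 if l.startswith("A") else 0.0 for l in labels])
        neg = 0
        for seed in range(20):
            z = ses_mntd(ab, d, n_null=199, rng=np.random.default_rng(seed))
            neg += z < 0
        assert neg >= 19


class TestBetaMntd:
    def test_identical_communities_zero(self, toy_dist):
        assert beta_mntd([1, 2, 3], [1, 2, 3], toy_dist) == 0.0

    def test_single_cross_distance(self, toy_dist):
        assert beta_mntd([1, 0, 0], [0, 1, 0], toy_dist) == pytest.approx(2.0)

    def test_hand_computed_mixture(self, toy_dist):
        # {A} vs {B, C} equal weights: 0.5*[2 + (0.5*2 + 0.5*4)] = 2.5
        assert beta_mntd([1, 0, 0], [0, 1, 1], toy_dist) == pytest.approx(2.5)

    def test_symmetry(self, toy_dist):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x, y = rng.exponential(1, 3), rng.exponential(1, 3)
            assert beta_mntd(x, y, toy_dist) == pytest.approx(
                beta_mntd(y, x, toy_dist), abs=1e-12)

    def test_empty_community_rejected(self, toy_dist):
        with pytest.raises(ValueError):
            beta_mntd([0, 0, 0], [1, 0, 0], toy_dist)

    def test_brute_force_oracle(self):
        """Weighted betaMNTD matches a naive double loop to 1e-12."""
        from methanocoexist import generate_phylogeny

        phy = generate_phylogeny(8, 1.0, seed=9)
        d = phy.distance_submatrix(phy.tip_labels)
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = (rng.random(8) < 0.5) * rng.exponential(1, 8)
            y = (rng.random(8) < 0.5) * rng.exponential(1, 8)
            if (x > 0).sum() == 0 or (y > 0).sum() == 0:
                continue
            ix, iy = np.nonzero(x > 0)[0], np.nonzero(y > 0)[0]
            wx, wy = x[ix] / x[ix].sum(), y[iy] / y[iy].sum()
            t1 = sum(w * min(d[i, j] for j in iy) for i, w in zip(ix, wx))
            t2 = sum(w * min(d[j, i] for i in ix) for j, w in zip(iy, wy))
            assert beta_mntd(x, y, d) == pytest.approx(0.5 * (t1 + t2),
                                                       abs=1e-12)


class TestBetaNti:
    def test_identical_communities_degenerate(self, toy_dist):
        z = beta_nti([1, 1, 0], [1, 1, 0], toy_dist, n_null=99,
                     rng=np.random.default_rng(0))
        assert np.isnan(z)

    def test_null_calibration_95pct_within_2(self):
        from methanocoexist import generate_phylogeny

        phy = generate_phylogeny(40, 1.0, seed=5)
        d = phy.distance_submatrix(phy.tip_labels)
        rng = np.random.default_rng(0)
        zs = []
        for _ in range(200):
            a = (rng.random(40) < 0.4) * rng.exponential(1, 40)
            b = (rng.random(40) < 0.4) * rng.exponential(1, 40)
            if (a > 0).sum() and (b > 0).sum():
                zs.append(beta_nti(a, b, d, n_null=199, rng=rng))
        frac = np.mean(np.abs(zs) <= 2)
        assert 0.90 <= frac <= 0.99
        assert abs(np.mean(zs)) < 0.3
        assert 0.7 <= np.std(zs) <= 1.3

    def test_label_shuffle_preserves_distance_multiset(self):
        from methanocoexist import generate_phylogeny

        phy = generate_phylogeny(12, 1.0, seed=2)
        d = phy.distance_submatrix(phy.tip_labels)
        rng = np.random.default_rng(0)
        perm = rng.permutation(12)
        dp = d[np.ix_(perm, perm)]
        assert np.allclose(np.sort(d[np.triu_indices(12, 1)]),
                           np.sort(dp[np.triu_indices(12, 1)]))

    def test_opposite_niche_extremes_deterministic(self, two_clade_tree):
        """Communities confined to opposite clades (the variable-selection
        limit) produce strongly positive z."""
        labels = two_clade_tree.tip_labels
        d = two_clade_tree.distance_submatrix(labels)
        a = np.array([1.0 if l.startswith("A") else 0.0 for l in labels])
        b = np.array([1.0 if l.startswith("B") else 0.0 for l in labels])
        pos = 0
        for seed in range(10):
            z = beta_nti(a, b, d, n_null=299, rng=np.random.default_rng(seed))
            pos += z > 2
        assert pos >= 8


class TestAssemblyFractions:
    def test_half_and_half(self):
        det, sto = assembly_fractions([3, -3, 0, 1])
        assert det == 50.0 and sto == 50.0

    def test_all_stochastic(self):
        det, sto = assembly_fractions([-1.9, 0.0, 1.9])
        assert det == 0.0 and sto == 100.0

    def test_literal_boundary_asymmetry(self):
        det_neg, _ = assembly_fractions([-2.0])
        det_pos, _ = assembly_fractions([2.0])
        assert det_neg == 100.0   # z <= -2 is deterministic
        assert det_pos == 0.0     # z == +2 is stochastic (rule is z > 2)

    def test_symmetric_option(self):
        det, _ = assembly_fractions([2.0], symmetric=True)
        assert det == 100.0

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            assembly_fractions([np.nan, np.nan])


def _groups_from_pairs(common, endemic):
    g = CoexistenceGroups()
    g.edges["always_common"] = [
        EdgeFrequency(tuple(sorted(p)), 5, [f"N{i}" for i in range(5)])
        for p in common]
    g.edges["always_endemic"] = [
        EdgeFrequency(tuple(sorted(p)), 1, ["N0"]) for p in endemic]
    return g


class TestGroupAssembly:
    def test_identical_groups_identical_fractions(self):
        ds = simulate_dataset(n_sites=3, samples_per_site=6, n_taxa=32,
                              depth=800, n_common_pairs=4,
                              endemic_pairs_per_site=0, n_modules=0, seed=2)
        pairs = ds.truth.common_pairs
        g1 = _groups_from_pairs(pairs, [])
        g2 = _groups_from_pairs(pairs, [])
        cfg = PipelineConfig(seed=5, n_null_phylo=99)
        r1 = group_assembly(ds.table, ds.phylogeny, g1, cfg, max_pairs=40)
        r2 = group_assembly(ds.table, ds.phylogeny, g2, cfg, max_pairs=40)
        assert r1["always_common"].fraction_determinism == \
            r2["always_common"].fraction_determinism

    def test_too_small_group_flagged_unavailable(self, toy_tree):
        table = CommunityTable(["A", "B", "C"], ["s1", "s2"],
                               [[1, 2], [3, 1], [0, 5]])
        g = CoexistenceGroups()
        res = group_assembly(table, toy_tree, g,
                             PipelineConfig(seed=0, n_null_phylo=49))
        assert all(not r.available for r in res.values())

    def test_skipped_pairs_counted(self, toy_tree):
        # one sample has no abundance for the group's OTUs
        table = CommunityTable(["A", "B", "C"], ["s1", "s2", "s3"],
                               [[1, 0, 2], [3, 0, 1], [2, 1, 1]])
        g = _groups_from_pairs([("A", "B")], [])
        res = group_assembly(table, toy_tree, g,
                             PipelineConfig(seed=0, n_null_phylo=49))
        r = res["always_common"]
        assert r.n_skipped >= 2  # pairs involving the empty sample s2

    def test_niche_determinism_dial_monotone(self):
        """Stronger trait signal and narrower niches raise the deterministic
        fraction among samples from the thermal extremes (3-point grid)."""
        fracs = []
        for trait, sigma in ((0.0, 40.0), (1.0, 5.0), (4.0, 2.0)):
            vals = []
            for seed in (3, 4):
                ds = simulate_dataset(
                    n_sites=6, samples_per_site=6, n_taxa=48, depth=600,
                    n_common_pairs=0, endemic_pairs_per_site=0, n_modules=0,
                    trait_signal=trait, niche_breadth=sigma,
                    baseline_sd=0.0, noise_sd=1.0, seed=seed)
                site_mat = ds.metadata.groupby("site_id")["mat"].first()
                cold = site_mat.idxmin()
                warm = site_mat.idxmax()
                keep = ds.metadata[ds.metadata.site_id.isin([cold, warm])]
                sub = ds.table.subset_samples(keep["sample_id"].tolist())
                z, _ = beta_nti_matrix(sub, ds.phylogeny, n_null=199,
                                       rng=np.random.default_rng(seed))
                det, _ = assembly_fractions(z)
                vals.append(det)
            fracs.append(np.mean(vals))
        assert fracs[0] <= fracs[1] <= fracs[2]
        assert fracs[2] > fracs[0]
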
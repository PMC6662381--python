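import warnings

import numpy as np
import pandas as pd
import pytest

from phylomorph import mk, simulate, stats
from phylomorph.tree import read_newick


def star_tree(n, depth=1.0):
    return read_newick("(" + ",".join(f"s{i}:{depth}" for i in range(n)) + "):0;")


def ordinary_manova_trace(Y, groups):
    levels = sorted(set(groups.tolist()))
    n = len(groups)
    X = np.zeros((n, len(levels)))
    for j, g in enumerate(levels):
        X[groups == g, j] = 1.0
    H = X @ np.linalg.pinv(X.T @ X) @ X.T
    one = np.ones((n, 1))
    H0 = one @ np.linalg.pinv(one.T @ one) @ one.T
    ssm = np.sum(((H - H0) @ Y) ** 2)
    ssr = np.sum(((np.eye(n) - H) @ Y) ** 2)
    sst = np.sum(((np.eye(n) - H0) @ Y) ** 2)
    df1, df2 = len(levels) - 1, n - len(levels)
    return ssm / sst, (ssm / df1) / (ssr / df2)


class TestAncestralStates:
    def test_two_tip_midpointish(self):
        t = read_newick("(A:1,B:1):0;")
        anc = stats.ancestral_states_bm(t, np.array([[0.0], [2.0]]))
        assert anc[0, 0] == pytest.approx(1.0)

    def test_node_covariance_tips_match_phylo_covariance(self):
        t = simulate.simulate_yule_tree(12, seed=1, height=1.0)
        from phylomorph.tree import phylo_covariance

        Call = stats.node_covariance(t)
        C, _ = phylo_covariance(t, t.tip_labels)
        np.testing.assert_allclose(Call[: t.n_tips, : t.n_tips], C, atol=1e-12)

    def test_gls_reconstruction_matches_independent_oracle(self):
        """Re-rooting oracle: the root state equals the GLS mean; a clade
        node's estimate is conditionally shrunk toward its subtree."""
        t = read_newick("((A:1,B:1):1,C:2):0;")
        Y = np.array([[1.0], [3.0], [8.0]])
        anc = stats.ancestral_states_bm(t, Y)
        # brute force: E[x_u | tips] = Cut Ctt^-1 (Y - a) + a
        Call = stats.node_covariance(t)
        Ctt, Cut = Call[:3, :3], Call[3:, :3]
        Ci = np.linalg.inv(Ctt)
        one = np.ones(3)
        a = (one @ Ci @ Y) / (one @ Ci @ one)
        expected = a + Cut @ Ci @ (Y - a)
        np.testing.assert_allclose(anc, expected, atol=1e-12)


class TestPhylogeneticAnova:
    def test_star_tree_equals_ordinary_manova(self):
        n = 24
        t = star_tree(n)
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((n, 4))
        groups = np.array((["a"] * 8) + (["b"] * 8) + (["c"] * 8))
        data = stats.GroupedTraitMatrix(species=list(t.tip_labels), Y=Y, group=groups)
        res = stats.phylogenetic_anova(t, data, n_perm=49, seed=1)
        R2, F = ordinary_manova_trace(Y, groups)
        assert res.F == pytest.approx(F, abs=1e-9)
        assert res.R2 == pytest.approx(R2, abs=1e-9)

    def test_p_value_convention_and_reproducibility(self):
        t = simulate.simulate_yule_tree(30, seed=2, height=1.0)
        Y = simulate.simulate_multivariate_bm(t, p=3, rate=1.0, seed=3).to_numpy()
        g = np.array(["a", "b", "c"])[np.random.default_rng(4).integers(3, size=30)]
        data = stats.GroupedTraitMatrix(species=list(t.tip_labels), Y=Y, group=g)
        r1 = stats.phylogenetic_anova(t, data, n_perm=99, seed=5)
        r2 = stats.phylogenetic_anova(t, data, n_perm=99, seed=5)
        assert r1.p == r2.p and r1.Z == r2.Z
        assert 0 < r1.p <= 1
        assert r1.p * (1 + 99) == pytest.approx(round(r1.p * 100))

    def test_single_group_rejected(self):
        t = star_tree(6)
        data = stats.GroupedTraitMatrix(species=list(t.tip_labels),
                                        Y=np.zeros((6, 2)), group=np.array(["a"] * 6))
        with pytest.raises(ValueError, match="2 groups"):
            stats.phylogenetic_anova(t, data, n_perm=9, seed=0)

    def test_strong_signal_detected(self):
        t = simulate.simulate_yule_tree(40, seed=6, height=1.0)
        rng = np.random.default_rng(7)
        g = np.array(["a"] * 20 + ["b"] * 20)
        Y = rng.standard_normal((40, 3)) * 0.1
        Y[g == "b"] += 5.0
        data = stats.GroupedTraitMatrix(species=list(t.tip_labels), Y=Y, group=g)
        res = stats.phylogenetic_anova(t, data, n_perm=199, seed=8)
        assert res.p <= 0.01


class TestPairwise:
    def test_identical_group_means_zero_distance(self):
        t = star_tree(8)
        Y = np.tile(np.array([[1.0, 2.0]]), (8, 1))
        g = np.array(["a", "b"] * 4)
        data = stats.GroupedTraitMatrix(species=list(t.tip_labels), Y=Y, group=g)
        res = stats.pairwise_group_distances(t, data, n_perm=9, seed=0)
        assert res.distances.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_triangle_inequality(self):
        t = simulate.simulate_yule_tree(30, seed=9, height=1.0)
        Y = simulate.simulate_multivariate_bm(t, p=4, rate=1.0, seed=10).to_numpy()
        g = np.array(["a", "b", "c"])[np.random.default_rng(11).integers(3, size=30)]
        data = stats.GroupedTraitMatrix(species=list(t.tip_labels), Y=Y, group=g)
        res = stats.pairwise_group_distances(t, data, n_perm=9, seed=12)
        D = res.distances.to_numpy()
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-12


class TestSigmaMult:
    def test_constant_traits_zero_rate(self):
        t = star_tree(5)
        assert stats.sigma_mult(t, np.ones((5, 3))) == pytest.approx(0.0, abs=1e-20)

    def test_bm_rate_recovery(self):
        ests = []
        for rep in range(25):
            t = simulate.simulate_yule_tree(300, seed=20 + rep, height=1.0)
            Y = simulate.simulate_multivariate_bm(t, p=4, rate=0.5, seed=50 + rep)
            ests.append(stats.sigma_mult(t, Y))
        ests = np.asarray(ests)
        assert np.all(np.abs(ests - 0.5) / 0.5 < 0.25)
        assert abs(ests.mean() - 0.5) / 0.5 < 0.05

    def test_univariate_reduces_to_gls_estimator(self):
        t = simulate.simulate_yule_tree(50, seed=30, height=1.0)
        Y = simulate.simulate_multivariate_bm(t, p=1, rate=2.0, seed=31).to_numpy()
        from phylomorph.tree import phylo_covariance

        C, order = phylo_covariance(t, t.tip_labels)
        Ci = np.linalg.inv(C)
        one = np.ones(t.n_tips)
        a = (one @ Ci @ Y) / (one @ Ci @ one)
        r = (Y - a).ravel()
        expected = float(r @ Ci @ r) / t.n_tips
        assert stats.sigma_mult(t, Y) == pytest.approx(expected, rel=1e-9)

    def test_rotation_invariance(self):
        t = simulate.simulate_yule_tree(40, seed=32, height=1.0)
        Y = simulate.simulate_multivariate_bm(t, p=4, rate=1.0, seed=33).to_numpy()
        rng = np.random.default_rng(34)
        Q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        assert stats.sigma_mult(t, Y) == pytest.approx(stats.sigma_mult(t, Y @ Q),
                                                       rel=1e-9)


class TestRateComparison:
    def test_equal_rates_ratio_near_one(self):
        t = simulate.simulate_yule_tree(200, seed=40, height=1.0)
        _, tips = simulate.paint_clade_history(t, seed=41)
        Y = simulate.simulate_multivariate_bm(t, p=6, rate=1.0, seed=42)
        g = np.array([tips[l] for l in t.tip_labels])
        data = stats.GroupedTraitMatrix(species=list(t.tip_labels),
                                        Y=Y.to_numpy(), group=g)
        res = stats.compare_rates_by_group(t, data, n_sim=99, seed=43)
        assert res.ratio < 1.6
        assert res.p > 0.05

    def test_fourfold_rates_recovered_and_significant(self):
        t = simulate.simulate_yule_tree(300, seed=44, height=1.0)
        hist, tips = simulate.paint_clade_history(t, seed=45)
        Y = simulate.simulate_multivariate_bm(t, p=6, history=hist,
                                              rate_by_state={"bg": 1.0, "fg": 4.0},
                                              seed=46)
        g = np.array([tips[l] for l in t.tip_labels])
        data = stats.GroupedTraitMatrix(species=list(t.tip_labels),
                                        Y=Y.to_numpy(), group=g)
        res = stats.compare_rates_by_group(t, data, n_sim=199, seed=47)
        assert 3.0 <= res.ratio <= 5.0
        assert res.p <= 0.01
        assert res.sigma2_by_group["fg"] > res.sigma2_by_group["bg"]

    def test_singleton_group_excluded_with_warning(self):
        t = star_tree(7)
        g = np.array(["a"] * 3 + ["b"] * 3 + ["c"])
        Y = np.random.default_rng(48).standard_normal((7, 2))
        data = stats.GroupedTraitMatrix(species=list(t.tip_labels), Y=Y, group=g)
        with pytest.warns(UserWarning, match="excluded"):
            res = stats.compare_rates_by_group(t, data, n_sim=9, seed=49)
        assert set(res.sigma2_by_group) == {"a", "b"}


class TestC1:
    def test_identical_focal_tips_give_one(self):
        t = simulate.simulate_yule_tree(20, seed=50, height=1.0)
        Y = simulate.simulate_multivariate_bm(t, p=3, rate=1.0, seed=51)
        focal = list(t.tip_labels[:4])
        Y.loc[focal] = Y.loc[focal].iloc[0].to_numpy()
        res = stats.convergence_c1(t, Y, focal, n_sim=19, seed=52)
        assert res.C1 == pytest.approx(1.0, abs=1e-12)

    def test_tip_distance_equal_max_ancestral_gives_zero(self):
        t = read_newick("(A:1,B:1):0;")
        # two tips straight from the root: ancestors are on the segment
        # between them, so Dmax equals Dtip
        Y = pd.DataFrame([[0.0, 0.0], [2.0, 0.0]], index=["A", "B"])
        res = stats.convergence_c1(t, Y, ["A", "B"], n_sim=9, seed=53)
        assert res.C1 == pytest.approx(0.0, abs=1e-9)

    def test_translation_rotation_invariance(self):
        t = simulate.simulate_yule_tree(15, seed=54, height=1.0)
        Y = simulate.simulate_multivariate_bm(t, p=3, rate=1.0, seed=55)
        focal = list(t.tip_labels[:5])
        c1a = stats.convergence_c1(t, Y, focal, n_sim=5, seed=56).C1
        rng = np.random.default_rng(57)
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        Y2 = pd.DataFrame(Y.to_numpy() @ Q + 7.0, index=Y.index)
        c1b = stats.convergence_c1(t, Y2, focal, n_sim=5, seed=58).C1
        assert c1a == pytest.approx(c1b, rel=1e-9)

    def test_attraction_regime_detected(self):
        t = simulate.simulate_yule_tree(100, seed=59, height=1.0)
        rng = np.random.default_rng(60)
        focal = list(rng.choice(t.tip_labels, size=8, replace=False))
        Y = simulate.simulate_convergent_traits(t, focal, attractor=np.full(4, 1.5),
                                                strength=4.0, base_rate=1.0, seed=61)
        res = stats.convergence_c1(t, Y, focal, n_sim=99, seed=62)
        assert res.p_C1 <= 0.05


class TestC5:
    def _worked_example(self):
        """10-tip tree with hand-placed 2D traits.

        Focal tips cluster far from everything else; with all ancestral
        estimates pulled toward the grand mean, exactly the three focal
        lineages cross into the focal hull.
        """
        nwk = ("(((f1:1,f2:1):1,(f3:1,o1:1):1):2,"
               "((o2:1,o3:1):1,((o4:0.5,o7:0.5):0.5,(o5:0.5,o6:0.5):0.5):1):2):0;")
        t = read_newick(nwk)
        Y = pd.DataFrame(0.0, index=t.tip_labels, columns=["x", "y"])
        for lab in t.tip_labels:
            if lab.startswith("o"):
                Y.loc[lab] = np.random.default_rng(hash(lab) % 2**31).normal(0, 0.3, 2)
        Y.loc["f1"] = [10.0, 10.0]
        Y.loc["f2"] = [11.0, 10.0]
        Y.loc["f3"] = [10.5, 11.0]
        return t, Y, ["f1", "f2", "f3"]

    def test_hand_counted_crossings(self):
        t, Y, focal = self._worked_example()
        res = stats.convergence_c5(t, Y, focal, dims=2, n_sim=9, seed=63)
        assert res.C5 == 3

    def test_nonfocal_visitor_also_counted(self):
        t, Y, focal = self._worked_example()
        Y.loc["o1"] = [10.5, 10.3]  # non-focal tip parked inside the hull
        res = stats.convergence_c5(t, Y, focal, dims=2, n_sim=9, seed=64)
        assert res.C5 == 4

    def test_degenerate_hull_rejected(self):
        t, Y, focal = self._worked_example()
        Y.loc["f1"] = [10.0, 10.0]
        Y.loc["f2"] = [11.0, 11.0]
        Y.loc["f3"] = [12.0, 12.0]
        with pytest.raises(ValueError, match="degenerate"):
            stats.convergence_c5(t, Y, focal, dims=2, n_sim=9, seed=65)


class TestAllometricConvergence:
    def test_identical_groups_zero_statistic(self):
        rng = np.random.default_rng(70)
        Y = rng.standard_normal((10, 3))
        s = rng.uniform(1, 2, 10)
        data = stats.GroupedTraitMatrix(
            species=[f"q{i}" for i in range(20)],
            Y=np.vstack([Y, Y]), group=np.array(["a"] * 10 + ["b"] * 10),
            size=np.concatenate([s, s]))
        res = stats.allometric_convergence(data, n_perm=19, seed=71)
        assert res.D_small == pytest.approx(0.0, abs=1e-9)
        assert res.D_large == pytest.approx(0.0, abs=1e-9)

    def test_constructed_convergence_detected(self):
        """Trajectories distinct at small size that meet at large size."""
        rng = np.random.default_rng(72)
        ns = 30
        s = np.concatenate([np.linspace(0, 1, ns)] * 2)
        grp = np.array(["arb"] * ns + ["cave"] * ns)
        Y1 = np.column_stack([1 - s[:ns], np.zeros(ns)]) + 0.02 * rng.standard_normal((ns, 2))
        Y2 = np.column_stack([-(1 - s[ns:]), np.zeros(ns)]) + 0.02 * rng.standard_normal((ns, 2))
        data = stats.GroupedTraitMatrix(species=[f"q{i}" for i in range(2 * ns)],
                                        Y=np.vstack([Y1, Y2]), group=grp, size=s)
        res = stats.allometric_convergence(data, n_perm=199, seed=73)
        assert res.statistic > 0
        assert res.p <= 0.05

    def test_requires_two_groups_with_sizes(self):
        data = stats.GroupedTraitMatrix(species=["a", "b", "c"],
                                        Y=np.zeros((3, 2)),
                                        group=np.array(["x", "x", "x"]),
                                        size=np.ones(3))
        with pytest.raises(ValueError, match="two groups"):
            stats.allometric_convergence(data, n_perm=9, seed=74)
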
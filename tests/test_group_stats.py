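import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from rhizofun import (
    FunctionTable,
    anosim,
    auto_group_test,
    partial_eta_squared,
)
from .oracles import anosim_exhaustive, eta2_bruteforce


class TestAutoGroupTest:
    def test_identical_groups(self):
        values = np.tile([1.0, 2.0, 3.0, 4.0, 5.0], 2)
        labels = np.repeat(["a", "b"], 5)
        res = auto_group_test(values, labels)
        assert res.pvalue > 0.95

    def test_two_group_branches(self, rng):
        values = rng.normal(size=10)
        labels = np.repeat(["a", "b"], 5)
        res = auto_group_test(values, labels)
        assert res.test in ("t", "Wilcoxon")
        if res.gate_passed:
            assert res.test == "t"
        else:
            assert res.test == "Wilcoxon"

    def test_four_group_branches(self, rng):
        values = rng.normal(size=20)
        labels = np.repeat(list("abcd"), 5)
        res = auto_group_test(values, labels)
        assert res.test in ("ANOVA", "Kruskal-Wallis")

    def test_heavy_tails_trigger_rank_branch(self):
        # lognormal data with outliers should fail the gate most of the time
        rank_picked = 0
        n_rep = 40
        for rep in range(n_rep):
            r = np.random.default_rng(rep)
            values = np.exp(r.normal(0, 2.5, size=20))
            labels = np.repeat(list("abcd"), 5)
            res = auto_group_test(values, labels)
            rank_picked += res.test == "Kruskal-Wallis"
        assert rank_picked / n_rep > 0.6

    def test_power_at_three_sd_shift(self):
        rejections = 0
        n_rep = 60
        for rep in range(n_rep):
            r = np.random.default_rng(1000 + rep)
            a = r.normal(0.0, 1.0, 5)
            b = r.normal(3.0, 1.0, 5)
            res = auto_group_test(
                np.concatenate([a, b]), np.repeat(["a", "b"], 5)
            )
            rejections += res.pvalue < 0.05
        assert rejections / n_rep >= 0.9

    def test_small_groups_skip_gate(self):
        res = auto_group_test(
            np.array([1.0, 2.0, 3.0, 4.0]), np.array(["a", "a", "b", "b"])
        )
        assert res.gate_passed is None
        assert res.test == "Wilcoxon"
        assert any("gate skipped" in w for w in res.warnings)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            auto_group_test(np.arange(5.0), np.repeat("a", 5))


class TestPartialEtaSquared:
    def test_pure_factor_effect(self, design20):
        plant_effect = design20.frame["plant"].map(
            {"Z.mays": 1.0, "S.davidii": -1.0}
        )
        fn = FunctionTable(pd.DataFrame({"OC": plant_effect.astype(float)}))
        eta = partial_eta_squared(fn, design20)
        assert eta.loc["OC", "plant"] == pytest.approx(1.0)
        assert eta.loc["OC", "system"] == pytest.approx(0.0, abs=1e-10)
        assert eta.loc["OC", "interaction"] == pytest.approx(0.0, abs=1e-10)

    def test_matches_bruteforce_sums_of_squares(self, design20, rng):
        values = pd.DataFrame(
            rng.normal(size=(20, 4)),
            index=design20.sample_ids,
            columns=["OC", "TP", "WC", "pH"],
        )
        eta = partial_eta_squared(values, design20)
        for col in values.columns:
            ep, es, ei = eta2_bruteforce(
                values[col].to_numpy(),
                design20.frame["plant"].to_numpy(),
                design20.frame["system"].to_numpy(),
            )
            assert eta.loc[col, "plant"] == pytest.approx(ep, abs=1e-10)
            assert eta.loc[col, "system"] == pytest.approx(es, abs=1e-10)
            assert eta.loc[col, "interaction"] == pytest.approx(ei, abs=1e-10)

    def test_null_mean_matches_theory(self, design20):
        # under pure noise each eta_p^2 with (1, 16) df has mean 1/17
        sums = np.zeros(3)
        n_rep = 200
        for rep in range(n_rep):
            r = np.random.default_rng(rep)
            values = pd.DataFrame(
                {"y": r.normal(size=20)}, index=design20.sample_ids
            )
            eta = partial_eta_squared(values, design20)
            sums += eta.loc["y"].to_numpy()
        means = sums / n_rep
        assert np.allclose(means, 1 / 17, atol=0.02)

    def test_affine_invariance(self, design20, rng):
        values = pd.DataFrame(
            {"y": rng.normal(size=20)}, index=design20.sample_ids
        )
        eta1 = partial_eta_squared(values, design20)
        eta2 = partial_eta_squared(values * 12.0 - 3.0, design20)
        assert np.allclose(eta1, eta2, atol=1e-10)


class TestAnosim:
    def separated_distances(self):
        # two tight clusters far apart: all between > all within
        points = np.array([[0.0], [0.1], [0.2], [10.0], [10.1], [10.2]])
        return squareform(pdist(points)), np.repeat(["a", "b"], 3)

    def test_perfect_separation_gives_r_one(self):
        d, labels = self.separated_distances()
        res = anosim(d, labels, n_permutations=199, seed=0)
        assert res.R == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        r = np.random.default_rng(5)
        points = r.normal(size=(6, 3))
        d = squareform(pdist(points))
        labels = np.repeat(["a", "b"], 3)
        r_obs, p_exact = anosim_exhaustive(d, labels)
        res = anosim(d, labels, n_permutations=9999, seed=11)
        assert res.R == pytest.approx(r_obs, abs=1e-12)
        se = np.sqrt(p_exact * (1 - p_exact) / 9999)
        assert abs(res.pvalue - p_exact) <= 3 * se + 1e-4

    def test_null_r_centred_on_zero(self):
        rs = []
        for rep in range(40):
            r = np.random.default_rng(rep)
            d = squareform(pdist(r.normal(size=(12, 4))))
            labels = r.permutation(np.repeat(list("abc"), 4))
            rs.append(anosim(d, labels, n_permutations=99, seed=rep).R)
        assert abs(np.mean(rs)) < 0.08

    def test_monotone_transform_invariance(self):
        d, labels = self.separated_distances()
        res1 = anosim(d, labels, n_permutations=499, seed=3)
        res2 = anosim(d**2, labels, n_permutations=499, seed=3)
        assert res1.R == pytest.approx(res2.R)
        assert res1.pvalue == res2.pvalue

    def test_agrees_with_skbio(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import anosim as skbio_anosim

        r = np.random.default_rng(8)
        d = squareform(pdist(r.normal(size=(9, 3))))
        labels = np.repeat(["a", "b", "c"], 3)
        mine = anosim(d, labels, n_permutations=999, seed=0)
        theirs = skbio_anosim(
            DistanceMatrix(d), list(labels), permutations=999
        )
        assert mine.R == pytest.approx(theirs["test statistic"], abs=1e-12)

    def test_p_never_zero(self):
        d, labels = self.separated_distances()
        res = anosim(d, labels, n_permutations=199, seed=0)
        assert res.pvalue >= 1 / 200

    def test_degenerate_inputs_rejected(self):
        d, labels = self.separated_distances()
        with pytest.raises(ValueError):
            anosim(d, np.repeat("a", 6))
        with pytest.raises(ValueError):
            anosim(d[:5, :6], labels)
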
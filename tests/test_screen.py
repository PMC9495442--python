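import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rhizofun import (
    compute_responses,
    intersect_selected,
    kw_screen,
    mantel,
    run_screen,
    simulate_study,
    spearman_screen,
)
from rhizofun.simulate import SimulationSpec
from .oracles import mantel_exhaustive


@pytest.fixture
def response(design20, rng):
    return pd.Series(rng.normal(size=20), index=design20.sample_ids)


class TestSpearmanScreen:
    def test_identity_and_negation(self, response):
        feats = pd.DataFrame({"same": response, "neg": -response})
        out = spearman_screen(feats, response)
        assert out.loc["same", "rho"] == pytest.approx(1.0)
        assert out.loc["neg", "rho"] == pytest.approx(-1.0)
        assert out["selected"].all()

    def test_matches_scipy_with_ties(self, design20, response, rng):
        feats = pd.DataFrame(
            rng.poisson(2.0, size=(20, 30)).astype(float),
            index=design20.sample_ids,
            columns=[f"f{i}" for i in range(30)],
        )
        feats = feats.loc[:, feats.nunique() > 1]
        out = spearman_screen(feats, response)
        for col in feats.columns:
            rho, p = stats.spearmanr(feats[col], response)
            assert out.loc[col, "rho"] == pytest.approx(rho, abs=1e-12)
            assert out.loc[col, "p"] == pytest.approx(p, abs=1e-12)

    def test_constant_features_skipped(self, response):
        feats = pd.DataFrame(
            {"flat": np.ones(20), "ok": np.arange(20.0)}, index=response.index
        )
        with pytest.warns(UserWarning, match="constant"):
            out = spearman_screen(feats, response)
        assert list(out.index) == ["ok"]

    def test_needs_five_samples(self):
        y = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(ValueError):
            spearman_screen(pd.DataFrame({"f": y}), y)


class TestKwScreen:
    def test_planted_shift_selected(self, design20, rng):
        base = rng.normal(size=20)
        shifted = base.copy()
        shifted[:5] += 5.0  # one group moved by 5 SD
        feats = pd.DataFrame(
            {"shifted": shifted, "noise": rng.normal(size=20)},
            index=design20.sample_ids,
        )
        out = kw_screen(feats, design20)
        assert out.loc["shifted", "selected"]

    def test_all_tied_feature_never_selected(self, design20):
        feats = pd.DataFrame(
            {"tied": np.ones(20), "ok": np.arange(20.0)},
            index=design20.sample_ids,
        )
        out = kw_screen(feats, design20)
        assert out.loc["tied", "p"] == 1.0
        assert not out.loc["tied", "selected"]

    def test_null_selection_rate_near_alpha(self, design20):
        selected = total = 0
        for rep in range(30):
            r = np.random.default_rng(rep)
            feats = pd.DataFrame(
                r.normal(size=(20, 60)),
                index=design20.sample_ids,
                columns=[f"f{i}" for i in range(60)],
            )
            out = kw_screen(feats, design20)
            selected += out.selected.sum()
            total += len(out)
        assert 0.02 <= selected / total <= 0.08


def test_intersection_examples():
    assert intersect_selected(["x", "y"], ["y", "z"]) == ["y"]
    assert intersect_selected(["x"], ["z"]) == []
    assert intersect_selected(["a", "b"], ["a", "b"]) == ["a", "b"]


class TestMantel:
    def test_identity_r_one(self, response):
        res = mantel(pd.DataFrame({"y": response}), response, 99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        for seed in range(5):
            r = np.random.default_rng(seed)
            feats = pd.DataFrame(
                r.normal(size=(5, 3)), index=list("abcde")
            )
            y = pd.Series(r.normal(size=5), index=list("abcde"))
            r_oracle, p_oracle = mantel_exhaustive(feats, y)
            res = mantel(feats, y, n_permutations=999, seed=seed)
            assert res.r == pytest.approx(r_oracle, abs=1e-12)
            se = np.sqrt(p_oracle * (1 - p_oracle) / 999)
            assert abs(res.pvalue - p_oracle) <= 3 * se + 2e-3

    def test_agrees_with_skbio(self, design20, rng):
        from scipy.spatial.distance import pdist, squareform
        from skbio import DistanceMatrix
        from skbio.stats.distance import mantel as skbio_mantel

        feats = pd.DataFrame(
            rng.normal(size=(12, 4)), index=[f"s{i}" for i in range(12)]
        )
        y = pd.Series(rng.normal(size=12), index=feats.index)
        res = mantel(feats, y, n_permutations=99, seed=0, zscore=False)
        d1 = DistanceMatrix(squareform(pdist(feats.to_numpy())))
        d2 = DistanceMatrix(squareform(pdist(y.to_numpy()[:, None])))
        r_ref = skbio_mantel(d1, d2, method="spearman", permutations=0)[0]
        assert res.r == pytest.approx(r_ref, abs=1e-12)

    def test_invariances(self, response, rng):
        feats = pd.DataFrame(
            rng.normal(size=(20, 3)), index=response.index
        )
        base = mantel(feats, response, 199, seed=1)
        shifted = mantel(feats + 100.0, response, 199, seed=1)
        assert base.r == pytest.approx(shifted.r, abs=1e-12)
        order = rng.permutation(20)
        reordered = mantel(
            feats.iloc[order], response.iloc[order], 199, seed=1
        )
        assert base.r == pytest.approx(reordered.r, abs=1e-12)

    def test_p_never_zero_and_errors(self, response):
        res = mantel(pd.DataFrame({"y": response}), response, 99, seed=0)
        assert res.pvalue >= 1 / 100
        with pytest.raises(ValueError, match="constant"):
            mantel(
                pd.DataFrame({"flat": np.ones(20)}, index=response.index),
                response,
                99,
            )
        with pytest.raises(ValueError, match="at least one feature"):
            mantel(pd.DataFrame(index=response.index), response, 99)


class TestComputeResponses:
    def test_mf_columns_and_tradeoff(self, functions20):
        out = compute_responses(functions20, anpp=None)
        assert set(out.columns) == {"CCMF", "NCMF", "PCMF", "AEMF", "TRADEOFF"}
        assert (out["TRADEOFF"] >= 0).all()

    def test_anpp_passthrough(self, functions20, design20, rng):
        anpp = pd.Series(rng.normal(size=20), index=design20.sample_ids)
        out = compute_responses(functions20, anpp=anpp)
        assert np.allclose(out["ANPP"], anpp)

    def test_unknown_response_rejected(self, functions20):
        with pytest.raises(ValueError, match="unknown response"):
            compute_responses(functions20, responses=("YIELD",))


class TestRunScreen:
    @pytest.fixture(scope="class")
    def study(self):
        return simulate_study(
            SimulationSpec(n_taxa=150, library_size=20000, seed=5)
        )

    def test_table_shape_and_levels(self, study):
        res = run_screen(
            {"bacteria": study.otu},
            study.functions,
            study.design,
            responses=("CCMF", "ANPP"),
            anpp=study.anpp,
            n_permutations=99,
            seed=0,
        )
        assert set(res.table["level"]) <= {
            "whole",
            "locally_abundant",
            "locally_rare",
            "regionally_abundant",
            "regionally_rare",
        }
        assert set(res.table["response"]) == {"CCMF", "ANPP"}
        assert set(res.table["kind"]) <= {"species", "diversity"}

    def test_removing_response_removes_column(self, study):
        res = run_screen(
            {"bacteria": study.otu},
            study.functions,
            study.design,
            responses=("CCMF", "ANPP"),
            anpp=None,  # ANPP absent from the dataset
            n_permutations=99,
            seed=0,
        )
        assert set(res.table["response"]) == {"CCMF"}

    def test_intersection_subset_of_selections(self, study):
        res = run_screen(
            {"bacteria": study.otu},
            study.functions,
            study.design,
            responses=("AEMF",),
            n_permutations=99,
            seed=0,
        )
        for cell in res.cells:
            assert set(cell.intersection) <= set(cell.spearman_selected)
            assert set(cell.intersection) <= set(cell.kw_selected)

    def test_predicted_functions_add_kind(self, study, rng):
        pf = pd.DataFrame(
            rng.poisson(30.0, size=(20, 6)).astype(float),
            index=study.design.sample_ids,
            columns=[f"cat{i}" for i in range(6)],
        )
        res = run_screen(
            {"bacteria": study.otu},
            study.functions,
            study.design,
            responses=("AEMF",),
            predicted_functions={"bacteria": pf},
            n_permutations=99,
            seed=0,
        )
        whole_kinds = set(
            res.table[res.table.level == "whole"]["kind"]
        )
        assert "functions" in whole_kinds

    def test_deterministic_given_seed(self, study):
        kwargs = dict(
            responses=("AEMF",), n_permutations=99, seed=7
        )
        r1 = run_screen({"b": study.otu}, study.functions, study.design, **kwargs)
        r2 = run_screen({"b": study.otu}, study.functions, study.design, **kwargs)
        pd.testing.assert_frame_equal(r1.table, r2.table)
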
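"""Tests for the cohort correlation model, bands, clustering and ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from renomorph import CohortCorrelation, interpret_r, summarize
from renomorph.synthetic import default_cohort_spec, simulate_cohort


class TestSummarize:
    def test_basic_statistics(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        row = summarize(df).loc["x"]
        assert row["N"] == 3 and row["mean"] == 2.0 and row["sd"] == 1.0
        assert row["min"] == 1.0 and row["max"] == 3.0

    def test_constant_column_sd_zero(self):
        assert summarize(pd.DataFrame({"x": [5.0] * 4})).loc["x", "sd"] == 0.0

    def test_missing_values_reduce_n(self):
        df = pd.DataFrame({"x": [1.0, np.nan, 3.0, np.nan, 5.0]})
        assert summarize(df).loc["x", "N"] == 3

    def test_all_missing_column_undefined(self):
        row = summarize(pd.DataFrame({"x": [np.nan] * 4})).loc["x"]
        assert row["N"] == 0 and np.isnan(row["mean"])


class TestInterpretR:
    @pytest.mark.parametrize(
        "r,band",
        [(0.95, "very high"), (0.85, "high"), (0.60, "moderate"),
         (0.40, "low"), (0.10, "negligible"), (-0.45, "low")],
    )
    def test_band_values(self, r, band):
        assert interpret_r(r) == band

    @pytest.mark.parametrize(
        "r,band",
        [(0.90, "very high"), (0.70, "high"), (0.50, "moderate"), (0.30, "low")],
    )
    def test_boundaries_assigned_to_upper_band(self, r, band):
        assert interpret_r(r) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            interpret_r(1.2)

    @given(st.floats(min_value=-1.0, max_value=1.0))
    def test_every_r_maps_to_exactly_one_band(self, r):
        assert interpret_r(r) in {"very high", "high", "moderate", "low", "negligible"}


def _corrmodel(df):
    return CohortCorrelation(df)


class TestPearsonMatrix:
    def test_perfect_linear_relation(self):
        x = np.arange(10, dtype=float)
        res = _corrmodel(pd.DataFrame({"x": x, "y": 2 * x})).fit()
        assert res.r.loc["x", "y"] == pytest.approx(1.0)
        assert res.p.loc["x", "y"] <= 1e-12

    def test_bivariate_normal_within_fisher_interval(self):
        rng = np.random.default_rng(42)
        n, rho = 500, 0.8
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        res = _corrmodel(pd.DataFrame(z, columns=["a", "b"])).fit()
        z_hat = np.arctanh(res.r.loc["a", "b"])
        z_true = np.arctanh(rho)
        half = 2.576 / np.sqrt(n - 3)
        assert z_true - half <= z_hat <= z_true + half

    def test_constant_column_flagged_undefined(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "c": [7.0] * 4})
        with pytest.warns(UserWarning, match="constant"):
            res = _corrmodel(df).fit()
        assert np.isnan(res.r.loc["x", "c"])

    def test_pairwise_complete_n(self):
        df = pd.DataFrame({
            "x": [1.0, 2.0, 3.0, 4.0, 5.0],
            "y": [np.nan, np.nan, 1.0, 2.0, 3.5],
        })
        res = _corrmodel(df).fit()
        assert res.n.loc["x", "y"] == 3
        assert res.n.loc["x", "x"] == 5

    def test_pairs_below_observation_floor_undefined(self):
        df = pd.DataFrame({
            "x": [1.0, 2.0, np.nan, np.nan, 5.0],
            "y": [np.nan, 1.0, 2.0, 3.0, 4.0],
        })
        res = _corrmodel(df).fit(min_n=3)
        assert np.isnan(res.r.loc["x", "y"])

    def test_matrix_invariants(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(40, 6)), columns=list("abcdef"))
        res = _corrmodel(df).fit()
        r = res.r.to_numpy()
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)
        assert (np.abs(r) <= 1.0 + 1e-12).all()

    def test_p_monotone_decreasing_in_abs_r(self):
        # construct samples with exact target correlation via orthogonalization
        rng = np.random.default_rng(3)
        n = 30
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        e = rng.normal(size=n)
        e -= e.mean() + x * np.dot(e - e.mean(), x) / np.dot(x, x)
        e /= np.linalg.norm(e)
        x /= np.linalg.norm(x)
        prev_p = 1.1
        for r_target in (0.2, 0.4, 0.6, 0.8, 0.95):
            y = r_target * x + np.sqrt(1 - r_target**2) * e
            res = _corrmodel(pd.DataFrame({"x": x, "y": y})).fit()
            assert res.r.loc["x", "y"] == pytest.approx(r_target, abs=1e-9)
            p = res.p.loc["x", "y"]
            assert p < prev_p
            prev_p = p

    def test_duplicate_case_ids_rejected(self):
        df = pd.DataFrame({"case_id": ["a", "a", "b"], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="duplicate"):
            CohortCorrelation(df)

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError, match="3 cases"):
            CohortCorrelation(pd.DataFrame({"x": [1.0, 2.0]}))


class TestClustering:
    def test_correlated_pair_adjacent_in_ordering(self):
        rng = np.random.default_rng(1)
        n = 400
        a = rng.normal(size=n)
        b = 0.97 * a + np.sqrt(1 - 0.97**2) * rng.normal(size=n)
        c = rng.normal(size=n)
        res = _corrmodel(pd.DataFrame({"A": a, "B": b, "C": c})).fit()
        order, linkage = res.cluster_variables()
        ia, ib = order.index("A"), order.index("B")
        assert abs(ia - ib) == 1

    def test_duplicated_column_merges_first_at_zero_distance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        df = pd.DataFrame({"x1": x, "x2": x.copy(), "y": rng.normal(size=50)})
        res = _corrmodel(df).fit()
        order, linkage = res.cluster_variables()
        assert linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {order.index("x1"), order.index("x2")} in \
            ({0, 1}, {1, 2})  # adjacent leaves

    def test_independent_columns_give_valid_tree(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(200, 5)), columns=list("abcde"))
        res = _corrmodel(df).fit()
        order, linkage = res.cluster_variables()
        assert sorted(order) == list("abcde")
        assert linkage.shape == (4, 4)

    def test_undefined_pairs_imputed_with_warning(self):
        df = pd.DataFrame({
            "x": [1.0, 2.0, 3.0, 4.0],
            "c": [5.0] * 4,
            "y": [2.0, 1.0, 4.0, 3.0],
        })
        with pytest.warns(UserWarning):
            res = _corrmodel(df).fit()
            order, _ = res.cluster_variables()
        assert sorted(order) == ["c", "x", "y"]

    def test_single_variable_rejected(self):
        res = _corrmodel(pd.DataFrame({"x": [1.0, 2.0, 3.0]})).fit()
        res.r = res.r.iloc[:1, :1]
        with pytest.raises(ValueError, match="at least 2"):
            res.cluster_variables()


@pytest.fixture(scope="module")
def fitted():
    table, truth = simulate_cohort(default_cohort_spec(n_cases=5000, seed=11))
    return CohortCorrelation(table).fit(), truth


@pytest.fixture(scope="module")
def small_fit():
    table, _ = simulate_cohort(default_cohort_spec(n_cases=300, seed=5))
    return CohortCorrelation(table).fit()


class TestCompartmentRanking:

    def test_auto_pairing_covers_visual_columns(self, fitted):
        res, _ = fitted
        ranking = res.rank_compartment_correlations()
        assert "Vis-Tri" in set(ranking["measure"])
        assert "CKAvg" in set(ranking["measure"])

    def test_strong_targets_ranked_above_weak(self, fitted):
        res, _ = fitted
        ranking = res.rank_compartment_correlations().set_index("measure")
        assert ranking.loc["CKAvg", "r"] > ranking.loc["Vis-Tri", "r"]
        assert ranking.loc["PAS", "r"] > ranking.loc["RedTri", "r"]
        assert (ranking["r"].to_numpy()[:-1] >= ranking["r"].to_numpy()[1:]).all()

    def test_single_pair(self, fitted):
        res, _ = fitted
        out = res.rank_compartment_correlations([("Ctx-Tri", "Med-Tri")])
        assert len(out) == 1 and out.loc[0, "measure"] == "Tri"

    def test_missing_pair_member_skipped_with_warning(self, fitted):
        res, _ = fitted
        with pytest.warns(UserWarning, match="missing"):
            out = res.rank_compartment_correlations(
                [("Ctx-Tri", "Med-Tri"), ("Ctx-Nope", "Med-Nope")]
            )
        assert len(out) == 1


class TestReporting:
    def test_long_format_columns(self, small_fit):
        res = small_fit
        long = res.to_long()
        assert set(long.columns) == {"var1", "var2", "n", "r", "p", "band"}
        k = len(res.variables)
        assert len(long) == k * (k - 1) // 2

    def test_bh_adjustment_optional(self, small_fit):
        res = small_fit
        long = res.to_long(adjust="bh")
        assert "p_adj" in long.columns
        ok = long.dropna(subset=["p", "p_adj"])
        assert (ok["p_adj"] >= ok["p"] - 1e-15).all()

    def test_summary_mentions_cases_and_bands(self, small_fit):
        res = small_fit
        text = res.summary()
        assert "Cases: 300" in text
        assert "very high" in text

    def test_heatmap_written(self, small_fit, tmp_path):
        res = small_fit
        out = tmp_path / "heat.png"
        res.plot_heatmap(out)
        assert out.stat().st_size > 0
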
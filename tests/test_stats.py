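"""Correlation structure, VIF pruning and the regression battery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bwsnorms import stats as st
from bwsnorms import synthetic_world as sw


def _hadamard_predictors(n=16):
    """Exactly orthogonal, zero-mean predictor columns."""
    h = np.array([[1.0]])
    while h.shape[0] < n:
        h = np.block([[h, h], [h, -h]])
    return pd.DataFrame(h[:n, 1:4], columns=["p1", "p2", "p3"])


class TestCorrelationMatrix:
    def test_identical_and_reversed_columns(self):
        rng = np.random.default_rng(0)
        x = rng.random(30)
        df = pd.DataFrame({"x": x, "same": x.copy(), "rev": -3 * x + 1})
        corr, _ = st.correlation_matrix(df)
        assert corr.loc["x", "same"] == pytest.approx(1.0)
        assert corr.loc["x", "rev"] == pytest.approx(-1.0)

    def test_five_point_hand_oracle(self):
        """Spearman = Pearson on ranks, checked against a manual computation."""
        df = pd.DataFrame({"a": [3.0, 1.0, 4.0, 1.5, 5.0], "b": [2.0, 0.5, 9.0, 7.0, 3.0]})
        corr, _ = st.correlation_matrix(df)
        ra, rb = sps.rankdata(df["a"]), sps.rankdata(df["b"])
        manual = np.corrcoef(ra, rb)[0, 1]
        assert corr.loc["a", "b"] == pytest.approx(manual)

    def test_clustering_groups_correlated_variables(self):
        rng = np.random.default_rng(1)
        x = rng.random(200)
        z = rng.random(200)
        df = pd.DataFrame(
            {"x1": x, "far": z, "x2": x + rng.normal(0, 0.05, 200)}
        )
        corr, order = st.correlation_matrix(df)
        assert abs(order.index("x1") - order.index("x2")) == 1

    def test_constant_column_excluded(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 2, 2, 2], "c": [4.0, 3, 2, 1]})
        corr, order = st.correlation_matrix(df)
        assert "b" not in corr.columns and "b" not in order


class TestVif:
    def test_orthogonal_predictors_all_one(self):
        df = _hadamard_predictors()
        report = st.vif_prune(df, ["p1", "p2", "p3"])
        assert np.allclose(report.initial, 1.0)
        assert report.removal_sequence == []
        assert report.retained == ["p1", "p2", "p3"]

    def test_duplicated_column_removed_first_as_infinite(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.random((40, 3)), columns=["a", "b", "c"])
        df["a_copy"] = df["a"]
        report = st.vif_prune(df, ["a", "a_copy", "b", "c"])
        first_removed, value = report.removal_sequence[0]
        assert first_removed in ("a", "a_copy")
        assert np.isinf(value)
        assert report.max_final <= 4.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_predictor_regression_oracle(self, seed):
        """VIF_j == 1/(1-R^2_j) from an independent least-squares fit."""
        rng = np.random.default_rng(seed)
        p = int(rng.integers(3, 7))
        base = rng.random((50, p))
        base[:, 0] += 0.8 * base[:, 1]  # induce correlation
        df = pd.DataFrame(base, columns=[f"v{j}" for j in range(p)])
        ours = st.vif(df, list(df.columns))
        for j, col in enumerate(df.columns):
            others = df.drop(columns=[col]).to_numpy()
            X = np.column_stack([np.ones(len(df)), others])
            y = df[col].to_numpy()
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            r2 = 1 - resid.var() / y.var()
            assert ours[col] == pytest.approx(1 / (1 - r2), rel=1e-6)

    def test_agrees_with_statsmodels_oracle(self):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.random((60, 4)), columns=list("abcd"))
        df["a"] += df["b"]
        ours = st.vif(df, list(df.columns))
        X = np.column_stack([np.ones(len(df)), df.to_numpy()])
        for j, col in enumerate(df.columns, start=1):
            assert ours[col] == pytest.approx(variance_inflation_factor(X, j), rel=1e-8)

    def test_pruning_stops_below_cutoff(self):
        rng = np.random.default_rng(3)
        x = rng.random(80)
        df = pd.DataFrame(
            {
                "x1": x,
                "x2": x + rng.normal(0, 0.05, 80),
                "x3": x + rng.normal(0, 0.05, 80),
                "y1": rng.random(80),
            }
        )
        report = st.vif_prune(df, ["x1", "x2", "x3", "y1"], cutoff=4.0)
        assert report.max_final <= 4.0
        assert len(report.removal_sequence) >= 1

    def test_requires_enough_rows(self):
        df = pd.DataFrame(np.random.default_rng(0).random((4, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match="complete rows"):
            st.vif_prune(df, list("abc"))


class TestFitAndSelect:
    def test_exact_linear_fit_selects_linear(self):
        x = np.linspace(0, 1, 50)
        df = pd.DataFrame({"x": x, "y": 2 + 3 * x})
        report = st.fit_and_select(df, "y", ["x"])
        assert report.form == "linear"
        assert report.r2 == pytest.approx(1.0)
        assert report.fits["linear"]["bic"] < report.fits["quadratic"]["bic"]

    def test_u_shaped_data_selects_quadratic(self):
        rng = np.random.default_rng(4)
        x = rng.random(500)
        y = (x - 0.5) ** 2 + rng.normal(0, 0.01, 500)
        report = st.fit_and_select(pd.DataFrame({"x": x, "y": y}), "y", ["x"])
        assert report.form == "quadratic"
        assert report.pvalues["x^2"] < 0.01

    def test_noiseless_quadratic_coefficients_recovered(self):
        x = np.linspace(0, 1, 40)
        a, b, c = 1.5, -2.0, 4.0
        df = pd.DataFrame({"x": x, "y": a + b * x + c * x**2})
        report = st.fit_and_select(df, "y", ["x"])
        assert report.form == "quadratic"
        assert report.coef["const"] == pytest.approx(a, abs=1e-8)
        assert report.coef["x"] == pytest.approx(b, abs=1e-8)
        assert report.coef["x^2"] == pytest.approx(c, abs=1e-8)

    def test_bic_selection_invariant_to_predictor_rescaling(self):
        rng = np.random.default_rng(5)
        x = rng.random(300)
        y = (x - 0.4) ** 2 + rng.normal(0, 0.02, 300)
        df1 = pd.DataFrame({"x": x, "y": y})
        df2 = pd.DataFrame({"x": 10 * x - 3, "y": y})
        assert (
            st.fit_and_select(df1, "y", ["x"]).form
            == st.fit_and_select(df2, "y", ["x"]).form
        )

    def test_singular_design_rejected_with_diagnostic(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"x": rng.random(30)})
        df["x2"] = df["x"]
        df["y"] = rng.random(30)
        with pytest.raises(ValueError, match="singular"):
            st.fit_and_select(df, "y", ["x", "x2"], forms=("linear",))


def _rt_tables(n=1000, coeffs=None, noise=10.0, seed=0):
    world = sw.sample_world(n, seed=seed)
    coeffs = coeffs if coeffs is not None else {"specificity": 50.0}
    rt = sw.simulate_latencies(world, coefficients=coeffs, intercept=500.0,
                               noise_sd=noise, seed=seed + 1)
    norms = world.table
    return rt, norms


class TestRtRegressions:
    def test_specificity_slope_recovered_within_ten_percent(self):
        rt, norms = _rt_tables()
        report = st.rt_regressions(rt, norms, "spec_only")
        assert report.coef["specificity"] == pytest.approx(50.0, rel=0.10)
        assert report.pvalues["specificity"] < 0.01

    def test_null_predictor_rarely_significant(self):
        """With RT independent of the predictor, ~5% of fits reach p < .05."""
        sig = 0
        n_sims = 100
        rng = np.random.default_rng(8)
        for _ in range(n_sims):
            x = rng.random(200)
            y = rng.normal(600, 30, 200)
            rep = st.fit_and_select(
                pd.DataFrame({"x": x, "y": y}), "y", ["x"], forms=("linear",)
            )
            sig += rep.pvalues["x"] < 0.05
        assert sig <= 12  # 99.9% binomial bound at p=0.05

    def test_interaction_term_recovered_with_correct_sign(self):
        world = sw.sample_world(1000, seed=9)
        tab = world.table
        rng = np.random.default_rng(10)
        rt_vals = (
            500
            + 200 * tab["specificity"]
            - 150 * tab["specificity"] * tab["concreteness"]
            + rng.normal(0, 10, len(tab))
        )
        rt = pd.DataFrame({"word": tab.index, "rt_ms": rt_vals.to_numpy()})
        report = st.rt_regressions(rt, tab, "interaction")
        inter = "specificity:concreteness"
        assert report.coef[inter] < 0
        assert report.pvalues[inter] < 0.01
        assert report.coef[inter] == pytest.approx(-150.0, rel=0.15)

    def test_full_model_with_post_vif_predictors(self):
        coeffs = {"specificity": 50.0, "familiarity": -75.0, "aoa": 120.0}
        rt, norms = _rt_tables(coeffs=coeffs, seed=11)
        report = st.rt_regressions(
            rt, norms, "full", predictors=["specificity", "familiarity", "aoa", "valence"]
        )
        for var, expected in coeffs.items():
            assert report.coef[var] == pytest.approx(expected, rel=0.10)
        assert report.pvalues["valence"] > 0.001  # no injected effect

    def test_subset_models_split_by_class(self):
        rt, norms = _rt_tables(n=400, seed=12)
        norms = norms.copy()
        norms["class"] = np.where(norms["concreteness"] >= 0.5, "concrete", "abstract")
        out = st.rt_regressions(
            rt, norms, "subset",
            predictors=["specificity", "concreteness", "familiarity", "aoa"],
        )
        assert set(out) == {"all", "abstract", "concrete"}
        for rep in out.values():
            assert "concreteness" not in rep.predictors
        assert out["abstract"].n + out["concrete"].n == out["all"].n


class TestAblation:
    def test_deltas_nonnegative_and_sorted(self):
        coeffs = {"specificity": 40.0, "aoa": 100.0, "frequency": -90.0}
        rt, norms = _rt_tables(n=500, coeffs=coeffs, noise=20.0, seed=13)
        report = st.ablation(rt, norms, ["specificity", "aoa", "frequency", "valence"])
        assert (report.deltas >= 0).all()
        assert list(report.deltas) == sorted(report.deltas, reverse=True)
        assert (report.full_r2 >= report.sub_r2 - 1e-12).all()

    def test_orthogonal_predictors_delta_equals_marginal_r2(self):
        """Under exact orthogonality the r^2 decomposition is additive."""
        df = _hadamard_predictors(32)
        rng = np.random.default_rng(14)
        df["rt_ms"] = 600 + 10 * df["p1"] - 6 * df["p2"] + rng.normal(0, 2, len(df))
        df["word"] = [f"w{i}" for i in range(len(df))]
        rt = df[["word", "rt_ms"]]
        norms = df.set_index("word")[["p1", "p2", "p3"]]
        report = st.ablation(rt, norms, ["p1", "p2", "p3"])
        joined = rt.set_index("word").join(norms)
        for p in ("p1", "p2", "p3"):
            marginal = st.fit_and_select(joined, "rt_ms", [p], forms=("linear",)).r2
            assert report.deltas[p] == pytest.approx(marginal, abs=1e-10)

    def test_duplicated_predictor_contributes_nothing(self):
        rt, norms = _rt_tables(n=200, seed=15)
        norms = norms.copy()
        norms["spec_copy"] = norms["specificity"]
        report = st.ablation(rt, norms, ["specificity", "spec_copy", "aoa"])
        assert report.deltas["spec_copy"] == pytest.approx(0.0, abs=1e-10)
        assert report.deltas["specificity"] == pytest.approx(0.0, abs=1e-10)
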
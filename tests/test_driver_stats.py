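"""Driver-analysis checks: correlation screening, stepwise selection,
standardized effects, and the two nonlinear fits."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sedshuttle.driver_stats import (
    apply_transform_policy,
    compare_nested,
    exp_association_fit,
    one_phase_decay_fit,
    screen_candidates,
    simple_lr,
    spearman_matrix,
    standardized_coefficients,
    stepwise_aic_mlr,
    _fit_ols,
)
from statsmodels.stats.outliers_influence import variance_inflation_factor
import statsmodels.api as sm


class TestSpearman:
    def test_monotone_cube(self):
        x = np.linspace(-3, 3, 12)
        df = pd.DataFrame({"x": x, "y": x ** 3})
        rho, _ = spearman_matrix(df, ["x", "y"])
        assert rho.loc["x", "y"] == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "y": -x})
        rho, _ = spearman_matrix(df, ["x", "y"])
        assert rho.loc["x", "y"] == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0])
        df = pd.DataFrame({"x": x, "y": y})
        rho, _ = spearman_matrix(df, ["x", "y"])
        # midrank, then plain Pearson on the ranks
        expected = stats.pearsonr(stats.rankdata(x), stats.rankdata(y))[0]
        assert rho.loc["x", "y"] == pytest.approx(expected, rel=1e-12)

    def test_constant_column_flagged_nan(self):
        df = pd.DataFrame({"x": np.arange(6.0), "c": np.ones(6)})
        rho, _ = spearman_matrix(df, ["x", "c"])
        assert math.isnan(rho.loc["x", "c"])

    def test_symmetry_and_diagonal(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        rho, p = spearman_matrix(df)
        assert np.allclose(rho.values, rho.values.T)
        assert np.allclose(np.diag(rho.values), 1.0)


class TestSimpleLR:
    def test_exact_line(self):
        x = np.arange(5.0)
        res = simple_lr(x, 3 * x + 1)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(3.0)

    def test_hand_computed_four_points(self):
        # {(0,0),(1,2),(2,4),(3,7)}: Sxy=11.5, Sxx=5, Syy=26.75
        res = simple_lr([0, 1, 2, 3], [0, 2, 4, 7])
        assert res.slope == pytest.approx(11.5 / 5)
        assert res.intercept == pytest.approx(3.25 - 2.3 * 1.5)
        assert res.r_squared == pytest.approx(11.5 ** 2 / (5 * 26.75))

    def test_null_pvalues_uniformish(self):
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(200):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            pvals.append(simple_lr(x, y).pvalue)
        # uniform on [0,1]: mean near 0.5, KS not wildly off
        assert abs(np.mean(pvals) - 0.5) < 0.08
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="variance"):
            simple_lr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _table_with_signal(rng, n=12, n_noise=4, beta=1.0, noise_sd=0.5):
    x = rng.normal(size=n)
    df = pd.DataFrame({"signal": x})
    for i in range(n_noise):
        df[f"z{i}"] = rng.normal(size=n)
    df["y"] = beta * x + rng.normal(0, noise_sd, n)
    return df


class TestStepwise:
    def test_single_candidate_std_coef_equals_pearson_r(self, rng):
        df = _table_with_signal(rng)
        report = stepwise_aic_mlr(df, "y", ["signal"])
        r = stats.pearsonr(df["signal"], df["y"])[0]
        beta_std = report.coefficients.set_index("term").loc["signal", "std_coef"]
        assert beta_std == pytest.approx(r, abs=1e-10)

    def test_deterministic_given_table(self, rng):
        df = _table_with_signal(rng)
        cands = ["signal", "z0", "z1", "z2", "z3"]
        r1 = stepwise_aic_mlr(df, "y", cands)
        r2 = stepwise_aic_mlr(df, "y", cands)
        assert r1.selected == r2.selected
        assert r1.criterion_value == r2.criterion_value

    def test_strong_signal_selected(self):
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(50):
            df = _table_with_signal(rng, beta=2.0, noise_sd=0.3)
            rep = stepwise_aic_mlr(df, "y", ["signal", "z0", "z1", "z2", "z3"])
            if "signal" in rep.selected:
                hits += 1
        assert hits == 50

    def test_all_noise_prefers_intercept_only(self):
        rng = np.random.default_rng(5)
        sizes = []
        for _ in range(50):
            df = _table_with_signal(rng, beta=0.0, noise_sd=1.0)
            rep = stepwise_aic_mlr(df, "y", ["signal", "z0", "z1", "z2", "z3"])
            sizes.append(len(rep.selected))
        # intercept-only is the modal outcome under the null
        assert sizes.count(0) > len(sizes) / 2

    def test_collinear_candidate_dropped_with_log(self, rng):
        df = _table_with_signal(rng)
        df["dup"] = df["signal"] * 2.0  # perfect collinearity
        rep = stepwise_aic_mlr(df, "y", ["signal", "dup"])
        assert any("collinear" in line for line in rep.log)
        assert "dup" not in rep.selected

    def test_cohen_d_formula(self, rng):
        df = _table_with_signal(rng)
        rep = stepwise_aic_mlr(df, "y", ["signal"])
        row = rep.coefficients.set_index("term").loc["signal"]
        df_resid = rep.n - 2
        assert row["cohen_d"] == pytest.approx(2 * row["t"] / math.sqrt(df_resid))

    def test_scaling_predictor_leaves_std_coef_unchanged(self, rng):
        df = _table_with_signal(rng)
        rep1 = stepwise_aic_mlr(df, "y", ["signal"])
        df2 = df.assign(signal=df["signal"] * 10.0)
        rep2 = stepwise_aic_mlr(df2, "y", ["signal"])
        assert (
            rep1.coefficients["std_coef"].iloc[0]
            == pytest.approx(rep2.coefficients["std_coef"].iloc[0], rel=1e-10)
        )


class TestVif:
    def test_orthogonal_predictors_unit_vif(self):
        n = 16
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        X = sm.add_constant(pd.DataFrame({"x1": x1, "x2": x2}))
        assert variance_inflation_factor(X.values, 1) == pytest.approx(1.0)
        assert variance_inflation_factor(X.values, 2) == pytest.approx(1.0)

    def test_near_duplicate_predictors_explode(self, rng):
        x = rng.normal(size=30)
        X = sm.add_constant(pd.DataFrame({
            "x1": x, "x2": x + rng.normal(0, 1e-3, 30)
        }))
        assert variance_inflation_factor(X.values, 1) > 100


def test_compare_nested_matches_f_distribution(rng):
    y = rng.normal(size=20)
    df = pd.DataFrame({"a": rng.normal(size=20)})
    reduced = _fit_ols(y, df, [])
    full = _fit_ols(y, df, ["a"])
    cmp = compare_nested(reduced, full)
    # F for one added term equals squared t of that term
    assert cmp["F"] == pytest.approx(full.tvalues["a"] ** 2, rel=1e-9)


def test_screen_candidates_keeps_true_driver(rng):
    df = _table_with_signal(rng, beta=2.0, noise_sd=0.3)
    kept = screen_candidates(df, "y", ["signal", "z0", "z1"])
    assert "signal" in kept


def test_transform_policy_logs_skewed_predictor():
    rng = np.random.default_rng(8)
    x = np.exp(rng.normal(0, 1.2, 40))  # strongly right-skewed, positive
    y = np.log10(x) * 2.0 + rng.normal(0, 0.1, 40)
    df = pd.DataFrame({"x": x, "y": y})
    out, cands, log = apply_transform_policy(df, "y", ["x"])
    assert cands == ["log10_x"]
    assert "log10_x" in out.columns
    assert log


class TestExpAssociation:
    def test_noise_free_identifiability(self):
        x = np.linspace(0, 2, 10)
        y = 1.0 * np.exp(2.0 * x) + 0.5
        fit = exp_association_fit(x, y)
        assert fit.a == pytest.approx(1.0, rel=1e-6)
        assert fit.b == pytest.approx(2.0, rel=1e-6)
        assert fit.c == pytest.approx(0.5, rel=1e-5)
        assert fit.r_squared == pytest.approx(1.0)

    def test_null_b_one_sided_p_near_half(self):
        rng = np.random.default_rng(9)
        pvals = []
        for _ in range(100):
            x = np.linspace(0, 3, 12)
            y = 2.0 + rng.normal(0, 0.3, 12)  # no association
            fit = exp_association_fit(x, y)
            if np.isfinite(fit.p_one_sided):
                pvals.append(fit.p_one_sided)
        assert 0.35 < np.mean(pvals) < 0.65

    def test_noisy_recovery_within_3se(self):
        rng = np.random.default_rng(10)
        x = np.linspace(0, 2, 15)
        y = 1.0 * np.exp(1.5 * x) + 0.5 + rng.normal(0, 0.2, 15)
        fit = exp_association_fit(x, y)
        assert abs(fit.b - 1.5) < 3 * fit.b_stderr

    def test_degrees_of_freedom(self):
        x = np.linspace(0, 2, 10)
        fit = exp_association_fit(x, np.exp(x))
        assert fit.df == 7


class TestOnePhaseDecay:
    def test_noise_free_identifiability(self):
        x = np.linspace(0, 100, 12)
        y = (3.0 - 1.0) * np.exp(-0.05 * x) + 1.0
        fit = one_phase_decay_fit(x, y)
        assert fit.y0 == pytest.approx(3.0, rel=1e-6)
        assert fit.plateau == pytest.approx(1.0, rel=1e-6)
        assert fit.k == pytest.approx(0.05, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    def test_plateau_only_flagged(self):
        x = np.linspace(0, 10, 8)
        fit = one_phase_decay_fit(x, np.full(8, 2.0))
        assert "k_unidentifiable" in fit.flags

    def test_noisy_recovery_and_reproducibility(self):
        rng = np.random.default_rng(11)
        x = np.linspace(0, 100, 15)
        y = 2.0 * np.exp(-0.05 * x) + 1.0 + rng.normal(0, 0.05, 15)
        f1 = one_phase_decay_fit(x, y)
        f2 = one_phase_decay_fit(x, y)
        assert abs(f1.k - 0.05) < 3 * f1.k_stderr
        assert f1.k == f2.k and f1.r_squared == f2.r_squared

    def test_k_constrained_nonnegative(self):
        rng = np.random.default_rng(13)
        x = np.linspace(0, 10, 10)
        y = 1.0 + 0.01 * x + rng.normal(0, 0.05, 10)  # mildly rising
        fit = one_phase_decay_fit(x, y)
        assert not np.isfinite(fit.k) or fit.k >= 0
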
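import numpy as np
import pandas as pd
import pytest

from spillnet import preprocessing as prep
from spillnet.robust_regression import (
    DESIGN_COLUMNS,
    InfluenceThresholds,
    build_design,
    classify_cyclicality,
    classify_demographic_effect,
    fit_mm,
    fit_ols,
    influence_stats,
    outlier_counts,
    spillover_regression,
    tuning_constant_for_breakdown,
    tuning_constant_for_efficiency,
)
from spillnet.synthetic_data import CovariateConfig, generate_covariates, make_calendar


def _loo_influence_oracle(y, x):
    """Literal leave-one-out refits: predictively studentized residual, DFFITS
    and the covariance-determinant ratio recomputed from scratch."""
    n, k = x.shape
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    s2 = np.sum((y - fitted) ** 2) / (n - k)
    xtx_inv = np.linalg.inv(x.T @ x)
    h = np.einsum("ij,jk,ik->i", x, xtx_inv, x)
    out = []
    for i in range(n):
        keep = np.arange(n) != i
        xi, yi = x[keep], y[keep]
        bi, *_ = np.linalg.lstsq(xi, yi, rcond=None)
        ri = yi - xi @ bi
        s2_i = ri @ ri / (n - 1 - k)
        xtx_i_inv = np.linalg.inv(xi.T @ xi)
        pred_var = s2_i * (1.0 + x[i] @ xtx_i_inv @ x[i])
        rstud = (y[i] - x[i] @ bi) / np.sqrt(pred_var)
        dffits = (fitted[i] - x[i] @ bi) / np.sqrt(s2_i * h[i])
        covratio = np.linalg.det(s2_i * xtx_i_inv) / np.linalg.det(s2 * xtx_inv)
        out.append((rstud, dffits, covratio))
    return out


class TestOLS:
    def test_exact_linear_data(self):
        x = np.column_stack([np.ones(20), np.arange(20.0)])
        y = 2.0 + 3.0 * np.arange(20.0)
        fit = fit_ols(y, x)
        np.testing.assert_allclose(fit.coef, [2.0, 3.0], atol=1e-10)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-10)

    def test_intercept_only_leverages(self, rng):
        y = rng.standard_normal(25)
        fit = fit_ols(y, np.ones((25, 1)))
        np.testing.assert_allclose(fit.leverage, 1.0 / 25, atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        n, k = 189, 7
        x = np.column_stack([np.ones(n), rng.standard_normal((n, k - 1))])
        y = rng.standard_normal(n)
        fit = fit_ols(y, x)
        oracle = np.linalg.inv(x.T @ x) @ x.T @ y
        np.testing.assert_allclose(fit.coef, oracle, atol=1e-10)

    def test_rank_deficiency_rejected(self, rng):
        x = np.column_stack([np.ones(30), np.ones(30)])
        with pytest.raises(np.linalg.LinAlgError):
            fit_ols(rng.standard_normal(30), x)


class TestInfluence:
    def test_matches_literal_loo_oracle(self, rng):
        n, k = 40, 3
        x = np.column_stack([np.ones(n), rng.standard_normal((n, k - 1))])
        y = x @ np.array([1.0, -2.0, 0.5]) + rng.standard_normal(n)
        records = influence_stats(fit_ols(y, x))
        oracle = _loo_influence_oracle(y, x)
        for rec, (rs, df, cr) in zip(records, oracle):
            assert rec.rstudent == pytest.approx(rs, abs=1e-8)
            assert rec.dffits == pytest.approx(df, abs=1e-8)
            assert rec.covratio == pytest.approx(cr, abs=1e-8)

    def test_perfect_fit_has_zero_dffits(self):
        x = np.column_stack([np.ones(12), np.tile(np.arange(6.0), 2)])
        y = 1.0 + 2.0 * x[:, 1]  # exact fit: every residual zero
        records = influence_stats(fit_ols(y, x))
        assert all(rec.dffits == 0.0 for rec in records)
        assert not any(rec.flagged for rec in records)

    def test_gross_outlier_flagged_with_max_rstudent(self, rng):
        n = 60
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = x @ np.array([0.5, 1.0]) + 0.3 * rng.standard_normal(n)
        y[17] += 8.0
        records = influence_stats(fit_ols(y, x))
        worst = max(records, key=lambda r: abs(r.rstudent))
        assert worst.index == 17 and worst.flagged_rstudent

    def test_thresholds_are_configurable(self, rng):
        n = 50
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n)
        strict = InfluenceThresholds(rstudent=0.0, dffits_scale=0.0, covratio_scale=0.0)
        records = influence_stats(fit_ols(y, x), strict)
        assert all(r.flagged for r in records)

    def test_too_few_observations_rejected(self, rng):
        x = np.ones((3, 2))
        x[:, 1] = [0.0, 1.0, 2.0]
        with pytest.raises(ValueError):
            influence_stats(fit_ols(rng.standard_normal(3), x))


class TestTuningConstants:
    def test_breakdown_half(self):
        assert tuning_constant_for_breakdown(0.5) == pytest.approx(1.5476, abs=1e-3)

    def test_efficiency_95(self):
        assert tuning_constant_for_efficiency(0.95) == pytest.approx(4.685, abs=1e-2)

    def test_efficiency_85(self):
        assert tuning_constant_for_efficiency(0.85) == pytest.approx(3.444, abs=1e-2)


class TestMM:
    def test_clean_data_close_to_ols(self, rng):
        n = 500
        x = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = x @ np.array([1.0, 2.0, -1.0]) + rng.standard_normal(n)
        mm = fit_mm(y, x, seed=1, n_resamples=100)
        ols = fit_ols(y, x)
        se = np.sqrt(np.diag(ols.sigma2 * ols.xtx_inv))
        assert np.all(np.abs(mm.coef - ols.coef) < 3 * se)
        assert mm.converged

    def test_contamination_resistance(self):
        rng = np.random.default_rng(0)
        n = 500
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = 1.0 + 2.0 * x[:, 1] + 0.5 * rng.standard_normal(n)
        bad = rng.choice(n, n // 10, replace=False)
        x[bad, 1] = 5.0
        y[bad] = -50.0  # gross high-leverage outliers
        mm = fit_mm(y, x, seed=3, n_resamples=200)
        ols = fit_ols(y, x)
        assert abs(mm.coef[1] - 2.0) < 0.05
        assert abs(ols.coef[1] - 2.0) > 0.5

    def test_scale_equivariance(self, rng):
        n = 300
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = 1.0 + 0.5 * x[:, 1] + rng.standard_normal(n)
        a = fit_mm(y, x, seed=2, n_resamples=100)
        b = fit_mm(4.0 * y, x, seed=2, n_resamples=100)
        np.testing.assert_allclose(b.coef, 4.0 * a.coef, rtol=1e-6)
        assert b.scale == pytest.approx(4.0 * a.scale, rel=1e-6)

    def test_bounded_influence_single_point(self, rng):
        n = 200
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = 1.0 + 2.0 * x[:, 1] + 0.3 * rng.standard_normal(n)
        base = fit_mm(y, x, seed=5, n_resamples=100)
        y2 = y.copy()
        y2[0] = 1e6
        moved = fit_mm(y2, x, seed=5, n_resamples=100)
        ols2 = fit_ols(y2, x)
        assert np.max(np.abs(moved.coef - base.coef)) < 0.5
        assert abs(ols2.coef[0] - 1.0) > 100.0

    def test_weights_in_unit_interval(self, rng):
        n = 150
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n)
        mm = fit_mm(y, x, seed=0, n_resamples=50)
        assert np.all(mm.weights >= 0) and np.all(mm.weights <= 1)

    def test_exact_fit_returns_zero_scale(self):
        x = np.column_stack([np.ones(30), np.arange(30.0)])
        y = 3.0 - 0.5 * x[:, 1]
        mm = fit_mm(y, x, seed=0, n_resamples=50)
        np.testing.assert_allclose(mm.coef, [3.0, -0.5], atol=1e-8)
        assert mm.scale <= 1e-12

    def test_too_small_sample_rejected(self, rng):
        x = np.ones((5, 3))
        with pytest.raises(ValueError, match="n > 2k"):
            fit_mm(rng.standard_normal(5), x)

    def test_type_one_error_quick(self):
        # 40-replicate version of the calibration check (full run in acceptance)
        rng = np.random.default_rng(7)
        n, k = 189, 7
        rejections = 0
        for rep in range(40):
            x = np.column_stack([np.ones(n), rng.standard_normal((n, k - 1))])
            y = 1.0 + rng.standard_normal(n)
            mm = fit_mm(y, x, seed=rep, n_resamples=50)
            rejections += abs(mm.zstats[1]) > 1.959964
        assert rejections <= 8  # 3-sigma binomial bound around 5% of 40


class TestSpilloverRegression:
    @pytest.fixture
    def monthly_inputs(self):
        cal = make_calendar("2000-01-01", "2015-09-30")
        covariates = generate_covariates(CovariateConfig(seed=3), cal)
        recipe = {c: "hp_cycle" for c in DESIGN_COLUMNS}
        cycles = prep.apply_recipe(covariates[list(DESIGN_COLUMNS)], recipe)
        x, names = build_design(cycles)
        return covariates, cycles, x, names

    def test_known_coefficient_recovery(self, monthly_inputs):
        covariates, cycles, x, names = monthly_inputs
        pi = np.zeros(len(names))
        pi[names.index("old_dep")] = 2.8
        rng = np.random.default_rng(9)
        y = x @ pi + 0.003 * rng.standard_normal(len(x))
        indices = pd.DataFrame({"TCI": y}, index=cycles.index)
        table = spillover_regression(
            indices, covariates, recipe={c: "hp_cycle" for c in DESIGN_COLUMNS},
            response_transform="none", n_resamples=100, seed=1,
        )
        row = table.tidy[table.tidy.term == "old_dep"].iloc[0]
        se = abs(row["coef"] / row["z"])
        assert abs(row["coef"] - 2.8) < 3 * se

    def test_nineteen_responses_give_nineteen_rows(self, monthly_inputs):
        covariates, cycles, x, names = monthly_inputs
        rng = np.random.default_rng(2)
        cols = {"TCI": rng.standard_normal(len(cycles))}
        for i in range(18):
            cols[f"CCS{i+1}"] = rng.standard_normal(len(cycles))
        indices = pd.DataFrame(cols, index=cycles.index)
        table = spillover_regression(
            indices, covariates, response_transform="none", n_resamples=50, seed=0
        )
        assert table.outliers.shape[0] == 19
        assert table.tidy["response"].nunique() == 19
        text = table.format_text()
        assert text.count("\n") == 19  # header + 19 rows

    def test_zero_noise_response_has_zero_outliers(self, monthly_inputs):
        covariates, cycles, x, names = monthly_inputs
        pi = np.array([0.1, -0.5, 2.8, 0.3, -0.2, 1.0, 0.05])
        indices = pd.DataFrame({"TCI": x @ pi}, index=cycles.index)
        table = spillover_regression(
            indices, covariates, response_transform="none", n_resamples=50, seed=0
        )
        assert table.outliers.loc["TCI"].tolist() == [0, 0, 0]

    def test_misalignment_reported(self, monthly_inputs):
        covariates, cycles, *_ = monthly_inputs
        indices = pd.DataFrame(
            {"TCI": np.zeros(10)}, index=covariates.index[:10]
        )
        with pytest.raises(ValueError, match="misaligned"):
            spillover_regression(indices, covariates)


class TestEffectClassification:
    @pytest.mark.parametrize(
        "young, ysig, old, osig, expected",
        [
            (-0.585, True, 1.261, True, "convex"),  # printed CCS3 pattern
            (1.250, True, -2.660, True, "concave"),  # printed CCS8 pattern
            (0.1, False, 0.2, False, "none"),
            (-0.5, False, 2.853, True, "positive-ageing"),
            (0.1, False, -0.627, True, "negative-ageing"),
            (-0.5, True, 0.1, False, "none"),
        ],
    )
    def test_demographic_effect(self, young, ysig, old, osig, expected):
        assert classify_demographic_effect(young, ysig, old, osig) == expected

    @pytest.mark.parametrize(
        "coef, sig, expected",
        [
            (1.735, True, "pro-cyclical"),  # printed CCS2 pattern
            (-1.078, True, "counter-cyclical"),  # printed CCS5 pattern
            (0.5, False, "acyclical"),
        ],
    )
    def test_cyclicality(self, coef, sig, expected):
        assert classify_cyclicality(coef, sig) == expected
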
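"""Design matrices, penalized WLS, the backfitting engine and the baseline."""

import numpy as np
import pytest
from scipy import optimize

from gwgcharts.bct import BCTParams, bct_quantile
from gwgcharts.preprocess import BMIGroup, GainRecord, ShiftedGainRecord
from gwgcharts.smooth_fit import (
    MCurveSpec,
    ModelSpec,
    SmoothCurveSpec,
    _deviance,
    build_design,
    curve_standard_error,
    fit_gamlss_bct,
    fit_linear_baseline,
    fit_penalized_wls,
    predict_params,
)
from gwgcharts.synthetic_data import SyntheticConfig, simulate_cohort
from gwgcharts.pipeline import prepare_group
from tests.conftest import RECOVERY_SEED


def shifted(t, y, group=BMIGroup.NORMAL):
    return [
        ShiftedGainRecord(f"w{i}", ti, yi - 20.0, group, False, y=yi)
        for i, (ti, yi) in enumerate(zip(t, y))
    ]


class TestBuildDesign:
    def test_bspline_partition_of_unity(self):
        t = np.linspace(0, 44.9, 500)
        basis, penalty = build_design(t, MCurveSpec(internal_breakpoints=(12, 20, 28, 34)))
        assert np.allclose(basis.sum(axis=1), 1.0, atol=1e-12)
        assert not penalty.any()

    def test_constant_in_span(self):
        t = np.linspace(0, 44, 200)
        basis, _ = build_design(t, MCurveSpec())
        coef, *_ = np.linalg.lstsq(basis, np.full(200, 3.7), rcond=None)
        assert np.allclose(basis @ coef, 3.7, atol=1e-10)

    def test_df2_smoothing_spline_is_affine(self):
        """With df = 2 the penalty null space (affine) is all that survives."""
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(0, 44, 400))
        y = np.sin(t / 5.0) + rng.normal(0, 0.3, t.size)
        basis, penalty = build_design(t, SmoothCurveSpec(df=2.0))
        beta, lam, achieved = fit_penalized_wls(basis, penalty, y, np.ones_like(y), 2.0)
        fitted = basis @ beta
        slope = np.polyfit(t, fitted, 1)
        assert np.max(np.abs(fitted - np.polyval(slope, t))) < 1e-6
        assert achieved == pytest.approx(2.0, abs=0.01)

    def test_breakpoint_outside_data_warns(self):
        t = np.linspace(15, 44, 100)
        with pytest.warns(UserWarning, match="breakpoints"):
            build_design(t, MCurveSpec(internal_breakpoints=(12.0, 20.0, 28.0, 34.0)))

    def test_too_few_distinct_ages_fatal(self):
        t = np.repeat([10.0, 20.0, 30.0], 20)
        with pytest.raises(ValueError, match="distinct"):
            build_design(t, MCurveSpec())


class TestFitEngine:
    def test_median_recovery_at_anchor_weeks(self, normal_chart, normal_truth):
        """Fitted median gain tracks the generator truth within 0.3 kg."""
        for wk in (20.0, 40.0):
            fitted = predict_params(normal_chart, wk).mu - 20.0
            assert abs(fitted - normal_truth.median_gain(wk)) < 0.3

    def test_constant_truth_yields_flat_slt_curves(self):
        """Data with constant sigma/nu/tau: the fitted S/L/T curves show no
        wiggle beyond sampling noise.

        Oracle: replicate fits on independent data give an empirical
        pointwise standard error of each link-scale curve; the mean curve
        range across replicates stays below three times its maximum."""
        p = BCTParams(mu=30.0, sigma=0.08, nu=0.8, tau=12.0)
        weeks = np.linspace(0.0, 42.0, 85)
        etas = {name: [] for name in ("sigma", "nu", "tau")}
        for seed in range(200, 206):
            rng = np.random.default_rng(seed)
            n = 6000
            t = rng.uniform(0, 42, n)
            y = np.asarray(bct_quantile(rng.uniform(size=n), p))
            chart = fit_gamlss_bct(shifted(t, y))
            for name in etas:
                etas[name].append(chart.curves[name].eta(weeks))
        for name, curves in etas.items():
            arr = np.array(curves)
            pointwise_se = arr.std(axis=0, ddof=1)
            mean_range = np.mean(arr.max(axis=1) - arr.min(axis=1))
            assert mean_range < 3.0 * pointwise_se.max(), name

    def test_curve_standard_errors_are_finite_and_positive(self, normal_chart):
        weeks = np.linspace(0.0, 42.0, 43)
        for name in ("mu", "sigma", "nu", "tau"):
            se = curve_standard_error(normal_chart, name, weeks)
            assert np.all(np.isfinite(se)) and np.all(se > 0)

    def test_refit_is_deterministic(self, normal_cohort):
        a = prepare_group(normal_cohort, BMIGroup.NORMAL, nudge_seed=RECOVERY_SEED)
        b = prepare_group(normal_cohort, BMIGroup.NORMAL, nudge_seed=RECOVERY_SEED)
        dev_a = fit_gamlss_bct(a, nudge_seed=RECOVERY_SEED).global_deviance
        dev_b = fit_gamlss_bct(b, nudge_seed=RECOVERY_SEED).global_deviance
        assert dev_a == pytest.approx(dev_b, abs=1e-6)

    def test_objective_path_non_increasing(self, normal_chart):
        path = np.array(normal_chart.objective_path)
        assert np.all(np.diff(path) <= 1e-6)
        # raw deviance must also come down from its starting point
        assert normal_chart.deviance_path[-1] < normal_chart.deviance_path[0]

    def test_degenerate_spec_matches_constant_mle_oracle(self):
        """Constant curves on all four parameters reproduce the direct
        4-parameter maximum-likelihood fit (independent optimizer)."""
        rng = np.random.default_rng(42)
        n = 5000
        p = BCTParams(mu=30.0, sigma=0.08, nu=0.8, tau=12.0)
        t = rng.uniform(0, 42, n)
        y = np.asarray(bct_quantile(rng.uniform(size=n), p))
        spec = ModelSpec(
            m_curve=MCurveSpec(degree=0, internal_breakpoints=()),
            s_curve=SmoothCurveSpec(df=1),
            l_curve=SmoothCurveSpec(df=1),
            t_curve=SmoothCurveSpec(df=1),
            tol=1e-6,
            max_outer_iterations=400,
        )
        chart = fit_gamlss_bct(shifted(t, y), spec)

        def negdev(par):
            mu, lsig, nu, ltau = par
            return _deviance(
                y, np.full(n, mu), np.full(n, np.exp(lsig)),
                np.full(n, nu), np.full(n, np.exp(ltau)),
            )

        oracle = optimize.minimize(
            negdev, [29.0, np.log(0.1), 1.0, np.log(10.0)],
            method="Nelder-Mead",
            options=dict(maxiter=6000, xatol=1e-9, fatol=1e-11),
        )
        assert chart.global_deviance == pytest.approx(oracle.fun, abs=0.1)

    def test_refuses_tiny_datasets(self):
        rng = np.random.default_rng(1)
        t = rng.uniform(0, 42, 50)
        y = rng.uniform(18, 35, 50)
        with pytest.raises(ValueError, match="refusing"):
            fit_gamlss_bct(shifted(t, y))

    def test_nonpositive_y_names_offender(self):
        rng = np.random.default_rng(2)
        t = rng.uniform(0, 42, 300)
        y = rng.uniform(18, 35, 300)
        records = shifted(t, y)
        records[5] = ShiftedGainRecord("bad", 10.0, -21.0, BMIGroup.NORMAL, False, y=-1.0)
        with pytest.raises(ValueError, match="bad"):
            fit_gamlss_bct(records)


class TestRecoveryReplicates:
    def test_median_recovery_and_coverage_over_replicates(self):
        """Across 20 seeded replicates of the default normal-weight cohort the
        fitted median-gain curve tracks truth (MAE < 0.3 kg at the check
        weeks) and P50/P2.3 coverage is calibrated."""
        from gwgcharts.charts import export_parameter_grid
        from gwgcharts.diagnostics import centile_coverage
        from gwgcharts.synthetic_data import default_truth

        truth = default_truth(BMIGroup.NORMAL)
        weeks = [13.0, 20.0, 26.0, 33.0, 40.0]
        errors, cov50, cov023 = [], [], []
        for seed in range(100, 120):
            cohort = simulate_cohort(
                SyntheticConfig(n_women=5000, seed=seed), groups=[BMIGroup.NORMAL]
            )
            data = prepare_group(cohort, BMIGroup.NORMAL, nudge_seed=seed)
            chart = fit_gamlss_bct(data, nudge_seed=seed)
            errors.append(
                np.mean([
                    abs(predict_params(chart, w).mu - 20.0 - truth.median_gain(w))
                    for w in weeks
                ])
            )
            cover = centile_coverage(data, export_parameter_grid(chart))
            cov50.append(cover[50.0])
            cov023.append(cover[2.3])
        assert np.mean(errors) < 0.3
        assert 0.48 <= np.mean(cov50) <= 0.52
        assert 0.013 <= np.mean(cov023) <= 0.033


class TestLinearBaseline:
    def test_exact_line_recovered(self):
        t = np.linspace(5, 40, 50)
        data = [GainRecord(f"w{i}", ti, 1.5 + 0.4 * ti, BMIGroup.NORMAL)
                for i, ti in enumerate(t)]
        fit = fit_linear_baseline(data)
        assert fit.slope == pytest.approx(0.4, abs=1e-10)
        assert fit.intercept == pytest.approx(1.5, abs=1e-9)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_ols_consistency(self):
        rng = np.random.default_rng(7)
        t = rng.uniform(0, 42, 1000)
        g = 0.35 * t + rng.normal(0, 1, 1000)
        data = [GainRecord(f"w{i}", ti, gi, BMIGroup.NORMAL)
                for i, (ti, gi) in enumerate(zip(t, g))]
        assert fit_linear_baseline(data).slope == pytest.approx(0.35, abs=0.02)

    def test_degenerate_design_fatal(self):
        data = [GainRecord(f"w{i}", 20.0, float(i), BMIGroup.NORMAL) for i in range(5)]
        with pytest.raises(ValueError, match="degenerate"):
            fit_linear_baseline(data)


class TestPredictParams:
    def test_log_links_guarantee_positivity(self, normal_chart):
        rng = np.random.default_rng(3)
        for t in rng.uniform(0, 45, 10_000):
            # BCTParams construction itself enforces sigma, tau > 0
            predict_params(normal_chart, float(t))

    def test_outside_domain_rejected(self, normal_chart):
        for t in (-0.1, 45.1):
            with pytest.raises(ValueError, match="domain"):
                predict_params(normal_chart, t)
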
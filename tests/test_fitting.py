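"""Least-squares fitting, information criteria, and the F/normality tests."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from gelkill.fitting import (
    FitResult,
    akaike_weights,
    compare_models,
    compute_aic,
    confidence_intervals,
    fit_model,
    lack_of_fit_test,
    nested_f_test,
    nested_lr_test,
    residual_diagnostics,
)
from gelkill.gel_data import records_to_frame, GelMeasurement
from gelkill.models import STUDY_PARAMS, get_model
from gelkill.synth import NoiseModel, builtin_designs, generate_dataset

pytestmark = pytest.mark.filterwarnings("ignore::UserWarning")

NOISELESS = NoiseModel(kind="none")


def simulate(model_name, design_name, params=None, noise=NOISELESS, seed=2):
    designs = builtin_designs()
    params = params or STUDY_PARAMS[model_name]
    return generate_dataset(designs[design_name], get_model(model_name), params, noise, seed=seed)


class TestFitModel:
    @pytest.mark.parametrize(
        "name,design", [("MA", "D1-B"), ("Sat", "D1-A"), ("Power", "D1-B"), ("SiGMA", "D1-B")]
    )
    def test_zero_noise_identifiability(self, name, design):
        truth = STUDY_PARAMS[name]
        data = simulate(name, design)
        fit = fit_model(data, get_model(name), n_starts=10, seed=2, keep_data=False)
        assert fit.ssr < 1e-12
        for p, v in truth.items():
            assert fit.params[p] == pytest.approx(v, rel=1e-6)

    def test_ssr_matches_residuals_and_bounds_hold(self, filtered_replica):
        fit = fit_model(filtered_replica, get_model("MA"), n_starts=5, seed=0)
        assert fit.ssr == pytest.approx(float(fit.residuals @ fit.residuals), rel=1e-10)
        for p, (lo, hi) in fit.model.bounds.items():
            assert lo <= fit.params[p] <= hi

    def test_deterministic_given_seed(self):
        data = simulate("MA", "dataset2", noise=NoiseModel(kind="gaussian", sigma=0.5))
        f1 = fit_model(data, get_model("MA"), n_starts=8, seed=7, keep_data=False)
        f2 = fit_model(data, get_model("MA"), n_starts=8, seed=7, keep_data=False)
        assert f1.params == f2.params
        assert f1.ssr == f2.ssr

    def test_rejects_zero_counts(self):
        df = records_to_frame([GelMeasurement(1, 1, 1, 1e4, 0, 0, 0.0)] * 5)
        with pytest.raises(ValueError, match="zero"):
            fit_model(df, get_model("EG"))

    def test_parameter_recovery_under_noise(self):
        """Moderate-noise simulation: estimates unbiased, CIs calibrated."""
        truth = {"alpha": 2.77, "r": 0.576, "k": 3.79e-7}
        noise = NoiseModel(kind="gaussian", sigma=0.3)
        estimates, covered = [], 0
        n_rep = 30
        for rep in range(n_rep):
            data = simulate("MA", "dataset2", params=truth,
                            noise=noise, seed=100 + rep)
            fit = fit_model(data, get_model("MA"), n_starts=6, seed=rep, keep_data=False)
            estimates.append([fit.params[p] for p in ("alpha", "r", "k")])
            lo, hi = fit.ci95["r"]
            covered += lo <= truth["r"] <= hi
        means = np.mean(estimates, axis=0)
        for m, v in zip(means, truth.values()):
            assert m == pytest.approx(v, rel=0.05)
        assert covered >= 25  # ~95% nominal coverage of 30


class TestAIC:
    def test_published_delta_is_convention_free(self):
        # n ln(SSR_MA/SSR_SiGMA) + 2 (K_MA - K_SiGMA) for the 431-gel fits
        delta = compute_aic(164, 431, 3) - compute_aic(112, 431, 5)
        assert delta == pytest.approx(431 * math.log(164 / 112) - 4, rel=1e-12)
        assert delta == pytest.approx(160, abs=1.0)
        delta_sat = compute_aic(118.5, 431, 4) - compute_aic(112, 431, 5)
        assert delta_sat == pytest.approx(23, abs=1.0)

    def test_gaussian_constant_reproduces_printed_absolute_values(self):
        assert compute_aic(164, 431, 3, constant="gaussian") == pytest.approx(814, abs=1.0)
        assert compute_aic(112, 431, 5, constant="gaussian") == pytest.approx(654, abs=1.0)

    def test_halving_ssr_drops_aic_by_n_ln2(self):
        n = 100
        assert compute_aic(10.0, n, 3) - compute_aic(5.0, n, 3) == pytest.approx(
            n * math.log(2)
        )

    def test_zero_ssr_sentinel(self):
        with pytest.warns(UserWarning):
            assert compute_aic(0.0, 10, 2) == -math.inf


class TestAkaikeWeights:
    def test_equal_aics_give_uniform_weights(self):
        delta, w = akaike_weights([5.0, 5.0, 5.0, 5.0])
        np.testing.assert_allclose(w, 0.25)
        np.testing.assert_allclose(delta, 0.0)

    def test_two_model_closed_form(self):
        _, w = akaike_weights([0.0, 2.0])
        assert w[0] == pytest.approx(1 / (1 + math.exp(-1)), rel=1e-6)
        assert w[0] == pytest.approx(0.7311, abs=1e-4)
        assert w[1] == pytest.approx(0.2689, abs=1e-4)

    def test_published_delta_pattern(self):
        delta, w = akaike_weights([160.0, 23.0, 14.0, 0.0])
        assert w[3] == pytest.approx(1.0, abs=2e-3)
        assert w[2] == pytest.approx(0.001, abs=2e-3)
        assert w[0] < 1e-10 and w[1] < 1e-4
        assert delta.min() == 0.0
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_constant_shift(self):
        aics = [3.0, 7.5, 4.2]
        d1, w1 = akaike_weights(aics)
        d2, w2 = akaike_weights([a + 431.7 for a in aics])
        np.testing.assert_allclose(d1, d2)
        np.testing.assert_allclose(w1, w2)


def _toy_fit(ssr, n_obs, n_params, name="MA"):
    return FitResult(
        model=get_model(name), params={}, ssr=ssr, n_obs=n_obs, n_params=n_params,
        aic=compute_aic(ssr, n_obs, n_params), residuals=np.zeros(n_obs),
        converged=True, n_starts_used=1, seed=0, boundary_warning=False, ci95=None,
    )


class TestNestedTests:
    def test_identical_fits_give_f_zero(self):
        f, _, p = nested_f_test(_toy_fit(8.0, 20, 2), _toy_fit(8.0, 20, 3))
        assert f == 0.0
        assert p == 1.0

    def test_hand_computed_f(self):
        # ((10-8)/1) / (8/17) = 4.25
        f, dfs, p = nested_f_test(_toy_fit(10.0, 20, 2), _toy_fit(8.0, 20, 3))
        assert f == pytest.approx(4.25)
        assert dfs == (1, 17)
        assert 0 < p < 1

    def test_reduced_must_not_beat_full(self):
        with pytest.raises(ValueError, match="optimizer"):
            nested_f_test(_toy_fit(5.0, 20, 2), _toy_fit(8.0, 20, 3))

    def test_lr_chi_square(self):
        chi2, df, p = nested_lr_test(_toy_fit(10.0, 20, 2), _toy_fit(8.0, 20, 3))
        assert chi2 == pytest.approx(20 * math.log(10 / 8))
        assert df == 1


class TestLackOfFit:
    @staticmethod
    def _toy_data():
        rows = []
        concs = {(1e4, 0.0): [3000, 3400], (1e4, 24.0): [7000, 8000], (1e4, 48.0): [15000, 18000]}
        for (ta, t), values in concs.items():
            for i, v in enumerate(values):
                rows.append(GelMeasurement(1, 1, i + 1, ta, 0.0, t, v))
        return records_to_frame(rows)

    def test_brute_force_anova_decomposition(self):
        data = self._toy_data()
        fit = fit_model(data, get_model("EG"), n_starts=5, seed=0)
        F, (df_lof, df_pe), p = lack_of_fit_test(fit)
        # independent decomposition: pure error about group means
        y = np.log(data["b16_measured"].to_numpy())
        ss_pe = sum(
            np.sum((y[i : i + 2] - y[i : i + 2].mean()) ** 2) for i in (0, 2, 4)
        )
        ss_lof = fit.ssr - ss_pe
        assert df_lof == 3 - 2 and df_pe == 6 - 3
        assert F == pytest.approx((ss_lof / 1) / (ss_pe / 3), rel=1e-9)
        assert 0 < p <= 1

    def test_perfect_group_mean_fit_gives_zero(self):
        # model through every group mean: SSR equals pure error, SS_lof = 0
        data = self._toy_data()
        fit = fit_model(data, get_model("EG"), n_starts=5, seed=0)
        y = np.log(data["b16_measured"].to_numpy())
        ss_pe = sum(np.sum((y[i : i + 2] - y[i : i + 2].mean()) ** 2) for i in (0, 2, 4))
        fit.ssr = ss_pe  # as if predictions hit every group mean
        F, _, p = lack_of_fit_test(fit, data)
        assert F == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_requires_replicates(self):
        rows = [GelMeasurement(1, 1, 1, 1e4, 0.0, t, 1000 * (t + 1)) for t in (0.0, 24.0, 48.0)]
        fit = fit_model(records_to_frame(rows), get_model("EG"), n_starts=3, seed=0)
        with pytest.raises(ValueError, match="replicated"):
            lack_of_fit_test(fit)


class TestResidualDiagnostics:
    def test_bimodal_residuals_strongly_rejected(self):
        fit = _toy_fit(100.0, 100, 2)
        fit.residuals = np.concatenate([np.full(50, -1.0), np.full(50, 1.0)])
        fit.residuals += np.linspace(-1e-6, 1e-6, 100)  # break exact ties
        out = residual_diagnostics(fit)
        assert out["shapiro_p"] < 1e-3

    def test_constant_residuals_flagged_degenerate(self):
        fit = _toy_fit(1.0, 10, 2)
        fit.residuals = np.full(10, 0.3)
        out = residual_diagnostics(fit)
        assert out["degenerate"]
        assert math.isnan(out["shapiro_w"])

    def test_normal_residuals_usually_pass(self):
        rng = np.random.default_rng(42)
        fit = _toy_fit(200.0, 200, 2)
        fit.residuals = rng.normal(size=200)
        assert residual_diagnostics(fit)["shapiro_p"] > 0.05


class TestConfidenceIntervals:
    @staticmethod
    def _linear_data(sigma=0.2, seed=3):
        rng = np.random.default_rng(seed)
        t = np.repeat([0.0, 24.0, 48.0, 72.0], 5)
        y = math.log(1e4 / 2.5) + 0.7 * t / 24.0 + rng.normal(0, sigma, t.size)
        rows = [
            GelMeasurement(1, 1, i + 1, 1e4, 0.0, float(tt), float(math.exp(yy)))
            for i, (tt, yy) in enumerate(zip(t, y))
        ]
        return records_to_frame(rows), t / 24.0, y

    def test_matches_closed_form_ols_interval(self):
        """EG is linear in (ln alpha, r); its r CI must equal the OLS slope CI."""
        data, t_days, y = self._linear_data()
        fit = fit_model(data, get_model("EG"), n_starts=8, seed=0)
        import statsmodels.api as sm
        ols = sm.OLS(y, sm.add_constant(t_days)).fit()
        lo, hi = ols.conf_int()[1]
        assert fit.ci95["r"][0] == pytest.approx(lo, rel=1e-5)
        assert fit.ci95["r"][1] == pytest.approx(hi, rel=1e-5)

    def test_zero_noise_interval_collapses(self):
        data, _, _ = self._linear_data(sigma=0.0)
        fit = fit_model(data, get_model("EG"), n_starts=5, seed=0)
        lo, hi = fit.ci95["r"]
        assert hi - lo < 1e-6

    def test_bootstrap_brackets_truth(self):
        data, _, _ = self._linear_data()
        fit = fit_model(data, get_model("EG"), n_starts=5, seed=0)
        ci = confidence_intervals(fit, method="bootstrap", n_boot=60, seed=1)
        assert ci["r"][0] < 0.7 < ci["r"][1]


class TestModelComparison:
    def test_selects_generating_model_on_its_own_data(self, filtered_replica):
        fits = [
            fit_model(filtered_replica, get_model(n), n_starts=6, seed=0, keep_data=False)
            for n in ("MA", "SiGMA")
        ]
        comp = compare_models(fits)
        assert comp.best == "SiGMA"
        assert min(comp.delta.values()) == 0.0
        assert sum(comp.weights.values()) == pytest.approx(1.0, abs=1e-12)

    def test_tie_prefers_fewer_parameters(self):
        a, b = _toy_fit(10.0, 50, 3), _toy_fit(10.0, 50, 3, name="Sat")
        b.n_params = 4
        b.aic = a.aic
        comp = compare_models([b, a])
        assert comp.best == "MA"
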
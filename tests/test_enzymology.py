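"""Burst kinetics, single-turnover and tight-binding fitting."""

import numpy as np
import pytest

from puckerfit import (BurstKineticsModel, TightBindingModel, TimeCourse,
                       Titration, burst_model_eval, fit_kd_app,
                       fit_multiple_turnover, fit_single_turnover,
                       fold_change, gen_time_course, gen_titration,
                       quadratic_bound_eval, single_turnover_eval)
from puckerfit.enzymology import quadratic_bound_bisect
from puckerfit.exceptions import (InsufficientDataError,
                                  UnidentifiableFitWarning)

# frozen from a 30-digit symbolic evaluation of 25*(1-exp(-2.3)) + 7.5
BURST_AT_T1 = 29.9935289069299066567514826551
# closed form 3 - sqrt(5) for A_T = B_T = K_D = 2 nM
AB_WORKED = 0.763932022500210303590826331269


class TestModelEvaluation:
    def test_passes_through_origin(self):
        assert burst_model_eval(25.0, 2.3, 7.5, 0.0) == 0.0
        assert single_turnover_eval(45.0, 2.6, 0.0) == 0.0

    def test_plateau_limit(self):
        assert burst_model_eval(25.0, 2.3, 0.0, 1e6) == pytest.approx(25.0)

    def test_high_precision_value(self):
        assert burst_model_eval(25.0, 2.3, 7.5, 1.0) == pytest.approx(
            BURST_AT_T1, rel=1e-14)

    def test_saturation_at_five_time_constants(self):
        assert single_turnover_eval(45.0, 2.6, 5.0 / 2.6) > 0.99 * 45.0

    def test_single_turnover_nests_in_burst(self):
        t = np.geomspace(0.01, 10, 30)
        for a, k in [(10, 0.5), (25, 2.3), (45, 2.6)]:
            assert np.allclose(single_turnover_eval(a, k, t),
                               burst_model_eval(a, k, 0.0, t))

    def test_monotone_and_initial_slope(self):
        t = np.linspace(0.0, 10.0, 500)
        y = burst_model_eval(25.0, 2.3, 7.5, t)
        assert np.all(np.diff(y) > 0)
        h = 1e-7
        slope = burst_model_eval(25.0, 2.3, 7.5, h) / h
        assert slope == pytest.approx(25.0 * 2.3 + 7.5, rel=1e-5)


class TestQuadraticBinding:
    def test_zero_protein_zero_complex(self):
        assert quadratic_bound_eval(0.0, 2.0, 3.0) == 0.0

    def test_tight_binding_limit(self):
        assert quadratic_bound_eval(10.0, 2.0, 1e-9) == pytest.approx(
            2.0, rel=1e-6)

    def test_worked_value(self):
        assert quadratic_bound_eval(2.0, 2.0, 2.0) == pytest.approx(
            AB_WORKED, rel=1e-12)
        assert quadratic_bound_bisect(2.0, 2.0, 2.0) == pytest.approx(
            AB_WORKED, rel=1e-10)

    def test_matches_bisection_on_log_grid(self):
        grid = np.geomspace(0.01, 1000.0, 10)
        for a_t in grid:
            for b_t in grid:
                for k_d in grid:
                    closed = quadratic_bound_eval(a_t, b_t, k_d)
                    root = quadratic_bound_bisect(a_t, b_t, k_d)
                    assert closed == pytest.approx(
                        root, rel=1e-10, abs=1e-12)
                    assert 0.0 <= closed <= min(a_t, b_t) + 1e-12

    def test_satisfies_mass_action(self):
        ab = quadratic_bound_eval(5.0, 2.0, 3.0)
        assert (5.0 - ab) * (2.0 - ab) == pytest.approx(3.0 * ab, rel=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            quadratic_bound_eval(-1.0, 2.0, 3.0)
        with pytest.raises(ValueError):
            quadratic_bound_eval(1.0, 2.0, 0.0)


class TestKineticFits:
    def test_noiseless_multiple_turnover_exact(self):
        tc = gen_time_course(25.0, 2.3, 7.5, noise_sd=0.0, replicates=3)
        fit = fit_multiple_turnover(tc)
        assert fit.amplitude == pytest.approx(25.0, rel=1e-6)
        assert fit.k_obs == pytest.approx(2.3, rel=1e-6)
        assert fit.v_ss == pytest.approx(7.5, rel=1e-6)
        assert fit.k_ss == fit.v_ss / fit.amplitude  # exact, derived

    def test_noiseless_single_turnover_exact(self):
        tc = gen_time_course(45.0, 2.6, 0.0, noise_sd=0.0, replicates=3)
        fit = fit_single_turnover(tc)
        assert fit.amplitude == pytest.approx(45.0, rel=1e-6)
        assert fit.k_obs == pytest.approx(2.6, rel=1e-6)
        assert np.isnan(fit.k_ss)

    def test_noisy_recovery_close(self):
        tc = gen_time_course(25.0, 2.3, 7.5, noise_sd=0.5, replicates=3,
                             seed=100)
        fit = fit_multiple_turnover(tc)
        assert fit.k_obs == pytest.approx(2.3, rel=0.15)
        assert fit.k_ss == pytest.approx(0.30, rel=0.15)
        assert fit.stderr["k_obs"] > 0

    def test_replicate_sem_errors_used_with_three_replicates(self):
        tc = gen_time_course(25.0, 2.3, 7.5, noise_sd=0.5, replicates=3,
                             seed=8)
        est = BurstKineticsModel().fit(tc.t, tc.product,
                                       replicate=tc.replicate)
        assert est.error_source_ == "replicate_sem"
        est2 = BurstKineticsModel().fit(tc.t, tc.product)
        assert est2.error_source_ == "pooled_covariance"

    def test_three_points_insufficient(self):
        with pytest.raises(InsufficientDataError):
            fit_single_turnover(TimeCourse(
                t=np.array([0.1, 1.0, 10.0]),
                product=np.array([1.0, 5.0, 9.0]),
                replicate=np.array([1, 1, 1])))

    def test_flat_signal_rejected(self):
        with pytest.raises(InsufficientDataError, match="flat"):
            fit_single_turnover(TimeCourse(
                t=np.geomspace(0.1, 10, 8),
                product=np.full(8, 5.0),
                replicate=np.ones(8, dtype=int)))

    def test_all_zero_signal_rejected(self):
        with pytest.raises(InsufficientDataError, match="zero"):
            fit_multiple_turnover(TimeCourse(
                t=np.geomspace(0.1, 10, 8),
                product=np.zeros(8),
                replicate=np.ones(8, dtype=int)))

    def test_sklearn_protocol(self):
        est = BurstKineticsModel(steady_state=False)
        assert est.get_params()["steady_state"] is False
        tc = gen_time_course(45.0, 2.6, 0.0, noise_sd=0.0, replicates=1)
        est.fit(tc.t.reshape(-1, 1), tc.product)
        pred = est.predict(np.array([[1.0]]))
        assert pred[0] == pytest.approx(single_turnover_eval(45.0, 2.6, 1.0),
                                        rel=1e-6)


class TestFoldChange:
    def test_lower_bound_reference(self):
        fc = fold_change(200.0, 2.3, reference_is_lower_bound=True)
        assert str(fc) == "> 87.0-fold"
        assert fc.value == pytest.approx(200.0 / 2.3)

    def test_identity(self):
        fc = fold_change(2.3, 2.3)
        assert fc.value == 1.0
        assert str(fc) == "1.0-fold"

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 1.0)


class TestBindingFit:
    def test_noiseless_exact_recovery(self):
        titr = gen_titration(3.0, 2.0, noise_sd=0.0)
        fit = fit_kd_app(titr)
        assert fit.k_d_app == pytest.approx(3.0, rel=1e-6)

    def test_noisy_recovery_close(self):
        titr = gen_titration(2.9, 2.0, noise_sd=0.03, seed=17)
        fit = fit_kd_app(titr)
        assert fit.k_d_app == pytest.approx(2.9, rel=0.2)

    def test_fit_scale_option(self):
        titr = gen_titration(3.0, 2.0, noise_sd=0.0)
        scaled = Titration(titr.a_total, titr.fraction_bound * 0.9,
                           titr.b_total)
        fit = fit_kd_app(scaled, fit_scale=True)
        assert fit.scale == pytest.approx(0.9, rel=1e-4)
        assert fit.k_d_app == pytest.approx(3.0, rel=1e-3)

    def test_saturated_titration_warns(self):
        a_t = np.array([50.0, 60.0, 80.0, 100.0, 150.0, 200.0])
        frac = quadratic_bound_eval(a_t, 2.0, 3.0) / 2.0
        with pytest.warns(UnidentifiableFitWarning, match="half-saturation"):
            TightBindingModel(b_total=2.0).fit(a_t, frac)

    def test_undersaturated_titration_warns(self):
        a_t = np.array([0.0, 0.1, 0.2, 0.3, 0.4, 0.5])
        frac = quadratic_bound_eval(a_t, 2.0, 30.0) / 2.0
        with pytest.warns(UnidentifiableFitWarning, match="half-saturation"):
            TightBindingModel(b_total=2.0).fit(a_t, frac)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_kd_app(Titration(np.array([0.0, 1.0, 5.0]),
                                 np.array([0.0, 0.2, 0.6]), 2.0))

    def test_csv_round_trip(self, tmp_path):
        titr = gen_titration(3.0, 2.0, noise_sd=0.03, seed=5)
        path = tmp_path / "titr.csv"
        titr.to_csv(path)
        back = Titration.from_csv(path, b_total=2.0)
        assert np.allclose(back.a_total, titr.a_total)
        assert np.allclose(back.fraction_bound, titr.fraction_bound)
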
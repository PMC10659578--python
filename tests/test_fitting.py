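"""Exponential, hyperbolic, linear k_obs, and BLI fits."""

import warnings

import numpy as np
import pytest

from steapkin import fixtures
from steapkin.fitting import (FitError, NoCurvatureWarning, compute_kd,
                              fit_bli, fit_hyperbolic, fit_linear_kobs,
                              fit_multiexponential, select_phase_count)
from steapkin.synth import (HyperbolicLaw, LinearLaw, NoiseModel, TimeCourse,
                            generate_bli, generate_timecourse,
                            generate_titration, log_time_grid)


class TestMultiExponential:
    def test_noiseless_biexponential_round_trip(self):
        """Recovered rates/fractions equal generator truth to 1e-6."""
        tc = fixtures.timecourse("fig2A_fadh_steap1", seed=0, sigma_AU=0.0)
        fit = fit_multiexponential(tc, 2, direction="rise")
        truth = dict(tc.provenance["phases"])
        assert fit.phases[0].k_obs == pytest.approx(7.7, rel=1e-6)
        assert fit.phases[1].k_obs == pytest.approx(0.67, rel=1e-6)
        assert fit.phases[0].amplitude == pytest.approx(truth[7.7], rel=1e-6)
        assert fit.phases[0].fraction == pytest.approx(60.0, rel=1e-6)
        assert fit.offset == pytest.approx(0.06, rel=1e-6)

    def test_constant_trace_gives_zero_amplitude_and_mean_offset(self):
        t = np.linspace(0.1, 10.0, 60)
        tc = TimeCourse(427.0, t, np.full(60, 0.25))
        fit = fit_multiexponential(tc, 1, direction="rise")
        assert abs(fit.phases[0].amplitude) < 1e-10
        assert fit.offset == pytest.approx(0.25, abs=1e-10)

    def test_phases_returned_fast_first_regardless_of_input_order(self):
        t = log_time_grid(1e-3, 20.0, 300)
        for phases in ([(0.5, 0.02), (8.0, 0.03)], [(8.0, 0.03), (0.5, 0.02)]):
            tc = generate_timecourse(phases, 0.1, NoiseModel(0.0, 0), t, 427.0)
            fit = fit_multiexponential(tc, 2)
            assert fit.phases[0].k_obs > fit.phases[1].k_obs
            assert fit.phases[0].k_obs == pytest.approx(8.0, rel=1e-6)

    def test_time_unit_rescaling_scales_rates_inversely(self):
        t = log_time_grid(1e-3, 20.0, 300)
        tc = generate_timecourse([(8.0, 0.03), (0.5, 0.02)], 0.1,
                                 NoiseModel(0.0, 0), t, 427.0)
        tc_ms = TimeCourse(427.0, t * 1000.0, tc.absorbance)
        fit_s = fit_multiexponential(tc, 2)
        fit_ms = fit_multiexponential(tc_ms, 2)
        for p_s, p_ms in zip(fit_s.phases, fit_ms.phases):
            assert p_ms.k_obs == pytest.approx(p_s.k_obs / 1000.0, rel=1e-5)
            assert p_ms.fraction == pytest.approx(p_s.fraction, rel=1e-5)

    @pytest.mark.parametrize("n_phases", [1, 2, 3])
    def test_fractions_sum_to_100(self, n_phases, rng):
        t = log_time_grid(1e-3, 50.0, 350)
        phases = [(10.0 ** (1 - i), 0.01 * (i + 1)) for i in range(n_phases)]
        tc = generate_timecourse(phases, 0.05, NoiseModel(0.002, 1), t, 427.0)
        fit = fit_multiexponential(tc, n_phases)
        assert sum(fit.fractions) == pytest.approx(100.0, abs=1e-6)

    def test_window_must_lie_within_data(self):
        tc = fixtures.timecourse("fig2A_fadh_steap1", seed=0)
        with pytest.raises(ValueError, match="window"):
            fit_multiexponential(tc, 1, window_s=(0.0, 100.0))

    def test_too_few_points_rejected(self):
        t = np.linspace(0.1, 1.0, 10)
        tc = TimeCourse(427.0, t, np.ones(10))
        with pytest.raises(ValueError, match="points"):
            fit_multiexponential(tc, 2)


class TestSelectPhaseCount:
    def test_pure_single_exponential_selects_one(self):
        t = log_time_grid(1e-3, 20.0, 300)
        tc = generate_timecourse([(2.0, 0.05)], 0.06, NoiseModel(0.0, 0), t,
                                 427.0)
        assert select_phase_count(tc, 3) == 1

    def test_two_phase_fixture_selects_two(self):
        tc = fixtures.timecourse("fig2A_fadh_steap1", seed=2)
        assert select_phase_count(tc, 3) == 2

    def test_white_noise_around_constant_selects_one(self, rng):
        t = np.linspace(0.1, 10.0, 200)
        tc = TimeCourse(427.0, t, 0.3 + 0.002 * rng.standard_normal(200))
        assert select_phase_count(tc, 3) == 1


class TestHyperbolic:
    def test_noiseless_recovery_of_published_parameters(self):
        table = generate_titration(HyperbolicLaw(12.0, 4.7),
                                   [1.0, 2.0, 5.0, 10.0, 20.0], 0.0, 0)
        fit = fit_hyperbolic(table)
        assert fit.vmax == pytest.approx(12.0, rel=1e-8)
        assert fit.km == pytest.approx(4.7, rel=1e-8)

    def test_half_saturation_property(self):
        table = generate_titration(HyperbolicLaw(8.0, 3.0),
                                   [3.0, 1.0, 10.0, 30.0], 0.0, 0)
        fit = fit_hyperbolic(table)
        predicted = fit.vmax * 3.0 / (fit.km + 3.0)
        assert predicted == pytest.approx(4.0, rel=1e-8)

    def test_noisy_fit_matches_grid_search_oracle(self):
        table = generate_titration(HyperbolicLaw(12.0, 4.7),
                                   [1.0, 2.0, 5.0, 10.0, 20.0], 0.05, 42)
        fit = fit_hyperbolic(table)
        # dense SSE grid as the independent optimum
        vg = np.linspace(8.0, 16.0, 401)
        kg = np.linspace(2.0, 8.0, 401)
        V, K = np.meshgrid(vg, kg)
        sse = np.zeros_like(V)
        for s, k in zip(table.substrate_uM, table.k_obs):
            sse += (k - V * s / (K + s)) ** 2
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert fit.vmax == pytest.approx(V[i, j], abs=vg[1] - vg[0])
        assert fit.km == pytest.approx(K[i, j], abs=kg[1] - kg[0])

    def test_linear_data_warns_about_unbounded_km(self):
        table = generate_titration(LinearLaw(1e4, 0.0),
                                   [1.0, 2.0, 3.0, 4.0], 0.0, 0)
        with pytest.warns(NoCurvatureWarning):
            fit_hyperbolic(table)


class TestLinearKobs:
    @pytest.mark.parametrize("k_on,k_off,kd", [
        (1.5e5, 7.5, 50.0),
        (3.5e3, 0.3, 85.7),
    ])
    def test_noiseless_published_parameters_give_published_kd(self, k_on,
                                                              k_off, kd):
        table = generate_titration(LinearLaw(k_on, k_off),
                                   [25.0, 75.0, 125.0, 175.0], 0.0, 0)
        fit = fit_linear_kobs(table)
        assert round(fit.kd_uM, 1) == pytest.approx(kd, abs=0.05)
        assert fit.k_on == pytest.approx(k_on, rel=1e-9)
        assert fit.k_off == pytest.approx(k_off, rel=1e-9)

    def test_two_points_fit_exactly_with_warning(self):
        from steapkin.synth import TitrationTable
        table = TitrationTable(np.array([10.0, 20.0]), np.array([2.0, 3.0]))
        with pytest.warns(UserWarning, match="two points"):
            fit = fit_linear_kobs(table)
        assert fit.residual_sse == pytest.approx(0.0, abs=1e-20)
        assert fit.k_off == pytest.approx(1.0, rel=1e-12)

    def test_equals_closed_form_normal_equations(self, rng):
        s = np.array([25.0, 75.0, 125.0, 175.0])
        k = 1.5e5 * s * 1e-6 + 7.5 + 0.3 * rng.standard_normal(4)
        from steapkin.synth import TitrationTable
        fit = fit_linear_kobs(TitrationTable(s, k))
        n = s.size
        slope = (n * (s @ k) - s.sum() * k.sum()) / \
            (n * (s @ s) - s.sum() ** 2)
        intercept = (k.sum() - slope * s.sum()) / n
        assert fit.k_on == pytest.approx(slope * 1e6, rel=1e-12)
        assert fit.k_off == pytest.approx(intercept, rel=1e-12)

    def test_negative_slope_is_an_error(self):
        from steapkin.synth import TitrationTable
        table = TitrationTable(np.array([1.0, 2.0, 3.0]),
                               np.array([3.0, 2.0, 1.0]))
        with pytest.raises(FitError, match="slope"):
            fit_linear_kobs(table)


class TestComputeKd:
    @pytest.mark.parametrize("k_on,k_off,expected", [
        (7.6e3, 0.2, 26.3),
        (1.1e4, 2.2, 200.0),
        (1.5e5, 7.5, 50.0),
        (3.5e3, 0.3, 85.7),
    ])
    def test_published_pairs(self, k_on, k_off, expected):
        assert float(f"{compute_kd(k_on, k_off):.3g}") == expected

    def test_zero_koff_gives_zero_kd(self):
        assert compute_kd(1e5, 0.0) == 0.0

    def test_nonpositive_kon_rejected(self):
        with pytest.raises(ValueError):
            compute_kd(0.0, 1.0)


class TestBLIFit:
    def test_noiseless_round_trip(self):
        series = generate_bli(5.0, 1.5, [0.6, 1.3, 2.5, 5.0, 10.0, 20.0],
                              0.05, NoiseModel(0.0, 0))
        fit = fit_bli(series)
        assert fit.kd_uM == pytest.approx(5.0, rel=1e-6)
        assert fit.rmax == pytest.approx(1.5, rel=1e-6)

    def test_req_at_kd_is_half_rmax(self):
        series = generate_bli(5.0, 1.5, [0.6, 1.3, 2.5, 5.0, 10.0, 20.0],
                              0.05, NoiseModel(0.0, 0))
        fit = fit_bli(series)
        j = int(np.flatnonzero(series.analyte_uM == 5.0)[0])
        assert fit.req[j] == pytest.approx(fit.rmax / 2.0, rel=1e-6)

    def test_too_few_concentrations_rejected(self):
        series = generate_bli(5.0, 1.0, [1.0, 5.0, 20.0], 0.05,
                              NoiseModel(0.0, 0))
        with pytest.raises(ValueError):
            fit_bli(series)
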
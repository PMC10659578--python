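"""Sequential chains, two-population oxidation, and the FAD shuttle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from steapkin.fitting import fit_multiexponential
from steapkin.kinetics import (PseudoFirstOrderWarning, SequentialModel,
                               ShuttleChainModel, TwoPopulationBindingModel,
                               bateman_fractions, electron_balance,
                               simulate_sequential, simulate_shuttle_chain,
                               simulate_two_population_oxidation)
from steapkin.synth import TimeCourse


def _ode_oracle(rates, t, rtol=1e-10):
    """Independent stiff integration of the chain (Radau)."""
    n = len(rates) + 1
    K = np.zeros((n, n))
    for i, k in enumerate(rates):
        K[i, i] -= k
        K[i + 1, i] += k
    c0 = np.zeros(n)
    c0[0] = 1.0
    t = np.asarray(t, dtype=float)
    t0 = 0.0 if t[0] > 0 else t[0]
    sol = solve_ivp(lambda _t, y: K @ y, (t0, t[-1]), c0, t_eval=t,
                    method="Radau", rtol=rtol, atol=1e-14)
    assert sol.success
    return sol.y.T


class TestSequential:
    def test_half_life(self):
        model = SequentialModel(("A", "B"), (1.0,))
        traj = simulate_sequential(model, 1.0, np.array([0.0, np.log(2.0)]))
        assert traj.species("A")[-1] == pytest.approx(0.5, rel=1e-12)

    def test_bateman_matches_stiff_ode_for_published_rates(self):
        """A->B->C with k = 177.9 and 0.13 s^-1 over 20 s."""
        rates = (177.9, 0.13)
        t = np.geomspace(1e-4, 20.0, 60)
        C = bateman_fractions(rates, t)
        C_ode = _ode_oracle(rates, t)
        np.testing.assert_allclose(C, C_ode, atol=1e-8)

    def test_degenerate_rates_fall_back_to_matrix_exponential(self):
        t = np.geomspace(1e-3, 10.0, 30)
        C = bateman_fractions((2.0, 2.0), t)
        C_ode = _ode_oracle((2.0, 2.0), t)
        np.testing.assert_allclose(C, C_ode, atol=1e-8)
        assert np.all(np.abs(C.sum(axis=1) - 1.0) < 1e-9)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(1e-4, 1e3), min_size=1, max_size=3),
           st.floats(0.1, 100.0))
    def test_mass_conservation(self, rates, c0):
        names = tuple(f"S{i}" for i in range(len(rates) + 1))
        t = np.geomspace(1e-4, 100.0, 40)
        traj = simulate_sequential(SequentialModel(names, rates), c0, t)
        np.testing.assert_allclose(traj.total(), c0, rtol=1e-9)
        assert np.all(traj.concentrations >= 0.0)

    def test_time_grid_refinement_invariance(self):
        model = SequentialModel(("A", "B", "C"), (5.0, 0.2))
        coarse = np.linspace(0.0, 10.0, 11)
        fine = np.linspace(0.0, 10.0, 101)
        tc = simulate_sequential(model, 2.0, coarse)
        tf = simulate_sequential(model, 2.0, fine)
        shared = np.isin(fine, coarse)
        np.testing.assert_allclose(tf.concentrations[shared],
                                   tc.concentrations, rtol=1e-9, atol=1e-12)

    def test_non_increasing_time_grid_rejected(self):
        model = SequentialModel(("A", "B"), (1.0,))
        with pytest.raises(ValueError, match="strictly increasing"):
            simulate_sequential(model, 1.0, np.array([0.0, 1.0, 1.0]))

    def test_rate_count_must_match_species(self):
        with pytest.raises(ValueError):
            SequentialModel(("A", "B", "C"), (1.0,))
        with pytest.raises(ValueError):
            SequentialModel(("A", "B"), (-1.0,))


class TestTwoPopulation:
    MODEL = TwoPopulationBindingModel((0.85, 0.15), (1.5e5, 7.6e3),
                                      (7.5, 0.2))

    def test_observed_rate_at_175_uM(self):
        """k_on [S] + k_off = 1.5e5 * 175e-6 + 7.5 = 33.75 s^-1."""
        fast, _slow = self.MODEL.observed_rates(175.0)
        assert fast == pytest.approx(33.75, rel=1e-12)

    def test_zero_substrate_decays_at_koff(self):
        t = np.geomspace(1e-3, 5.0, 50)
        with pytest.warns(PseudoFirstOrderWarning):
            trace = simulate_two_population_oxidation(self.MODEL, 0.0, 1.1, t)
        expected = 1.1 * (0.85 * np.exp(-7.5 * t) + 0.15 * np.exp(-0.2 * t))
        np.testing.assert_allclose(trace, expected, rtol=1e-12)

    def test_trace_is_non_increasing(self):
        t = np.geomspace(1e-4, 10.0, 200)
        trace = simulate_two_population_oxidation(self.MODEL, 175.0, 1.1, t)
        assert np.all(np.diff(trace) <= 0.0)

    def test_single_population_reduces_to_one_exponential(self):
        model = TwoPopulationBindingModel((1.0, 0.0), (1e5, 1e5), (2.0, 2.0))
        t = np.geomspace(1e-3, 2.0, 40)
        trace = simulate_two_population_oxidation(model, 100.0, 1.0, t)
        k = 1e5 * 100e-6 + 2.0
        np.testing.assert_allclose(trace, np.exp(-k * t), rtol=1e-12)

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            TwoPopulationBindingModel((0.7, 0.4), (1.0, 1.0), (0.0, 0.0))

    def test_negative_substrate_rejected(self):
        with pytest.raises(ValueError):
            simulate_two_population_oxidation(self.MODEL, -1.0, 1.0,
                                              np.array([0.0, 1.0]))


class TestShuttleChain:
    def test_no_nadph_means_no_change(self):
        model = ShuttleChainModel(nadph_uM=0.0, fe3_uM=50.0, k_sub=1.0)
        traj = simulate_shuttle_chain(model, np.linspace(0.0, 100.0, 20))
        drift = np.abs(traj.concentrations - traj.concentrations[0][None, :])
        assert drift.max() < 1e-9

    def test_electron_bookkeeping_holds_everywhere(self):
        model = ShuttleChainModel(k_hyd=0.05, k_et=5.0, k_sub=0.5,
                                  nadph_uM=20.0, fad_uM=5.0,
                                  steap1_heme_uM=1.0, steap2_heme_uM=1.1,
                                  fe3_uM=100.0)
        traj = simulate_shuttle_chain(model, np.linspace(0.0, 200.0, 100))
        held, supplied = electron_balance(traj)
        assert np.all(held <= supplied + 1e-6)

    def test_slow_hydride_transfer_is_rate_limiting(self):
        """With k_hyd = 1e-3 s^-1 and downstream rates >= 1 s^-1 the heme
        reduction progress curve is monoexponential with an effective rate
        within 10% of the NADPH consumption rate."""
        model = ShuttleChainModel(k_hyd=1e-3, k_release=1.0,
                                  k_bind_steap1=1.0, k_bind_steap2=1.0,
                                  k_et=10.0, nadph_uM=10.0, fad_uM=5.0,
                                  steap1_heme_uM=15.0, steap2_heme_uM=15.0)
        t = np.geomspace(1.0, 6000.0, 300)
        traj = simulate_shuttle_chain(model, t)
        ferrous = traj.species("heme_ferrous")
        nadph = traj.species("nadph")
        k_heme = fit_multiexponential(
            TimeCourse(427.0, t, ferrous), 1, direction="rise").phases[0].k_obs
        k_nadph = fit_multiexponential(
            TimeCourse(427.0, t, nadph), 1, direction="decay").phases[0].k_obs
        assert k_heme == pytest.approx(k_nadph, rel=0.10)
        assert k_nadph == pytest.approx(1e-3, rel=0.10)

    def test_degenerate_all_zero_rates_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ShuttleChainModel(k_hyd=0.0, k_release=0.0, k_bind_steap1=0.0,
                              k_bind_steap2=0.0, k_et=0.0, k_sub=0.0)

    def test_heme_pool_required(self):
        with pytest.raises(ValueError):
            ShuttleChainModel(steap1_heme_uM=0.0, steap2_heme_uM=0.0)
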
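"""Synthetic dataset generators: determinism, noiseless exactness, fixtures."""

import numpy as np
import pytest

from steapkin import fixtures
from steapkin.kinetics import SequentialModel
from steapkin.spectral import SpeciesLibrary
from steapkin.synth import (ExperimentConditions, HyperbolicLaw, LinearLaw,
                            NoiseModel, generate_bli, generate_rapid_scan,
                            generate_timecourse, generate_titration,
                            log_time_grid)


class TestRapidScan:
    def test_same_seed_is_bit_identical_different_seed_differs(self):
        a = fixtures.rapid_scan("fig3A_b5r", seed=7)
        b = fixtures.rapid_scan("fig3A_b5r", seed=7)
        c = fixtures.rapid_scan("fig3A_b5r", seed=8)
        np.testing.assert_array_equal(a.absorbance, b.absorbance)
        assert not np.array_equal(a.absorbance, c.absorbance)

    def test_noiseless_dataset_equals_composition(self, ref_library):
        lib = ref_library
        mech = SequentialModel(("ferric_heme", "ferrous_heme"), (2.0,))
        cond = ExperimentConditions(enzyme_uM=1.1, dead_time_s=0.0)
        t = np.linspace(0.0, 3.0, 20)
        ds = generate_rapid_scan(mech, lib, cond, NoiseModel(0.0, 0), t)
        from steapkin.kinetics import simulate_sequential
        traj = simulate_sequential(mech, 1.1, t)
        E = lib.epsilon_matrix(["ferric_heme", "ferrous_heme"])
        expected = (traj.concentrations / 1000.0) @ E.T
        np.testing.assert_array_equal(ds.absorbance, expected)

    def test_three_species_fixture_has_rank_three(self):
        """Noiseless matrix of the three-species reduction has numerical
        rank 3 (singular values above 1e-10 of the largest)."""
        ds = fixtures.rapid_scan("fig3A_b5r", seed=0, sigma_AU=0.0)
        s = np.linalg.svd(ds.absorbance, compute_uv=False)
        assert int(np.sum(s > 1e-10 * s[0])) == 3

    def test_species_missing_from_library_rejected(self, ref_library):
        mech = SequentialModel(("ferric_heme", "nonesuch"), (1.0,))
        with pytest.raises(KeyError, match="nonesuch"):
            generate_rapid_scan(mech, ref_library,
                                ExperimentConditions(enzyme_uM=1.0),
                                NoiseModel(0.0, 0), np.linspace(0, 1, 5))

    def test_dead_time_advances_the_mechanism(self, ref_library):
        mech = SequentialModel(("ferric_heme", "ferrous_heme"), (100.0,))
        t = np.linspace(0.0, 0.1, 10)
        make = lambda dt: generate_rapid_scan(
            mech, ref_library, ExperimentConditions(enzyme_uM=1.0,
                                                    dead_time_s=dt),
            NoiseModel(0.0, 0), t)
        a0 = make(0.0).absorbance
        a5 = make(5e-3).absorbance  # ~40% of A already converted
        assert not np.allclose(a0[0], a5[0])


class TestTimeCourse:
    def test_single_phase_plateau(self):
        t = log_time_grid(1e-3, 100.0, 50)
        tc = generate_timecourse([(5.0, 0.04)], 0.06, NoiseModel(0.0, 0), t,
                                 427.0, "rise")
        assert tc.absorbance[-1] == pytest.approx(0.10, rel=1e-8)

    def test_biphasic_fixture_matches_hand_computed_sum(self):
        tc = fixtures.timecourse("fig2A_fadh_steap1", seed=0, sigma_AU=0.0)
        t = tc.time_s
        expected = 0.06 + 0.03 * (1 - np.exp(-7.7 * t)) \
            + 0.02 * (1 - np.exp(-0.67 * t))
        np.testing.assert_allclose(tc.absorbance, expected, rtol=1e-12)

    def test_zero_amplitude_gives_constant_offset(self):
        t = np.linspace(0.1, 1.0, 10)
        tc = generate_timecourse([(1.0, 0.0)], 0.5, NoiseModel(0.0, 0), t,
                                 427.0, "decay")
        np.testing.assert_array_equal(tc.absorbance, np.full(10, 0.5))

    def test_empty_phase_list_rejected(self):
        with pytest.raises(ValueError):
            generate_timecourse([], 0.0, NoiseModel(0.0, 0),
                                np.linspace(0.1, 1, 10), 427.0)

    def test_decay_direction(self):
        t = np.linspace(0.0, 10.0, 30)
        tc = generate_timecourse([(2.0, 0.05)], 0.02, NoiseModel(0.0, 0), t,
                                 427.0, "decay")
        np.testing.assert_allclose(tc.absorbance,
                                   0.02 + 0.05 * np.exp(-2.0 * t), rtol=1e-12)


class TestTitration:
    def test_hyperbolic_half_saturation(self):
        law = HyperbolicLaw(vmax=12.0, km=4.7)
        table = generate_titration(law, [4.7, 9.4, 1.0], 0.0, 0)
        assert table.k_obs[0] == pytest.approx(6.0, rel=1e-12)

    def test_linear_law_intercept_is_koff(self):
        assert LinearLaw(1.5e5, 7.5).k_obs(np.array([0.0]))[0] == 7.5

    def test_published_steap2_fast_phase_value(self):
        """k_on 1.1e4 M^-1 s^-1, k_off 2.2 s^-1 at 125 uM -> 3.575 s^-1."""
        table = generate_titration(LinearLaw(1.1e4, 2.2), [75.0, 125.0, 175.0],
                                   0.0, 0)
        assert table.k_obs[1] == pytest.approx(3.575, rel=1e-12)

    def test_noise_is_multiplicative_and_seeded(self):
        law = HyperbolicLaw(vmax=10.0, km=5.0)
        a = generate_titration(law, [1.0, 5.0, 20.0], 0.05, 3)
        b = generate_titration(law, [1.0, 5.0, 20.0], 0.05, 3)
        np.testing.assert_array_equal(a.k_obs, b.k_obs)
        assert a.provenance["truth"]["vmax"] == 10.0

    def test_negative_noise_fraction_rejected(self):
        with pytest.raises(ValueError):
            generate_titration(HyperbolicLaw(1.0, 1.0), [1.0, 2.0, 3.0],
                               -0.1, 0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            generate_titration(HyperbolicLaw(1.0, 1.0), [1.0, 2.0], 0.0, 0)


class TestBLI:
    def test_req_at_kd_is_half_rmax(self):
        series = generate_bli(5.0, 2.0, [5.0, 1.0, 10.0, 20.0], 0.05,
                              NoiseModel(0.0, 0))
        assert series.req[0] == pytest.approx(1.0, rel=1e-12)

    def test_req_saturates_at_rmax(self):
        series = generate_bli(5.0, 2.0, [5e4, 1.0, 10.0, 20.0], 0.05,
                              NoiseModel(0.0, 0))
        assert series.req[0] == pytest.approx(2.0, rel=1e-3)

    def test_fixture_has_six_association_and_dissociation_traces(self):
        series = fixtures.bli(seed=0)
        assert series.analyte_uM.size == 6
        assert series.association.shape[1] == 6
        assert series.dissociation.shape[1] == 6

    def test_nonpositive_kd_rejected(self):
        with pytest.raises(ValueError):
            generate_bli(0.0, 1.0, [1.0, 2.0, 4.0, 8.0], 0.05,
                         NoiseModel(0.0, 0))

    def test_determinism(self):
        a = fixtures.bli(seed=11)
        b = fixtures.bli(seed=11)
        np.testing.assert_array_equal(a.association, b.association)
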
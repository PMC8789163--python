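"""Synthetic data generators: reference gait, fixture model, populations."""

import numpy as np
import pytest
from scipy.optimize import brentq

from stridesim.dynamics import CompiledModel
from stridesim.synth import (make_initial_population, make_planar_fixture,
                             make_reference_gait)


class TestReferenceGait:
    def test_same_seed_bitwise_identical(self):
        a = make_reference_gait(seed=42)
        b = make_reference_gait(seed=42)
        for name in a.signals:
            assert np.array_equal(a.mean(name), b.mean(name))
            assert np.array_equal(a.sd(name), b.sd(name))

    def test_different_seeds_differ(self):
        a = make_reference_gait(seed=0)
        b = make_reference_gait(seed=1)
        assert not np.array_equal(a.mean("knee_r"), b.mean("knee_r"))

    def test_periodicity_and_symmetry_invariants(self):
        ref = make_reference_gait(seed=3)
        ref.validate()  # raises on violation

    def test_half_cycle_symmetry_exact(self):
        ref = make_reference_gait(seed=0)
        half = (len(ref.grid) - 1) // 2
        r = ref.mean("knee_r")[:-1]
        l = ref.mean("knee_l")[:-1]
        assert np.allclose(np.roll(r, -half), l, atol=1e-12)

    def test_vertical_grf_impulse_balance(self):
        ref = make_reference_gait(seed=0, body_mass=62.0)
        vy = ref.mean("grf_r_vy")
        bw = 62.0 * 9.81
        # single-foot cycle average must be half body weight (periodic gait)
        assert np.mean(vy[:-1]) == pytest.approx(0.5 * bw, rel=0.02)

    def test_double_hump_shape(self):
        ref = make_reference_gait(seed=0)
        vy = ref.mean("grf_r_vy")
        from scipy.signal import find_peaks
        peaks, _ = find_peaks(vy, prominence=50)
        assert len(peaks) == 2

    def test_stance_fraction_matches_request(self):
        ref = make_reference_gait(seed=0, stance_fraction=0.60)
        vy = ref.mean("grf_r_vy")
        assert np.mean(vy[:-1] > 20.0) == pytest.approx(0.60, abs=0.04)

    def test_sd_nonnegative_and_emg_bounded(self):
        ref = make_reference_gait(seed=5)
        for name, sig in ref.signals.items():
            assert np.all(sig["sd"] >= 0)
            if name.endswith("_emg"):
                assert np.all(sig["mean"] >= 0.0)
                assert np.all(sig["mean"] <= 1.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            make_reference_gait(stance_fraction=0.1)
        with pytest.raises(ValueError):
            make_reference_gait(speed=-1.0)

    def test_speed_metadata(self):
        ref = make_reference_gait(seed=0)
        assert ref.speed == pytest.approx(1.33)
        assert ref.cycle_duration > 0


class TestPlanarFixture:
    def test_total_mass(self, fixture_spec):
        assert fixture_spec.total_mass() == pytest.approx(62.0, abs=1e-9)

    def test_coordinate_counts(self, fixture_spec):
        assert len(fixture_spec.coordinates) == 11
        no_toes = make_planar_fixture(with_toes=False)
        assert len(no_toes.coordinates) == 9

    def test_nine_muscles_per_leg(self, fixture_spec):
        right = [m for m in fixture_spec.muscles if m.name.endswith("_r")]
        left = [m for m in fixture_spec.muscles if m.name.endswith("_l")]
        assert len(right) == len(left) == 9

    def test_three_contact_spheres_per_foot(self, fixture_spec):
        right = [s for s in fixture_spec.contact_spheres if s.segment.endswith("_r")]
        assert len(right) == 3

    def test_toe_spring_damper_values(self, fixture_spec):
        p = fixture_spec.passive_torques["mtp_r"]
        assert p.k_lin == pytest.approx(25.0)
        assert p.damping == pytest.approx(2.0)

    def test_triceps_surae_tagged(self, fixture_spec):
        assert sorted(fixture_spec.triceps_surae()) == [
            "gastroc_l", "gastroc_r", "soleus_l", "soleus_r"]

    def test_standing_penetration_below_5mm(self, fixture_spec):
        # static solve oracle: equilibrium pelvis height vs zero-force height
        cm = CompiledModel(fixture_spec)
        weight = 62.0 * 9.81

        def resid(ty):
            q = np.zeros(cm.nq)
            q[1] = ty
            qc, _ = cm.contact_generalized_forces(q, np.zeros(cm.nq))
            return qc[1] - weight

        ty_eq = brentq(resid, 0.80, 0.95, xtol=1e-12)

        def clearance(ty):
            q = np.zeros(cm.nq)
            q[1] = ty
            k = cm.kin(q)
            return min(k["py"][cm.body_index[s.segment]]
                       + np.sin(k["ang"][cm.body_index[s.segment]]) * s.location[0]
                       + np.cos(k["ang"][cm.body_index[s.segment]]) * s.location[1]
                       - s.radius
                       for s in fixture_spec.contact_spheres)
        assert -clearance(ty_eq) < 0.005

    def test_anthropometric_scaling(self):
        spec = make_planar_fixture(body_mass=70.0, height=1.80)
        assert spec.total_mass() == pytest.approx(70.0, abs=1e-9)
        thigh = spec.segment("thigh_r")
        assert thigh.length == pytest.approx(0.245 * 1.80)


class TestInitialPopulation:
    @pytest.fixture(scope="class")
    def small_config(self):
        from stridesim.ocp import OCPConfig
        return OCPConfig(n_mesh=2)

    def test_single_guess_is_cold_start(self, fixture_spec, small_config):
        from stridesim.guesses import cold_start
        from stridesim.ocp import GaitProblem

        pop = make_initial_population(fixture_spec, small_config, 1, seed=0)
        prob = GaitProblem(fixture_spec, small_config)
        base = cold_start(prob)
        assert len(pop) == 1
        assert np.allclose(pop[0]["z"], base["z"])

    def test_zero_perturbation_identical(self, fixture_spec, small_config):
        pop = make_initial_population(fixture_spec, small_config, 3, seed=0,
                                      scale=0.0)
        assert np.array_equal(pop[0]["z"], pop[1]["z"])
        assert np.array_equal(pop[1]["z"], pop[2]["z"])

    def test_bounds_respected_and_deterministic(self, fixture_spec, small_config):
        from stridesim.ocp import GaitProblem

        prob = GaitProblem(fixture_spec, small_config)
        pop1 = make_initial_population(fixture_spec, small_config, 4, seed=9)
        pop2 = make_initial_population(fixture_spec, small_config, 4, seed=9)
        for g1, g2 in zip(pop1, pop2):
            assert np.array_equal(g1["z"], g2["z"])
            assert np.all(g1["z"] >= prob.z_lo - 1e-12)
            assert np.all(g1["z"] <= prob.z_hi + 1e-12)
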
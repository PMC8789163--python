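"""Musculotendon mechanics: tendon law, characteristic curves, equilibrium."""

import numpy as np
import pytest
from scipy.optimize import brentq

from stridesim import muscle as mus
from stridesim.muscle import (MuscleTendonParams, activation_dynamics,
                              active_fl, fit_polynomials, force_velocity,
                              hill_equilibrium, passive_fl, tendon_norm_force,
                              tendon_norm_length, tendon_shift)


def make_params(**kw):
    defaults = dict(name="test", f_max=1000.0, l_m_opt=0.10, l_t_slack=0.20,
                    alpha_opt=0.1, v_max=10.0, mass=0.5)
    defaults.update(kw)
    return MuscleTendonParams(**defaults)


class TestTendonShift:
    def test_generic_curve_has_zero_shift(self):
        assert tendon_shift(35.0) == pytest.approx(0.0, abs=1e-15)

    def test_forty_percent_stiffness_matches_numerical_oracle(self):
        # oracle: solve ft(1; k, s) = ft(1; 35, 0) for s numerically
        k = 14.0
        target = tendon_norm_force(1.0, 35.0, 0.0)
        s_oracle = brentq(lambda s: tendon_norm_force(1.0, k, s) - target,
                          -0.1, 0.1, xtol=1e-14)
        assert tendon_shift(k) == pytest.approx(s_oracle, abs=1e-12)
        assert tendon_shift(k) == pytest.approx(0.023748, abs=1e-6)

    @pytest.mark.parametrize("k", [3.5, 10.0, 14.0, 21.0, 28.0, 35.0, 50.0])
    def test_defining_property(self, k):
        assert abs(tendon_norm_force(1.0, k, tendon_shift(k))
                   - tendon_norm_force(1.0, 35.0, 0.0)) < 1e-12


class TestTendonCurve:
    def test_value_at_0995(self):
        # algebraic inversion: exponent zero -> 0.2 - 0.25
        assert tendon_norm_force(0.995) == pytest.approx(-0.05, abs=1e-12)

    def test_value_at_unity(self):
        expected = 0.2 * np.exp(0.175) - 0.25
        assert tendon_norm_force(1.0) == pytest.approx(expected, abs=1e-12)
        assert tendon_norm_force(1.0) == pytest.approx(-0.011751, abs=1e-6)
        # cross-check against a numerical root of the length-form equation
        root = brentq(lambda f: tendon_norm_length(f) - 1.0, -0.2, 1.0, xtol=1e-14)
        assert tendon_norm_force(1.0) == pytest.approx(root, abs=1e-10)

    def test_round_trip_identity(self):
        lt = np.linspace(0.98, 1.06, 200)
        back = tendon_norm_length(tendon_norm_force(lt))
        assert np.max(np.abs(back - lt)) < 1e-10

    def test_monotone_increasing_and_stiffer_with_k(self):
        lt = np.linspace(0.96, 1.08, 400)
        for frac in (0.3, 0.6, 1.0):
            k = 35.0 * frac
            f = tendon_norm_force(lt, k, float(tendon_shift(k)))
            assert np.all(np.diff(f) > 0)
        slopes = [35.0 * frac * 0.2 * np.exp(35.0 * frac * 0.01)
                  for frac in (0.3, 0.6, 1.0)]
        assert slopes == sorted(slopes)

    def test_lower_stiffness_longer_tendon_at_equal_force(self):
        ks = 35.0 * np.arange(0.3, 1.01, 0.1)
        lts = [tendon_norm_length(0.5, k, float(tendon_shift(k))) for k in ks]
        assert np.all(np.diff(lts) < 0)  # decreasing in k


class TestCharacteristicCurves:
    def test_active_fl_peaks_at_optimal_length(self):
        grid = np.linspace(0.4, 1.6, 5000)
        vals = active_fl(grid)
        assert active_fl(1.0) >= vals.max() - 5e-3
        assert abs(grid[np.argmax(vals)] - 1.0) < 0.05

    def test_force_velocity_isometric_normalization(self):
        assert force_velocity(0.0) == pytest.approx(1.0, abs=1e-3)

    def test_force_velocity_max_shortening(self):
        assert force_velocity(-1.0) <= 0.01
        assert force_velocity(-1.0) >= 0.0

    def test_force_velocity_monotone(self):
        v = np.linspace(-1.2, 1.2, 500)
        assert np.all(np.diff(force_velocity(v)) > 0)

    def test_passive_small_below_optimal(self):
        lm = np.linspace(0.5, 1.0, 50)
        assert np.all(np.abs(passive_fl(lm)) < 0.02)
        assert np.all(np.diff(passive_fl(np.linspace(1.0, 1.8, 50))) > 0)

    def test_curves_smooth_complex_step_matches_fd(self):
        for fn in (active_fl, force_velocity, passive_fl):
            for x in (0.7, 0.95, 1.0, 1.2, -0.3, 0.1):
                cs = np.imag(fn(x + 1e-30j)) / 1e-30
                fd = (fn(x + 1e-6) - fn(x - 1e-6)) / 2e-6
                assert cs == pytest.approx(fd, rel=1e-6, abs=1e-8)


class TestHillEquilibrium:
    def test_rigid_tendon_limit(self):
        class StiffParams(MuscleTendonParams):
            k = property(lambda self: 2000.0)
            shift = property(lambda self: float(tendon_shift(2000.0)))

        p = StiffParams(name="stiff", f_max=1000.0, l_m_opt=0.10,
                        l_t_slack=0.20, alpha_opt=0.0001, v_max=10.0, mass=0.5)
        l_mt = 0.301
        ft = brentq(lambda f: float(hill_equilibrium(0.5, l_mt, 0.0, f, p)["residual"]),
                    -0.2, 1.5, xtol=1e-14)
        out = hill_equilibrium(0.5, l_mt, 0.0, ft, p)
        lm = out["lm_tilde"] * p.l_m_opt
        assert lm == pytest.approx(l_mt - p.l_t_slack, rel=0.01)

    def test_zero_activation_substitution(self):
        p = make_params()
        ft = 0.05
        out = hill_equilibrium(0.0, 0.30, 0.0, ft, p)
        # residual = ft - (passive + damping*vm) * cos(alpha); vm = 0 here
        expected = ft - (passive_fl(out["lm_tilde"])
                         + mus.FIBER_DAMPING * out["vm_tilde"]) * out["cos_alpha"]
        assert out["residual"] == pytest.approx(float(expected), abs=1e-12)

    def test_equilibrium_matches_bisection_oracle(self, rng):
        p = make_params()
        for _ in range(10):
            a = rng.uniform(0.05, 1.0)
            l_mt = rng.uniform(0.29, 0.32)

            def res(f):
                return float(hill_equilibrium(a, l_mt, 0.0, f, p)["residual"])

            lo, hi = -0.2, 1.6
            # brute-force bisection oracle
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                if res(lo) * res(mid) <= 0:
                    hi = mid
                else:
                    lo = mid
            oracle = 0.5 * (lo + hi)
            fast = brentq(res, -0.2, 1.6, xtol=1e-13)
            assert fast == pytest.approx(oracle, abs=1e-8)
            assert abs(res(fast)) < 1e-10

    def test_force_scaling(self):
        p = make_params()
        out = hill_equilibrium(0.5, 0.30, 0.0, 0.4, p)
        assert out["f_t"] == pytest.approx(0.4 * p.f_max)

    def test_domain_error_on_collapsed_fiber(self):
        p = make_params()
        with pytest.raises(mus.HillGeometryError):
            hill_equilibrium(0.5, 0.18, 0.0, 0.9, p)


class TestActivationDynamics:
    def test_fixed_point(self):
        assert activation_dynamics(0.5, 0.5) == pytest.approx(0.0, abs=1e-15)

    def test_activation_rate_limit(self):
        rate = activation_dynamics(1.0, 0.0)
        assert rate == pytest.approx(1.0 / mus.TAU_ACTIVATION, rel=1e-6)

    def test_deactivation_rate_limit(self):
        rate = activation_dynamics(0.0, 1.0)
        assert rate == pytest.approx(-1.0 / mus.TAU_DEACTIVATION, rel=1e-6)

    def test_monotone_approach_to_full_activation(self):
        from scipy.integrate import solve_ivp

        sol = solve_ivp(lambda t, a: activation_dynamics(1.0, a), (0, 0.2), [0.0],
                        rtol=1e-10, atol=1e-12, dense_output=True)
        a = sol.sol(np.linspace(0, 0.2, 200))[0]
        assert np.all(np.diff(a) > -1e-12)
        assert a[-1] == pytest.approx(1.0, abs=1e-3)


class TestParams:
    def test_k_and_shift_consistency(self):
        p = make_params(stiffness_fraction=0.4)
        assert p.k == pytest.approx(14.0)
        assert p.shift == pytest.approx(float(tendon_shift(14.0)))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            make_params(f_max=-1.0)
        with pytest.raises(ValueError):
            make_params(stiffness_fraction=0.0)
        with pytest.raises(ValueError):
            make_params(fast_twitch_fraction=1.5)

    def test_muscle_state_validation(self):
        p = make_params()
        mus.MuscleState(0.5, 0.1).validate(p)
        with pytest.raises(ValueError):
            mus.MuscleState(1.5, 0.1).validate(p)
        with pytest.raises(ValueError):
            mus.MuscleState(0.5, -0.3).validate(p)


class TestPolynomialGeometry:
    def test_constant_moment_arm_recovered_exactly(self):
        q = np.linspace(-1.0, 1.0, 80)[:, None]
        r = 0.05
        l0 = 0.3
        lengths = l0 - r * q[:, 0]
        arms = np.full((80, 1), r)
        geom = fit_polynomials(q, lengths, arms, ["knee"], order=3)
        qt = np.linspace(-0.9, 0.9, 33)[:, None]
        assert np.allclose(geom.length(qt), l0 - r * qt[:, 0], atol=1e-12)
        assert np.allclose(geom.moment_arms(qt), r, atol=1e-12)

    def test_biarticular_path_fit_below_1mm(self, cmodel):
        gi = cmodel.muscle_names.index("gastroc_r")
        geom = cmodel.geometry["gastroc_r"]
        # oracle: exact via-point polyline length over a fresh random sample
        rng = np.random.default_rng(7)
        ranges = cmodel.coordinate_ranges()
        qk = rng.uniform(*ranges["knee_r"], size=200)
        qa = rng.uniform(*ranges["ankle_r"], size=200)
        qfull = np.zeros((200, cmodel.nq))
        qfull[:, cmodel.coordinates.index("knee_r")] = qk
        qfull[:, cmodel.coordinates.index("ankle_r")] = qa
        exact = cmodel.path_length(qfull, gi)
        approx = geom.length(np.column_stack([qk, qa]))
        assert np.max(np.abs(exact - approx)) < 1e-3

    def test_moment_arm_equals_negative_gradient(self, cmodel):
        geom = cmodel.geometry["gastroc_r"]
        rng = np.random.default_rng(3)
        q = rng.uniform(-0.5, 0.1, size=(50, 2))
        h = 1e-6
        for j in range(2):
            dq = np.zeros(2)
            dq[j] = h
            fd = -(geom.length(q + dq) - geom.length(q - dq)) / (2 * h)
            assert np.max(np.abs(geom.moment_arms(q)[:, j] - fd)) < 1e-8

    def test_underdetermined_fit_refused(self):
        q = np.linspace(0, 1, 12)[:, None]
        with pytest.raises(mus.PolynomialFitError):
            fit_polynomials(q, np.ones(12), np.ones((12, 1)), ["q"], order=9)

    def test_velocity_chain_rule(self, cmodel):
        # l_MT_dot = -sum_j r_j qd_j via the fitted polynomials
        rng = np.random.default_rng(5)
        q = rng.uniform(-0.3, 0.3, cmodel.nq)
        qd = rng.standard_normal(cmodel.nq)
        lmt, vmt, arms = cmodel.muscle_kinematics(q, qd)
        h = 1e-7
        lmt2, _, _ = cmodel.muscle_kinematics(q + h * qd, qd)
        fd = (lmt2 - lmt) / h
        assert np.max(np.abs(vmt - fd)) < 1e-5
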
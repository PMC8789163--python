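"""OCP transcription: census, Jacobian, guesses, cost structure, symmetry."""

import numpy as np
import pytest

from stridesim.guesses import cold_start, hot_start, perturb_guess
from stridesim.ocp import GaitProblem, OCPConfig, Weights, cost_integrand
from stridesim.synth import make_planar_fixture


@pytest.fixture(scope="module")
def prob(fixture_geometry):
    spec = make_planar_fixture()
    return GaitProblem(spec, OCPConfig(n_mesh=3), geometry=fixture_geometry)


@pytest.fixture(scope="module")
def prob_n2(fixture_geometry):
    spec = make_planar_fixture()
    return GaitProblem(spec, OCPConfig(n_mesh=2), geometry=fixture_geometry)


class TestCensus:
    def test_counts_match_closed_form(self, prob):
        # independent count: nq=11, nm=18, d=3, 6 contact spheres
        N, d = 3, 3
        nq, nm, ns = 11, 18, 6
        nx = 2 * nq + 2 * nm       # 58
        n_var = 1 + N * d * nx + N * nm + N * d * (nm + nq) + N * d * 2 * ns
        n_con = N * d * (nx + nm + nq + 2 * ns) + 1
        census = prob.census()
        assert census["n_var"] == n_var == prob.n_var
        assert census["n_con"] == n_con == prob.n_con
        z = cold_start(prob)["z"]
        obj, con = prob.residuals(z)
        assert len(z) == n_var
        assert con.shape[-1] == n_con

    def test_locking_toes_removes_mtp_rows(self, fixture_geometry):
        cfg = OCPConfig(n_mesh=2)
        with_toes = GaitProblem(make_planar_fixture(), cfg,
                                geometry=fixture_geometry)
        without = GaitProblem(make_planar_fixture(with_toes=False), cfg)
        N, d = 2, 3
        # 2 coordinates fewer: states drop 2*2, u_a drops 2 per point
        dvar = N * d * 4 + N * d * 2
        dcon = N * d * (4 + 2)
        assert with_toes.n_var - without.n_var == dvar
        assert with_toes.n_con - without.n_con == dcon


class TestJacobian:
    def test_matches_dense_complex_step(self, prob_n2, rng):
        g = cold_start(prob_n2)
        z = np.clip(g["z"] + rng.uniform(-0.05, 0.05, prob_n2.n_var),
                    prob_n2.z_lo, prob_n2.z_hi)
        J = prob_n2.jacobian(z)

        def G(zz):
            o, c = prob_n2.residuals(zz)
            return np.concatenate([c, o])

        for _ in range(5):
            v = rng.standard_normal(prob_n2.n_var)
            dd = np.imag(G(z + 1e-30j * v)) / 1e-30
            err = np.max(np.abs(J @ v - dd)) / max(1.0, np.max(np.abs(dd)))
            assert err < 1e-12

    def test_coloring_valid(self, prob_n2):
        # no two same-colored columns share a row
        pat = prob_n2._pattern.tocsc()
        for r in range(pat.shape[0]):
            row = pat.getrow(r) if hasattr(pat, "getrow") else None
        csr = pat.tocsr()
        for r in range(csr.shape[0]):
            cols = csr.indices[csr.indptr[r]:csr.indptr[r + 1]]
            colors = prob_n2.colors[cols]
            assert len(set(colors)) == len(colors)


class TestCostIntegrand:
    def test_all_zero(self):
        assert cost_integrand(np.zeros(10), np.zeros(5), np.zeros(5),
                              np.zeros(10)) == pytest.approx(0.0)

    def test_activation_only_arithmetic(self):
        w = Weights(metabolic=0, activation=1.0, acceleration=0, passive=0)
        a = np.full(10, 0.5)
        val = cost_integrand(a, np.zeros(5), np.zeros(5), np.zeros(10), weights=w)
        assert val == pytest.approx(2.5)

    def test_distance_normalization_halves(self):
        # objective = quadrature / d; doubling d at fixed integral halves J
        integrand = 3.7
        assert integrand / 2.0 == pytest.approx(0.5 * integrand / 1.0)

    def test_objective_terms_sum_to_objective(self, prob):
        z = cold_start(prob)["z"]
        terms = prob.objective_terms(z)
        assert sum(terms.values()) == pytest.approx(prob.objective(z), rel=1e-9)


class TestGuesses:
    def test_cold_forward_velocity_exact(self, prob):
        z = prob.to_phys(cold_start(prob)["z"])
        _, xc, _, _, _ = prob.unpack(z)
        qd_tx = xc[..., prob.nq + prob.itx]
        assert np.allclose(qd_tx, prob.config.speed, atol=1e-12)

    def test_cold_respects_bounds(self, prob):
        z = cold_start(prob)["z"]
        assert np.all(z >= prob.z_lo - 1e-12)
        assert np.all(z <= prob.z_hi + 1e-12)

    def test_cold_satisfies_symmetry_map_trivially(self, prob):
        z = prob.to_phys(cold_start(prob)["z"])
        _, xc, _, _, _ = prob.unpack(z)
        x0 = prob.start_state(xc)
        # mirrored end state matches the guess start state except for tx
        first = xc[0, 0, :].copy()
        expected = x0.copy()
        keep = [i for i in range(prob.nx) if i != prob.itx]
        assert np.allclose(first[keep], expected[keep], atol=1e-6)

    def test_hot_requires_all_coordinates(self, prob, reference):
        import copy

        broken = copy.deepcopy(reference)
        del broken.signals["knee_r"]
        with pytest.raises(KeyError):
            hot_start(prob, broken)

    def test_hot_resampling_identity_on_grid(self, reference):
        # a spline through the reference grid reproduces the grid values
        s = reference.interpolator("knee_r")
        assert np.allclose(s(reference.grid / 100.0), reference.mean("knee_r"),
                           atol=1e-12)

    def test_hot_linear_signal_exact(self, reference):
        from scipy.interpolate import CubicSpline

        x = np.linspace(0, 1, 101)
        lin = 1.0 - np.abs(2 * x - 1)  # periodic triangle
        cs = CubicSpline(x, lin, bc_type="periodic")
        fine = np.linspace(0.1, 0.4, 57)  # inside a linear segment
        assert np.allclose(cs(fine), 1.0 - np.abs(2 * fine - 1), atol=2e-4)

    def test_hot_bandlimited_resample_error(self, reference):
        from scipy.interpolate import CubicSpline

        x = np.linspace(0, 1, 101)
        sig = np.sin(2 * np.pi * x) + 0.3 * np.cos(6 * np.pi * x)
        cs = CubicSpline(x, sig, bc_type="periodic")
        fine = np.linspace(0, 1, 1013)
        exact = np.sin(2 * np.pi * fine) + 0.3 * np.cos(6 * np.pi * fine)
        assert np.max(np.abs(cs(fine) - exact)) < 1e-3 * np.ptp(exact)

    def test_hot_respects_bounds(self, prob, reference):
        z = hot_start(prob, reference)["z"]
        assert np.all(z >= prob.z_lo - 1e-12)
        assert np.all(z <= prob.z_hi + 1e-12)

    def test_perturbation_stays_in_bounds(self, prob, rng):
        g = perturb_guess(prob, cold_start(prob), rng, scale=0.5)
        assert np.all(g["z"] >= prob.z_lo - 1e-12)
        assert np.all(g["z"] <= prob.z_hi + 1e-12)


class TestSymmetry:
    def test_objective_invariant_under_left_right_relabel(self, prob, reference):
        z = hot_start(prob, reference)["z"].copy()
        obj0 = prob.objective(z)
        zp = prob.to_phys(z)
        t_f, xc, ue, up, fc = (a.copy() if hasattr(a, "copy") else a
                               for a in prob.unpack(zp))
        perm_q = prob.cm.mirror_coordinate_permutation()
        perm_m = prob.cm.mirror_muscle_permutation()
        xc2 = xc[..., prob.perm_state]
        ue2 = ue[..., perm_m]
        up2 = np.concatenate([up[..., :prob.nm][..., perm_m],
                              up[..., prob.nm:][..., perm_q]], axis=-1)
        # mirror the contact spheres (r <-> l blocks of 3 spheres x 2 comps)
        fc2 = fc.reshape(fc.shape[:-1] + (2, 3, 2))[..., ::-1, :, :].reshape(fc.shape)
        z2 = prob.to_scaled(np.concatenate([[t_f], xc2.ravel(), ue2.ravel(),
                                            up2.ravel(), fc2.ravel()]))
        assert prob.objective(z2) == pytest.approx(obj0, rel=1e-9)
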
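"""Skeletal dynamics: symbolic oracle, energy conservation, structure."""

import numpy as np
import pytest

from stridesim.dynamics import CompiledModel, torque_actuator_dynamics
from stridesim.model import Joint, ModelSpec, Segment


def pendulum_spec(n_links=2):
    """Planar n-link pendulum hanging from a kinematically fixed base."""
    segs = [Segment("trunk", 1.0, 0.1, 0.1, (0.0, 0.0))]
    joints = [Joint("base", "planar-free", "ground", "trunk",
                    coordinate="pelvis", range=(-1, 1))]
    coords = ["pelvis_tx", "pelvis_ty", "pelvis_tilt"]
    parent = "trunk"
    for i in range(n_links):
        name = f"link{i}_r"
        segs.append(Segment(name, 1.5 + 0.5 * i, 0.03 + 0.01 * i, 0.4,
                            (0.02, -0.18)))
        joints.append(Joint(f"j{i}", "hinge", parent, name,
                            (0.0, 0.0 if i == 0 else -0.4),
                            coordinate=f"q{i}_r", range=(-6, 6)))
        coords.append(f"q{i}_r")
        parent = name
    return ModelSpec(name="pendulum", segments=segs, joints=joints,
                     coordinates=coords).validate()


@pytest.fixture(scope="module")
def pend():
    return CompiledModel(pendulum_spec())


@pytest.fixture(scope="module")
def symbolic_double_pendulum():
    """Closed-form M, C, G of the 2-link pendulum via a sympy Lagrangian."""
    import sympy as sp

    t = sp.Symbol("t")
    q1, q2 = sp.Function("q1")(t), sp.Function("q2")(t)
    g = 9.81
    masses = [1.5, 2.0]
    inertias = [0.03, 0.04]
    com = sp.Matrix([0.02, -0.18])
    L1 = 0.4

    def rot(a):
        return sp.Matrix([[sp.cos(a), -sp.sin(a)], [sp.sin(a), sp.cos(a)]])

    th1, th2 = q1, q1 + q2
    p1 = rot(th1) @ com
    p2 = rot(th1) @ sp.Matrix([0, -L1]) + rot(th2) @ com
    T = 0
    V = 0
    for p, m, I, th in ((p1, masses[0], inertias[0], th1),
                        (p2, masses[1], inertias[1], th2)):
        v = p.diff(t)
        T += sp.Rational(1, 2) * m * (v.T @ v)[0] + sp.Rational(1, 2) * I * th.diff(t) ** 2
        V += m * g * p[1]
    L = sp.simplify(T - V)
    qs = [q1, q2]
    taus = [sp.simplify(L.diff(q.diff(t)).diff(t) - L.diff(q)) for q in qs]
    syms = sp.symbols("p1 p2 v1 v2 a1 a2")
    subs = {}
    for q, ps, vs, as_ in zip(qs, syms[:2], syms[2:4], syms[4:]):
        subs[q.diff(t, 2)] = as_
        subs[q.diff(t)] = vs
        subs[q] = ps
    fns = [sp.lambdify(syms, tau.subs(subs), "numpy") for tau in taus]
    return fns


class TestSymbolicOracle:
    def test_inverse_dynamics_matches_lagrangian(self, pend, symbolic_double_pendulum):
        rng = np.random.default_rng(2)
        for _ in range(8):
            qh = rng.uniform(-2, 2, 2)
            vh = rng.uniform(-3, 3, 2)
            ah = rng.uniform(-5, 5, 2)
            q = np.zeros(5)
            qd = np.zeros(5)
            qdd = np.zeros(5)
            q[3:] = qh
            qd[3:] = vh
            qdd[3:] = ah
            tau = pend.inverse_dynamics(q, qd, qdd)[3:]
            expected = [f(*qh, *vh, *ah) for f in symbolic_double_pendulum]
            assert np.allclose(tau, expected, atol=1e-10)

    def test_mass_matrix_symmetric_positive_definite(self, pend):
        rng = np.random.default_rng(3)
        for _ in range(5):
            q = np.zeros(5)
            q[3:] = rng.uniform(-2, 2, 2)
            m = pend.mass_matrix(q)
            assert np.allclose(m, m.T, atol=1e-12)
            assert np.all(np.linalg.eigvalsh(m) > 0)

    def test_residual_linear_in_accelerations(self, pend, rng):
        q = np.zeros(5)
        q[3:] = rng.uniform(-1, 1, 2)
        qd = np.zeros(5)
        qd[3:] = rng.uniform(-1, 1, 2)
        m = pend.mass_matrix(q)
        u1 = rng.standard_normal(5)
        u2 = rng.standard_normal(5)
        r0 = pend.dynamics_residual(q, qd, np.zeros(5))
        r1 = pend.dynamics_residual(q, qd, u1)
        r2 = pend.dynamics_residual(q, qd, u2)
        # linearity and Jacobian = M
        assert np.allclose(r1 + r2 - 2 * r0, m @ (u1 + u2) - 2 * (m @ np.zeros(5)),
                           atol=1e-9)
        assert np.allclose(r1 - r0, m @ u1, atol=1e-9)


class TestEnergyConservation:
    def test_passive_swing_energy_drift(self, pend):
        from scipy.integrate import solve_ivp

        hinge = [3, 4]

        def rhs(t, y):
            q = np.zeros(5)
            qd = np.zeros(5)
            q[hinge] = y[:2]
            qd[hinge] = y[2:]
            m = pend.mass_matrix(q)[np.ix_(hinge, hinge)]
            bias = pend.inverse_dynamics(q, qd, np.zeros(5))[hinge]
            acc = np.linalg.solve(m, -bias)
            return np.concatenate([y[2:], acc])

        y0 = np.array([1.2, -0.5, 0.0, 0.0])
        sol = solve_ivp(rhs, (0, 1.0), y0, rtol=1e-12, atol=1e-12,
                        dense_output=True)

        def energy(y):
            q = np.zeros(5)
            qd = np.zeros(5)
            q[hinge] = y[:2]
            qd[hinge] = y[2:]
            ke, pe = pend.energy(q, qd)
            return ke + pe

        e0 = energy(y0)
        e1 = energy(sol.y[:, -1])
        assert abs(e1 - e0) < 1e-6


class TestStaticEquilibrium:
    def test_standing_fixture_residual_zero_with_compensating_torques(self, cmodel):
        q = np.zeros(cmodel.nq)
        q[1] = 0.885
        qd = np.zeros(cmodel.nq)
        qc, _ = cmodel.contact_generalized_forces(q, qd)
        tp = cmodel.passive_torque_vector(q, qd)
        grav = cmodel.inverse_dynamics(q, qd, np.zeros(cmodel.nq))
        residual = cmodel.dynamics_residual(q, qd, np.zeros(cmodel.nq),
                                            applied_tau=grav - qc - tp + qc + tp)
        assert np.allclose(residual, 0.0, atol=1e-9)


class TestMuscleTorques:
    def test_zero_forces_zero_torques(self, cmodel):
        q = np.zeros(cmodel.nq)
        tau = cmodel.muscle_joint_torques(q, np.zeros(cmodel.nm))
        assert np.allclose(tau, 0.0)

    def test_single_muscle_single_coordinate(self, cmodel):
        q = np.zeros(cmodel.nq)
        f = np.zeros(cmodel.nm)
        mi = cmodel.muscle_names.index("vasti_r")
        f[mi] = 100.0
        tau = cmodel.muscle_joint_torques(q, f)
        knee = cmodel.coordinates.index("knee_r")
        assert tau[knee] != 0.0
        others = [i for i in range(cmodel.nq) if i != knee]
        assert np.allclose(tau[others], 0.0)

    def test_toes_receive_no_muscle_torque(self, cmodel, rng):
        q = rng.uniform(-0.3, 0.3, cmodel.nq)
        tau = cmodel.muscle_joint_torques(q, rng.uniform(0, 1, cmodel.nm))
        for c in ("mtp_r", "mtp_l"):
            assert tau[cmodel.coordinates.index(c)] == 0.0

    def test_virtual_work_oracle(self, cmodel, rng):
        # tau = -d(sum F_T * l_MT)/dq at constant F_T
        q = rng.uniform(-0.3, 0.3, cmodel.nq)
        f_t = rng.uniform(0, 500, cmodel.nm)
        tau = cmodel.muscle_joint_torques(q, f_t)
        h = 1e-6
        for c in range(cmodel.nq):
            dq = np.zeros(cmodel.nq)
            dq[c] = h
            lp, _, _ = cmodel.muscle_kinematics(q + dq)
            lm, _, _ = cmodel.muscle_kinematics(q - dq)
            fd = -np.sum(f_t * (lp - lm)) / (2 * h)
            assert tau[c] == pytest.approx(fd, abs=2e-4)


class TestTorqueActuator:
    def test_fixed_point_at_saturation(self):
        assert torque_actuator_dynamics(1.0, 50.0, 50.0) == pytest.approx(0.0)

    def test_zero_input_exponential_decay(self):
        from scipy.integrate import solve_ivp

        sol = solve_ivp(lambda t, y: torque_actuator_dynamics(0.0, y, 50.0),
                        (0, 0.1), [10.0], rtol=1e-10)
        assert sol.y[0, -1] == pytest.approx(10.0 * np.exp(-0.1 / 0.035), rel=1e-6)

    def test_step_response_63_percent_at_tau(self):
        from scipy.integrate import solve_ivp

        sol = solve_ivp(lambda t, y: torque_actuator_dynamics(1.0, y, 50.0),
                        (0, 0.035), [0.0], rtol=1e-10)
        assert sol.y[0, -1] / 50.0 == pytest.approx(1 - np.exp(-1), rel=1e-6)
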
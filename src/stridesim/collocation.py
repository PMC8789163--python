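"""Radau collocation coefficients and small integration utilities.

The scheme is right-Radau (Radau IIA) with ``degree`` collocation points per
mesh interval, the last of which coincides with the interval endpoint.  State
trajectories are represented per interval by a Lagrange polynomial through
the interval start point and the ``degree`` collocation points, exactly as in
standard direct-collocation transcriptions.
"""

from __future__ import annotations

import numpy as np
from scipy.special import roots_jacobi

__all__ = ["RadauScheme", "radau_points", "integrate"]


def radau_points(degree: int) -> np.ndarray:
    """Collocation points in (0, 1], including the right endpoint."""
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if degree == 1:
        return np.array([1.0])
    x, _ = roots_jacobi(degree - 1, 1.0, 0.0)
    return np.append((x + 1.0) / 2.0, 1.0)


class RadauScheme:
    """Differentiation, continuity and quadrature coefficients.

    ``C[j, r]`` is the derivative of the j-th Lagrange basis polynomial
    (over nodes [0, tau_1..tau_d]) at collocation point r, so the collocation
    defect at point r reads ``sum_j C[j, r] x_j - h f(x_r, u_r)``.
    ``D[j]`` evaluates the basis at tau=1 (for Radau, D selects the last
    point).  ``B[r]`` are the quadrature weights over the collocation points.
    """

    def __init__(self, degree: int = 3):
        self.degree = degree
        tau = radau_points(degree)
        self.tau = tau
        nodes = np.concatenate([[0.0], tau])
        d = degree
        C = np.zeros((d + 1, d))
        D = np.zeros(d + 1)
        for j in range(d + 1):
            basis = np.poly1d([1.0])
            for k in range(d + 1):
                if k != j:
                    basis *= np.poly1d([1.0, -nodes[k]]) / (nodes[j] - nodes[k])
            D[j] = basis(1.0)
            dbasis = basis.deriv()
            for r in range(d):
                C[j, r] = dbasis(tau[r])
        # quadrature weights over the collocation points only
        B = np.zeros(d)
        for r in range(d):
            basis = np.poly1d([1.0])
            for k in range(d):
                if k != r:
                    basis *= np.poly1d([1.0, -tau[k]]) / (tau[r] - tau[k])
            B[r] = basis.integ()(1.0)
        self.C = C
        self.D = D
        self.B = B

    def step_map(self, z: complex) -> complex:
        """Stability function: x1/x0 for one collocation step of dx/dt = z x/h.

        Solves the stage equations ``sum_j C[j, r] x_j = z x_r`` for the
        stage values given x0 = 1 and returns the endpoint value.
        """
        d = self.degree
        A = self.C[1:, :].T.astype(complex) - z * np.eye(d)
        rhs = -self.C[0, :].astype(complex)
        stages = np.linalg.solve(A, rhs)
        return float(self.D[0]) + self.D[1:] @ stages


def integrate(f, x0, t_span, n_intervals: int, scheme: RadauScheme | None = None):
    """Integrate ``dx/dt = f(t, x)`` with the collocation scheme itself.

    Solves the per-interval stage equations with a damped Newton iteration
    (finite-difference Jacobian); intended for convergence/oracle tests at
    small problem sizes, not production simulation.
    Returns (t_mesh, x_mesh).
    """
    from scipy.optimize import fsolve

    scheme = scheme or RadauScheme(3)
    d = scheme.degree
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    n = x0.size
    t0, t1 = t_span
    h = (t1 - t0) / n_intervals
    ts = [t0]
    xs = [x0.copy()]
    xk = x0.copy()
    tk = t0
    for _ in range(n_intervals):
        def stage_res(flat, xk=xk, tk=tk):
            st = flat.reshape(d, n)
            res = np.empty_like(st)
            for r in range(d):
                acc = scheme.C[0, r] * xk
                for j in range(d):
                    acc = acc + scheme.C[j + 1, r] * st[j]
                res[r] = acc - h * np.asarray(f(tk + scheme.tau[r] * h, st[r]))
            return res.ravel()

        guess = np.tile(xk, d)
        sol = fsolve(stage_res, guess, xtol=1e-13)
        st = sol.reshape(d, n)
        xk = scheme.D[0] * xk + scheme.D[1:] @ st
        tk += h
        ts.append(tk)
        xs.append(xk.copy())
    return np.array(ts), np.array(xs)
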
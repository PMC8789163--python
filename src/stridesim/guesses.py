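"""Initial guesses for the gait optimal-control problem.

The cold start is a static standing posture translating forward with
constant muscle states and controls.  The hot start resamples a reference
gait's coordinate curves onto the collocation grid; in its default "rich"
form it additionally seeds activations from the reference EMG envelopes,
tendon-force states from a pointwise fiber/tendon equilibrium solve and
per-point algebraic controls from finite differences of the resampled
states, which substantially enlarges the basin of convergence of the
penalty-based solver.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .muscle import hill_equilibrium
from .ocp import GaitProblem

__all__ = ["standing_pose", "cold_start", "hot_start", "perturb_guess"]


def standing_pose(prob: GaitProblem):
    """Static bilaterally-symmetric standing configuration.

    Joint angles are neutral; the pelvis height balances the contact forces
    against gravity (scalar root solve on the vertical residual).
    """
    cm = prob.cm
    q = np.zeros(cm.nq)
    weight = cm.spec.total_mass() * cm.spec.gravity

    def vertical_residual(ty):
        qq = q.copy()
        qq[prob.ity] = ty
        qc, _ = cm.contact_generalized_forces(qq, np.zeros_like(qq))
        return qc[prob.ity] - weight

    q[prob.ity] = brentq(vertical_residual, 0.75, 0.98, xtol=1e-10)
    return q


def passive_tendon_forces(prob: GaitProblem, q, activation: float = 0.1):
    """Per-muscle ft_tilde at static fiber/tendon equilibrium in pose ``q``."""
    lmt, _, _ = prob.cm.muscle_kinematics(q, np.zeros_like(q))
    return _equilibrium_ft(prob, np.atleast_2d(lmt),
                           np.zeros((1, prob.nm)),
                           np.full((1, prob.nm), activation))[0]


def _equilibrium_ft(prob: GaitProblem, lmt, vmt, a):
    """Rootsolve ft_tilde of the Hill residual per muscle and sample."""
    P = lmt.shape[0]
    out = np.empty((P, prob.nm))
    for mi, m in enumerate(prob.cm.muscles):
        lo = m.shift - 0.25 + 2e-3
        hi = 1.7
        for p in range(P):
            def res(ft):
                return float(np.real(hill_equilibrium(
                    a[p, mi], float(lmt[p, mi]), float(vmt[p, mi]), ft, m,
                    validate=False)["residual"]))
            try:
                out[p, mi] = brentq(res, lo, hi, xtol=1e-10)
            except ValueError:
                out[p, mi] = lo + 1e-3
    nq, nm = prob.nq, prob.nm
    return np.clip(out, prob.x_lo[2 * nq + nm:2 * nq + 2 * nm] + 1e-4, None)


def _ground_consistent_height(prob: GaitProblem, q, times, clearance=0.0015):
    """Shift pelvis_ty so the lowest contact sphere sits near the ground."""
    cm = prob.cm
    for i in range(q.shape[0]):
        k = cm.kin(q[i])
        lowest = min(
            (k["py"][cm.body_index[s.segment]]
             + np.sin(k["ang"][cm.body_index[s.segment]]) * s.location[0]
             + np.cos(k["ang"][cm.body_index[s.segment]]) * s.location[1]
             - s.radius)
            for s in cm.spec.contact_spheres)
        q[i, prob.ity] += clearance - lowest
    return q


def _assemble(prob: GaitProblem, t_f, q, qd, a, ft, e, dft_scaled, ua):
    """Pack per-point arrays into a scaled, clipped decision vector.

    Lifted contact-force variables are seeded from the contact model at the
    guessed states.
    """
    N, d, nm, nq = prob.N, prob.d, prob.nm, prob.nq
    X = np.concatenate([q, qd, a, ft], axis=1).reshape(N, d, prob.nx)
    Ue = e.reshape(N, d, nm).mean(axis=1)
    Up = np.concatenate([dft_scaled, ua], axis=1).reshape(N, d, prob.nu_p)
    Fc = prob.cm.contact_force_values(q, qd).reshape(N, d, prob.nf)
    z = np.concatenate([[t_f], X.ravel(), Ue.ravel(), Up.ravel(), Fc.ravel()])
    return np.clip(prob.to_scaled(z), prob.z_lo, prob.z_hi)


def cold_start(prob: GaitProblem, activation: float = 0.1):
    """Static standing posture translating forward at the target speed."""
    cfg = prob.config
    t_f = float(np.clip(cfg.t_f_init, *cfg.t_f_bounds))
    times = prob.point_times(t_f)
    P = len(times)
    nq, nm = prob.nq, prob.nm
    q0 = standing_pose(prob)
    ft0 = passive_tendon_forces(prob, q0, activation)
    q = np.tile(q0, (P, 1))
    q[:, prob.itx] = cfg.speed * times
    qd = np.zeros((P, nq))
    qd[:, prob.itx] = cfg.speed
    a = np.full((P, nm), activation)
    ft = np.tile(ft0, (P, 1))
    e = np.full((P, nm), activation)
    return {"z": _assemble(prob, t_f, q, qd, a, ft, e,
                           np.zeros((P, nm)), np.zeros((P, nq))),
            "label": "cold"}


def hot_start(prob: GaitProblem, reference, activation: float = 0.1,
              rich: bool = True, emg_gain: float = 0.5):
    """Guess resampled from a reference gait dataset.

    Coordinate states follow the reference half cycle (with the pelvis height
    shifted to keep the stance foot at the ground).  With ``rich=False``
    muscle states and all controls are constant; with ``rich=True`` (default)
    activations track the reference EMG envelopes, tendon forces solve the
    pointwise fiber/tendon equilibrium and the algebraic controls are seeded
    from finite differences of the resampled states.
    """
    cm = prob.cm
    missing = [c for c in cm.coordinates if c not in reference.signals]
    if missing:
        raise KeyError(f"reference gait lacks coordinate curves: {missing}")
    cfg = prob.config
    t_cycle = reference.cycle_duration
    t_f = float(np.clip(0.5 * t_cycle, *cfg.t_f_bounds))
    times = prob.point_times(t_f)
    P = len(times)
    nq, nm = prob.nq, prob.nm
    phi = times / t_cycle

    q = np.zeros((P, nq))
    qd = np.zeros((P, nq))
    for ci, c in enumerate(cm.coordinates):
        s = reference.interpolator(c)
        q[:, ci] = s(phi)
        qd[:, ci] = s.derivative()(phi) / t_cycle
    q[:, prob.itx] = cfg.speed * times
    qd[:, prob.itx] = cfg.speed
    q = _ground_consistent_height(prob, q, times)
    qd[:, prob.ity] = np.gradient(q[:, prob.ity], times)

    if not rich:
        q0 = standing_pose(prob)
        ft0 = passive_tendon_forces(prob, q0, activation)
        return {"z": _assemble(prob, t_f, q, qd,
                               np.full((P, nm), activation),
                               np.tile(ft0, (P, 1)),
                               np.full((P, nm), activation),
                               np.zeros((P, nm)), np.zeros((P, nq))),
                "label": "hot"}

    a = np.full((P, nm), activation)
    for mi, m in enumerate(cm.muscles):
        sig = m.name + "_emg"
        if sig in reference.signals:
            cs = CubicSpline(reference.grid / 100.0,
                             reference.signals[sig]["mean"], bc_type="periodic")
            a[:, mi] = 0.03 + emg_gain * np.clip(cs(phi), 0.0, 1.0)
    lmt, vmt, _ = cm.muscle_kinematics(q, qd)
    ft = _equilibrium_ft(prob, lmt, vmt, a)
    ua = np.gradient(qd, times, axis=0)
    dft = np.gradient(ft, times, axis=0) / cfg.dft_scale
    return {"z": _assemble(prob, t_f, q, qd, a, ft, a.copy(),
                           np.clip(dft, -1, 1), ua),
            "label": "hot"}


def from_solution(prob: GaitProblem, solution) -> dict:
    """Warm-start guess by resampling a solution onto another mesh.

    The source solution may come from a coarser (or finer) transcription of a
    structurally identical model; states are interpolated per interval, the
    algebraic controls and contact forces are re-derived at the new
    collocation points.
    """
    src = solution.problem
    t_f = solution.t_f
    times = prob.point_times(t_f)
    x = src.sample_states(solution.z, np.minimum(times, t_f * (1 - 1e-12)))
    u = src.controls_at(solution.z, np.minimum(times, t_f * (1 - 1e-12)))
    nq, nm = prob.nq, prob.nm
    return {"z": _assemble(prob, t_f, x[:, :nq], x[:, nq:2 * nq],
                           x[:, 2 * nq:2 * nq + nm], x[:, 2 * nq + nm:],
                           u[:, :nm], u[:, nm:2 * nm], u[:, 2 * nm:]),
            "label": f"warm({solution.guess_label})"}


def perturb_guess(prob: GaitProblem, guess: dict, rng, scale: float = 0.01):
    """Uniform perturbation of a guess in scaled units, respecting bounds."""
    z = guess["z"] + rng.uniform(-scale, scale, size=prob.n_var)
    return {"z": np.clip(z, prob.z_lo, prob.z_hi),
            "label": guess["label"] + "+perturbed"}
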
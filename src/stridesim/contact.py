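"""Smooth compliant sphere-plane foot-ground contact and GRF analysis.

The ground is the horizontal plane y = 0.  The normal force follows a
Hertz-type penetration law with velocity-dependent dissipation,

    F_n = k * d^(3/2) * (1 + 1.5 * c * ddot),

where both the contact/no-contact switch and the 3/2 power are regularized so
the force is differentiable everywhere and effectively zero above ground.
Tangential force is smoothed Coulomb friction plus a viscous term, odd in the
slip velocity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._smooth import smooth_pos

__all__ = ["ContactSphere", "sphere_force", "sphere_force_planar",
           "hunt_crossley_unsmoothed", "model_grf", "first_vertical_peak"]

#: Penetration regularization depth (m); forces vanish ~quadratically above
#: ground over this scale.
SMOOTHING_EPS = 1e-5


@dataclass(frozen=True)
class ContactSphere:
    """One contact sphere attached to a model segment."""

    segment: str
    location: tuple           # center in the segment frame (x, y), m
    radius: float             # m
    stiffness: float = 1.0e6  # N m^-3/2
    dissipation: float = 2.0  # s/m
    mu_static: float = 0.8
    mu_dynamic: float = 0.8
    mu_viscous: float = 0.5   # s/m, scaled by the normal force
    transition_velocity: float = 0.1  # m/s

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("sphere radius must be > 0")
        if self.stiffness <= 0:
            raise ValueError("contact stiffness must be > 0")
        if self.dissipation < 0:
            raise ValueError("dissipation must be >= 0")


def _normal_force(delta, delta_dot, sphere: ContactSphere, eps=SMOOTHING_EPS):
    d = smooth_pos(delta, eps)
    hertz = sphere.stiffness * d * np.sqrt(d)
    damp = 1.0 + 1.5 * sphere.dissipation * delta_dot
    # keep the dissipation factor non-negative without a kink
    damp = smooth_pos(damp, 1e-2)
    return hertz * damp


def sphere_force_planar(delta, delta_dot, v_slip, sphere: ContactSphere,
                        eps=SMOOTHING_EPS):
    """Planar contact force (f_tangential, f_normal) in ground axes.

    ``delta`` is penetration depth (positive below ground), ``delta_dot`` its
    rate, ``v_slip`` the tangential velocity of the sphere center.  Total and
    smooth in all arguments.
    """
    fn = _normal_force(delta, delta_dot, sphere, eps)
    vt = sphere.transition_velocity
    coulomb = sphere.mu_dynamic * v_slip / np.sqrt(v_slip * v_slip + vt * vt)
    ft = -fn * (coulomb + sphere.mu_viscous * v_slip)
    return ft, fn


def sphere_force(delta, delta_dot, v_slip, sphere: ContactSphere,
                 eps=SMOOTHING_EPS):
    """3-vector contact force (Fx, Fy, Fz) with Fy normal to the ground.

    ``v_slip`` is the 2-vector (vx, vz) of tangential slip; scalars are
    treated as (vx, 0).
    """
    v_slip = np.atleast_1d(np.asarray(v_slip, dtype=float))
    if v_slip.shape[-1] == 1:
        v_slip = np.concatenate([v_slip, np.zeros_like(v_slip)], axis=-1)
    fn = _normal_force(delta, delta_dot, sphere, eps)
    speed = np.sqrt(np.sum(v_slip * v_slip, axis=-1))
    vt = sphere.transition_velocity
    coulomb = sphere.mu_dynamic / np.sqrt(speed * speed + vt * vt)
    ftan = -fn * (coulomb + sphere.mu_viscous) * v_slip.T
    fx, fz = ftan[0].T, ftan[1].T
    return np.stack(np.broadcast_arrays(fx, fn, fz), axis=-1)


def hunt_crossley_unsmoothed(delta, delta_dot, sphere: ContactSphere):
    """Reference piecewise Hunt-Crossley normal force (no smoothing)."""
    delta = np.asarray(delta, dtype=float)
    fn = sphere.stiffness * np.maximum(delta, 0.0) ** 1.5 \
        * np.maximum(1.0 + 1.5 * sphere.dissipation * np.asarray(delta_dot), 0.0)
    return np.where(delta > 0, fn, 0.0)


def model_grf(q, qdot, cmodel):
    """Per-foot ground reaction force and center of pressure.

    Parameters
    ----------
    q, qdot : coordinate vectors (model order)
    cmodel : a :class:`stridesim.dynamics.CompiledModel`

    Returns
    -------
    dict with per-side entries ``{"r": {...}, "l": {...}}`` each holding
    ``force`` (fx, fy), ``cop`` (x of the center of pressure from the
    vertical-force moment balance; nan when unloaded) and ``spheres``
    (per-sphere forces), plus ``total`` over both feet.
    """
    per_sphere = cmodel.contact_forces(q, qdot)  # list of dicts
    out = {"r": _foot_accumulator(), "l": _foot_accumulator()}
    for entry in per_sphere:
        side = "r" if entry["segment"].endswith("_r") else "l"
        out[side]["spheres"].append(entry)
        out[side]["force"] = out[side]["force"] + entry["force"]
        out[side]["moment"] = out[side]["moment"] + entry["force"][..., 1] * entry["position"][..., 0]
    for side in ("r", "l"):
        fy = out[side]["force"][..., 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            out[side]["cop"] = np.where(np.abs(fy) > 1e-9,
                                        out[side]["moment"] / np.where(np.abs(fy) > 1e-9, fy, 1.0),
                                        np.nan)
        del out[side]["moment"]
    out["total"] = out["r"]["force"] + out["l"]["force"]
    return out


def _foot_accumulator():
    return {"force": np.zeros(2), "moment": 0.0, "spheres": []}


def first_vertical_peak(vgrf, prominence: float = 50.0, fallback_fraction: float = 0.5):
    """First local maximum of a vertical-GRF stance series.

    Uses :func:`scipy.signal.find_peaks` with a prominence threshold; when no
    local maximum qualifies (e.g. a monotone ramp), falls back to the maximum
    over the first ``fallback_fraction`` of the series.
    """
    from scipy.signal import find_peaks

    vgrf = np.asarray(vgrf, dtype=float)
    if vgrf.size == 0:
        raise ValueError("empty vertical GRF series")
    peaks, _ = find_peaks(vgrf, prominence=prominence)
    if peaks.size:
        return float(vgrf[peaks[0]])
    n = max(1, int(round(fallback_fraction * vgrf.size)))
    return float(np.max(vgrf[:n]))
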
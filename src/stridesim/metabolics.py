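"""Phenomenological muscle metabolic energetics and cost of transport.

The muscle-level model splits metabolic power into activation heat,
maintenance heat, shortening/lengthening heat and mechanical work rate.  Two
implementations are provided:

* :func:`bhargava_rate` - every conditional replaced by a tanh blend of
  configurable sharpness, suitable for gradient-based optimal control;
* :func:`bhargava_rate_piecewise` - the literal piecewise model, used for
  reporting and as the independent reference in tests.

Away from the switching surfaces the two agree to well below 1%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._smooth import smooth_step, smooth_pos
from .muscle import MuscleTendonParams, active_fl

__all__ = [
    "MetabolicRates",
    "bhargava_rate",
    "bhargava_rate_piecewise",
    "cost_of_transport",
    "per_group_breakdown",
    "BASAL_RATE_W_PER_KG",
]

# Heat rate coefficients, W per kg of muscle mass.
_ACT_FAST = 133.0
_ACT_SLOW = 40.0
_MAINT_FAST = 111.0
_MAINT_SLOW = 74.0

BASAL_RATE_W_PER_KG = 1.2  # W per kg of *body* mass, added once per model


@dataclass
class MetabolicRates:
    """Component metabolic rates (W); fields broadcast as numpy arrays."""

    activation: np.ndarray
    maintenance: np.ndarray
    shortening: np.ndarray
    work: np.ndarray
    basal: np.ndarray
    total: np.ndarray


def _maintenance_fl_piecewise(lm_tilde):
    lm = np.asarray(lm_tilde, dtype=float)
    return np.where(lm <= 0.5, 0.5,
                    np.where(lm <= 1.0, lm,
                             np.where(lm <= 1.5, -2.0 * lm + 3.0, 0.0)))


def _maintenance_fl_smooth(lm_tilde, width):
    # Blend of the segments 0.5 | lm | 3 - 2 lm | 0 at lm = 0.5, 1.0, 1.5.
    lm = lm_tilde
    s1 = smooth_step(lm - 0.5, width)
    s2 = smooth_step(lm - 1.0, width)
    s3 = smooth_step(lm - 1.5, width)
    seg = 0.5 + s1 * (lm - 0.5)
    seg = seg + s2 * ((3.0 - 2.0 * lm) - lm)
    seg = seg + s3 * (0.0 - (3.0 - 2.0 * lm))
    return smooth_pos(seg, 1e-4)


def _recruitment(x):
    """Slow/fast-twitch recruitment weighting of excitation or activation."""
    return np.sin(0.5 * np.pi * x), 1.0 - np.cos(0.5 * np.pi * x)


def bhargava_rate(e, a, lm_tilde, vm_tilde, f_m_active, f_m_total,
                  params: MuscleTendonParams, sharpness: float = 100.0,
                  basal: float = 0.0, clamp_total: bool = True):
    """Smooth metabolic rate of one muscle.

    Parameters
    ----------
    e, a : excitation and activation in [0, 1]
    lm_tilde, vm_tilde : normalized fiber length and velocity
    f_m_active : active fiber force (N)
    f_m_total : total fiber force (N), active + passive
    sharpness : tanh blend sharpness; switch width is 1/sharpness
    basal : basal rate (W) to add to the total (0 at muscle level; the whole
        model adds 1.2 W/kg body mass once)
    clamp_total : smoothly clamp the muscle's net rate at >= 0 so eccentric
        work cannot drive the total negative

    Returns
    -------
    MetabolicRates
    """
    width = 1.0 / sharpness
    f_st = 1.0 - params.fast_twitch_fraction
    f_ft = params.fast_twitch_fraction
    e_s, e_f = _recruitment(e)
    a_s, a_f = _recruitment(a)

    h_act = params.mass * (_ACT_SLOW * f_st * e_s + _ACT_FAST * f_ft * e_f)
    h_maint = params.mass * _maintenance_fl_smooth(lm_tilde, width) * (
        _MAINT_SLOW * f_st * a_s + _MAINT_FAST * f_ft * a_f)

    # Shortening liberates heat at -alpha_S*v (v < 0); lengthening at
    # +alpha_L*v (v > 0).  Both branches are non-negative.
    v_m = vm_tilde * params.v_max * params.l_m_opt  # m/s, >0 lengthening
    f_iso = a * active_fl(lm_tilde) * params.f_max
    alpha_short = 0.16 * f_iso + 0.18 * f_m_active
    alpha_len = 0.157 * f_m_active
    lengthening = smooth_step(v_m, width * 0.1)
    h_sl = (1.0 - lengthening) * (-alpha_short * v_m) + lengthening * (alpha_len * v_m)

    w_dot = -f_m_active * v_m

    raw = h_act + h_maint + h_sl + w_dot
    if clamp_total:
        total = smooth_pos(raw, 1e-3) + basal
    else:
        total = raw + basal
    return MetabolicRates(activation=h_act, maintenance=h_maint, shortening=h_sl,
                          work=w_dot, basal=basal + 0.0 * np.asarray(raw),
                          total=total)


def bhargava_rate_piecewise(e, a, lm_tilde, vm_tilde, f_m_active, f_m_total,
                            params: MuscleTendonParams, basal: float = 0.0,
                            clamp_total: bool = True):
    """Literal piecewise counterpart of :func:`bhargava_rate`."""
    f_st = 1.0 - params.fast_twitch_fraction
    f_ft = params.fast_twitch_fraction
    e_s, e_f = _recruitment(e)
    a_s, a_f = _recruitment(a)
    h_act = params.mass * (_ACT_SLOW * f_st * e_s + _ACT_FAST * f_ft * e_f)
    h_maint = params.mass * _maintenance_fl_piecewise(lm_tilde) * (
        _MAINT_SLOW * f_st * a_s + _MAINT_FAST * f_ft * a_f)
    v_m = np.asarray(vm_tilde) * params.v_max * params.l_m_opt
    f_iso = a * active_fl(lm_tilde) * params.f_max
    h_sl = np.where(v_m > 0, 0.157 * np.asarray(f_m_active) * v_m,
                    -(0.16 * f_iso + 0.18 * np.asarray(f_m_active)) * v_m)
    w_dot = -np.asarray(f_m_active) * v_m
    raw = h_act + h_maint + h_sl + w_dot
    total = (np.maximum(raw, 0.0) if clamp_total else raw) + basal
    return MetabolicRates(activation=h_act, maintenance=h_maint, shortening=h_sl,
                          work=w_dot, basal=basal + 0.0 * raw, total=total)


def cost_of_transport(times, total_rate, distance, body_mass):
    """Whole-gait cost of transport, J kg^-1 m^-1.

    ``times``/``total_rate`` sample the summed metabolic rate (W, including
    any basal term) over one full gait cycle; ``distance`` is the forward
    distance traveled by the pelvis over that cycle.
    """
    times = np.asarray(times, dtype=float)
    total_rate = np.asarray(total_rate, dtype=float)
    if distance <= 0:
        raise ValueError("distance traveled must be positive")
    energy = np.trapezoid(total_rate, times)
    return energy / (body_mass * distance)


def per_group_breakdown(muscle_energy_a: dict, muscle_energy_b: dict,
                        groups: dict):
    """Share of the metabolic-cost difference attributable to muscle groups.

    ``muscle_energy_*`` map muscle name -> integrated metabolic energy (J) for
    two solutions over the same muscle set; ``groups`` maps group name -> list
    of muscle names and must partition the muscle set.  Returns group -> share
    of the total difference in percent (shares sum to 100 unless the total
    difference is zero, in which case all shares are 0).
    """
    if set(muscle_energy_a) != set(muscle_energy_b):
        raise ValueError("solutions have different muscle sets")
    grouped = [name for members in groups.values() for name in members]
    if sorted(grouped) != sorted(muscle_energy_a):
        raise ValueError("groups must partition the muscle set")
    delta = {name: muscle_energy_b[name] - muscle_energy_a[name]
             for name in muscle_energy_a}
    total = sum(delta.values())
    if total == 0.0:
        return {g: 0.0 for g in groups}
    return {g: 100.0 * sum(delta[name] for name in members) / total
            for g, members in groups.items()}
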
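"""Hill-type muscle-tendon mechanics.

Smooth characteristic curves (active/passive force-length, force-velocity),
the exponential tendon force-length law with adjustable stiffness and its
force-invariance shift, first-order excitation-activation coupling, the
implicit fiber/tendon force equilibrium used as a path constraint by the
optimal-control layer, and multivariate polynomial approximation of
muscle-tendon length and moment arms.

Conventions
-----------
* Normalized fiber length ``lm_tilde = l_M / l_M_opt``.
* Normalized fiber velocity ``vm_tilde = v_M / (v_max * l_M_opt)`` so that
  ``vm_tilde = -1`` is maximal shortening.
* Normalized tendon length ``lt_tilde = l_T / l_T_slack``; normalized tendon
  force ``ft_tilde = F_T / F_max``.
* The tendon law reads ``lt_tilde = log(5 (ft_tilde + 0.25 - s)) / k + 0.995``
  with generic stiffness ``k = 35``; the shift ``s`` keeps the force at
  ``lt_tilde = 1`` independent of ``k``.

All curve evaluations broadcast over numpy arrays and accept complex input
(complex-step differentiation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GENERIC_TENDON_STIFFNESS",
    "TAU_ACTIVATION",
    "TAU_DEACTIVATION",
    "FIBER_DAMPING",
    "PathPoint",
    "MuscleTendonParams",
    "MuscleState",
    "MTUGeometry",
    "tendon_shift",
    "tendon_norm_force",
    "tendon_norm_length",
    "tendon_compliance",
    "active_fl",
    "force_velocity",
    "passive_fl",
    "hill_equilibrium",
    "activation_dynamics",
    "fit_polynomials",
]

GENERIC_TENDON_STIFFNESS = 35.0
TAU_ACTIVATION = 0.015  # s
TAU_DEACTIVATION = 0.060  # s
FIBER_DAMPING = 0.01  # normalized, well-posedness of the force-velocity inverse

# Active force-length: sum of three Gaussians with length-dependent widths.
_FL_B = (
    (0.814483478343008, 1.055033428970575, 0.162384573599574, 0.063303448465465),
    (0.433004984392647, 0.716775413397760, -0.029947116970696, 0.200356847296188),
    (0.100000000000000, 1.000000000000000, 0.353553390593274, 0.000000000000000),
)

# Force-velocity: logarithmic curve f = d1*log(d2*v + d3 + sqrt((d2*v+d3)^2+1)) + d4.
_FV_D1 = -0.318323436899127
_FV_D2 = -8.149156043475250
_FV_D3 = -0.374121508647863
# d4 renormalized so that force_velocity(0) == 1 exactly (the published value
# gives 1.0022; the isometric normalization is load-bearing downstream).
_FV_D4 = 1.0 - _FV_D1 * np.log(_FV_D3 + np.sqrt(_FV_D3 * _FV_D3 + 1.0))

_KPE = 4.0
_E0 = 0.6


def tendon_shift(k):
    """Shift ``s`` making the tendon force at slack length independent of ``k``.

    Inverting the tendon law at ``lt_tilde = 1`` gives
    ``ft(1; k, s) = 0.2*exp(0.005 k) - 0.25 + s``; equating with the generic
    curve (k=35, s=0) yields the closed form below.  ``tendon_shift(35) == 0``.
    """
    return 0.2 * (np.exp(0.175) - np.exp(0.005 * np.asarray(k, dtype=float)))


def tendon_norm_force(lt_tilde, k=GENERIC_TENDON_STIFFNESS, s=0.0):
    """Normalized tendon force as a function of normalized tendon length."""
    return 0.2 * np.exp(k * (lt_tilde - 0.995)) - 0.25 + s


def tendon_norm_length(ft_tilde, k=GENERIC_TENDON_STIFFNESS, s=0.0):
    """Normalized tendon length as a function of normalized tendon force.

    Requires ``ft_tilde > s - 0.25`` for the logarithm to be defined.
    """
    return np.log(5.0 * (ft_tilde + 0.25 - s)) / k + 0.995


def tendon_compliance(ft_tilde, k=GENERIC_TENDON_STIFFNESS, s=0.0):
    """d(lt_tilde)/d(ft_tilde) along the tendon curve."""
    return 1.0 / (k * (ft_tilde + 0.25 - s))


def active_fl(lm_tilde):
    """Active force-length multiplier; peaks at ``lm_tilde`` ~ 1."""
    lm_tilde = np.asarray(lm_tilde)
    out = 0.0
    for b1, b2, b3, b4 in _FL_B:
        sigma = b3 + b4 * lm_tilde
        d = (lm_tilde - b2) / sigma
        out = out + b1 * np.exp(-0.5 * d * d)
    return out


def force_velocity(vm_tilde):
    """Force-velocity multiplier; 1 at rest, ~0 at maximal shortening."""
    t = _FV_D2 * np.asarray(vm_tilde) + _FV_D3
    return _FV_D1 * np.log(t + np.sqrt(t * t + 1.0)) + _FV_D4


def passive_fl(lm_tilde):
    """Passive fiber force multiplier; ~0 below optimal length."""
    return (np.exp(_KPE * (np.asarray(lm_tilde) - 1.0) / _E0) - 1.0) / (np.exp(_KPE) - 1.0)


def activation_dynamics(e, a, tau_act=TAU_ACTIVATION, tau_deact=TAU_DEACTIVATION,
                        width=0.1):
    """Smooth first-order excitation->activation coupling.

    da/dt = (e - a) * (sigma/tau_act + (1-sigma)/tau_deact) where sigma is a
    smooth switch on sign(e - a).  The fixed point is a = e; for e > a the
    rate approaches (e - a)/tau_act.
    """
    from ._smooth import smooth_step

    sigma = smooth_step(np.asarray(e) - np.asarray(a), width)
    return (e - a) * (sigma / tau_act + (1.0 - sigma) / tau_deact)


@dataclass(frozen=True)
class PathPoint:
    """A muscle path point fixed in a segment frame."""

    segment: str
    location: tuple  # (x, y) in the segment frame, m


@dataclass
class MuscleTendonParams:
    """Parameters of one Hill-type muscle-tendon unit."""

    name: str
    f_max: float                      # N
    l_m_opt: float                    # m
    l_t_slack: float                  # m
    alpha_opt: float = 0.1            # rad, pennation at optimal fiber length
    v_max: float = 10.0               # optimal fiber lengths / s
    stiffness_fraction: float = 1.0   # k = 35 * fraction
    fast_twitch_fraction: float = 0.5
    mass: float = 0.5                 # kg, for metabolic rates
    path: tuple = ()                  # PathPoint sequence (origin ... insertion)
    tags: tuple = ()                  # e.g. ("triceps_surae",)

    def __post_init__(self):
        if self.f_max <= 0 or self.l_m_opt <= 0 or self.l_t_slack <= 0:
            raise ValueError(f"{self.name}: f_max, l_m_opt, l_t_slack must be > 0")
        if not 0.0 < self.stiffness_fraction <= 1.0:
            raise ValueError(f"{self.name}: stiffness_fraction must be in (0, 1]")
        if not 0.0 <= self.fast_twitch_fraction <= 1.0:
            raise ValueError(f"{self.name}: fast_twitch_fraction must be in [0, 1]")

    @property
    def k(self) -> float:
        return GENERIC_TENDON_STIFFNESS * self.stiffness_fraction

    @property
    def shift(self) -> float:
        return float(tendon_shift(self.k))


@dataclass
class MuscleState:
    """Activation and normalized tendon force of one muscle."""

    activation: float
    ft_tilde: float

    def validate(self, params: MuscleTendonParams, eps: float = 1e-9):
        if not 0.0 <= self.activation <= 1.0:
            raise ValueError("activation out of [0, 1]")
        if self.ft_tilde <= params.shift - 0.25 + eps:
            raise ValueError("ft_tilde below the tendon curve's domain")


class HillGeometryError(ValueError):
    """Raised when muscle-tendon geometry implies a non-physical fiber."""


def hill_equilibrium(a, l_mt, v_mt, ft_tilde, params: MuscleTendonParams,
                     dft_dt=0.0, validate=True):
    """Implicit fiber/tendon force balance of one muscle-tendon unit.

    Parameters
    ----------
    a : activation in [0, 1]
    l_mt, v_mt : muscle-tendon length (m) and lengthening velocity (m/s)
    ft_tilde : normalized tendon force (state)
    dft_dt : time derivative of ``ft_tilde`` (1/s); determines the tendon and
        hence fiber velocity through the tendon compliance.
    validate : check fiber-length positivity (disable inside the solver where
        complex inputs are used).

    Returns a dict with ``residual`` (zero on the admissible manifold),
    ``lm_tilde``, ``vm_tilde``, ``cos_alpha``, ``f_t`` (tendon force, N).
    """
    k, s = params.k, params.shift
    lt_tilde = tendon_norm_length(ft_tilde, k, s)
    l_t = lt_tilde * params.l_t_slack
    w = params.l_m_opt * np.sin(params.alpha_opt)  # constant-thickness width
    proj = l_mt - l_t
    l_m = np.sqrt(w * w + proj * proj)
    if validate:
        if np.any(np.real(l_m) <= 0.1 * params.l_m_opt):
            raise HillGeometryError(f"{params.name}: fiber length collapsed")
        if np.any(np.real(proj) <= 0):
            raise HillGeometryError(f"{params.name}: tendon longer than path")
    lm_tilde = l_m / params.l_m_opt
    cos_alpha = proj / l_m
    v_t = params.l_t_slack * tendon_compliance(ft_tilde, k, s) * dft_dt
    v_m = cos_alpha * (v_mt - v_t)
    vm_tilde = v_m / (params.v_max * params.l_m_opt)
    f_fiber = (a * active_fl(lm_tilde) * force_velocity(vm_tilde)
               + passive_fl(lm_tilde) + FIBER_DAMPING * vm_tilde)
    residual = ft_tilde - f_fiber * cos_alpha
    return {
        "residual": residual,
        "lm_tilde": lm_tilde,
        "vm_tilde": vm_tilde,
        "cos_alpha": cos_alpha,
        "f_t": ft_tilde * params.f_max,
    }


# ---------------------------------------------------------------------------
# Polynomial muscle-tendon geometry
# ---------------------------------------------------------------------------

class PolynomialFitError(RuntimeError):
    pass


@dataclass
class MTUGeometry:
    """Polynomial approximation of muscle-tendon length over joint angles.

    Moment arms are *defined* as minus the coordinate gradient of the fitted
    length polynomial, so the virtual-work identity r_j = -d(l_MT)/d(q_j)
    holds exactly by construction.
    """

    coordinates: tuple          # names of spanned coordinates, in order
    exponents: np.ndarray       # (n_terms, n_coords) integer powers
    coefficients: np.ndarray    # (n_terms,)
    domain: np.ndarray          # (n_coords, 2) fit range per coordinate
    max_length_residual: float  # m
    max_arm_residual: float     # m

    def _powers(self, q):
        q = np.asarray(q)
        return q[..., None, :] ** self.exponents  # (..., n_terms, n_coords)

    def length(self, q):
        """Muscle-tendon length (m); ``q`` shaped (..., n_coords)."""
        return np.prod(self._powers(q), axis=-1) @ self.coefficients

    def moment_arms(self, q):
        """Moment arms r_j = -d(length)/d(q_j), shaped (..., n_coords)."""
        q = np.asarray(q)
        pw = self._powers(q)
        n_terms, n_c = self.exponents.shape
        arms = np.empty(q.shape, dtype=q.dtype)
        for j in range(n_c):
            ej = self.exponents[:, j]
            dpj = np.where(ej > 0,
                           ej * q[..., None, j] ** np.maximum(ej - 1, 0),
                           np.zeros_like(q[..., None, j]))
            rest = np.prod(np.delete(pw, j, axis=-1), axis=-1)
            arms[..., j] = -(dpj * rest) @ self.coefficients
        return arms

    def velocity(self, q, qdot):
        """Lengthening velocity d(l_MT)/dt = -sum_j r_j qdot_j."""
        return -np.sum(self.moment_arms(q) * qdot, axis=-1)


def _monomial_exponents(n_coords: int, order: int) -> np.ndarray:
    """All exponent tuples with total degree <= order."""
    exps = [()]
    for _ in range(n_coords):
        exps = [e + (p,) for e in exps for p in range(order + 1)]
    exps = [e for e in exps if sum(e) <= order]
    exps.sort(key=lambda e: (sum(e), e))
    return np.array(exps, dtype=int)


def fit_polynomials(q_samples, lengths, moment_arms, coordinates: Sequence[str],
                    order: int = 5, cond_limit: float = 1e10) -> MTUGeometry:
    """Least-squares fit of l_MT(q) with moment arms as derivative observations.

    The length samples and the (negated) moment-arm samples enter one joint
    linear system over the shared monomial coefficients, so the returned
    geometry is self-consistent by construction.
    """
    q = np.atleast_2d(np.asarray(q_samples, dtype=float))
    lengths = np.asarray(lengths, dtype=float)
    arms = np.atleast_2d(np.asarray(moment_arms, dtype=float))
    ns, nc = q.shape
    if len(coordinates) != nc:
        raise ValueError("coordinate names do not match sample dimension")
    exps = _monomial_exponents(nc, order)
    nt = len(exps)
    if ns < 10 * nt / (nc + 1):
        raise PolynomialFitError(
            f"need >= 10x more observations than coefficients ({ns*(nc+1)} obs, {nt} coeffs)")
    pw = q[:, None, :] ** exps  # (ns, nt, nc)
    a_len = np.prod(pw, axis=-1)
    blocks = [a_len]
    rhs = [lengths]
    for j in range(nc):
        ej = exps[:, j]
        dpj = np.where(ej > 0, ej * q[:, None, j] ** np.maximum(ej - 1, 0), 0.0)
        rest = np.prod(np.delete(pw, j, axis=-1), axis=-1)
        blocks.append(dpj * rest)
        rhs.append(-arms[:, j])  # r_j = -dL/dq_j
    design = np.vstack(blocks)
    target = np.concatenate(rhs)
    coeffs, _, rank, sv = np.linalg.lstsq(design, target, rcond=None)
    if rank < nt or sv[0] / sv[-1] > cond_limit:
        raise PolynomialFitError(
            f"ill-conditioned fit (rank {rank}/{nt}, cond {sv[0]/sv[-1]:.2e}); "
            "reduce the polynomial order or widen the sample grid")
    geom = MTUGeometry(
        coordinates=tuple(coordinates),
        exponents=exps,
        coefficients=coeffs,
        domain=np.stack([q.min(axis=0), q.max(axis=0)], axis=1),
        max_length_residual=0.0,
        max_arm_residual=0.0,
    )
    geom.max_length_residual = float(np.max(np.abs(geom.length(q) - lengths)))
    geom.max_arm_residual = float(np.max(np.abs(geom.moment_arms(q) - arms)))
    return geom
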
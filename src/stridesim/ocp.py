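"""Direct-collocation transcription of the predictive gait problem.

Formulation
-----------
A half gait cycle of duration ``t_f`` (free) is discretized into ``N`` mesh
intervals with ``degree``-point right-Radau collocation.  States are
``x = [q, qdot, a, ft_tilde]``.  Muscle excitations ``e`` are piecewise
constant per mesh interval; coordinate accelerations ``u_a`` and scaled
tendon-force derivatives ``dft`` -- the algebraic controls of the implicit
dynamics formulation -- live at every collocation point so the pointwise
skeleton-dynamics and equilibrium equalities remain satisfiable on coarse
meshes.  Skeleton dynamics, fiber/tendon equilibrium and activation
dynamics are equality path constraints at every collocation point.

Periodicity with left-right symmetry is built into the transcription: the
half-cycle start state is *defined* as the mirror image of the final
collocation state (with the pelvis forward translation reset to zero), so
the periodicity map is satisfied exactly.  A single equality constrains the
distance traveled to ``speed * t_f``.

The cost is the distance-normalized integral of squared metabolic rate,
activations, coordinate accelerations, passive torques and arm-motor
excitations, plus a small penalty on the remaining controls to avoid
singular arcs.  All terms are kept in sum-of-squares (residual) form so the
solver can exploit the Gauss-Newton structure.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import metabolics as _met
from .collocation import RadauScheme
from .dynamics import CompiledModel, fit_model_geometry
from .model import ModelSpec
from .muscle import (FIBER_DAMPING, activation_dynamics, active_fl,
                     force_velocity, passive_fl, tendon_shift)

__all__ = ["Weights", "OCPConfig", "GaitProblem", "GaitSolution",
           "cost_integrand"]


@dataclass
class Weights:
    """Cost-function weights (dimensionless)."""

    metabolic: float = 2.0e-4      # w1, on squared per-muscle metabolic rate (W)
    activation: float = 1.0        # w2
    acceleration: float = 2.0e-3   # w3, on squared coordinate accelerations
    passive: float = 1.0e-3       # w4, on squared passive torques
    arm_excitation: float = 1.0    # w5, torque-motor excitations
    singular: float = 1.0e-2       # penalty on the remaining (tendon-rate) controls


@dataclass
class OCPConfig:
    """Configuration of one predictive gait problem."""

    speed: float = 1.33            # m/s
    n_mesh: int = 25               # mesh intervals per half gait cycle
    degree: int = 3                # Radau collocation points per interval
    weights: Weights = field(default_factory=Weights)
    tol: float = 1.0e-4            # NLP feasibility tolerance (scaled constraints)
    t_f_bounds: tuple = (0.35, 0.8)
    t_f_init: float = 0.45         # s, cold-start half-cycle duration
    dft_scale: float = 100.0       # 1/s, scaling of tendon-force-derivative controls
    guess: str = "both"            # 'cold' | 'hot' | 'both'
    seed: int = 0
    poly_order: int = 5
    basal_rate: float = _met.BASAL_RATE_W_PER_KG  # W/kg body, reporting only
    solver: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_mesh < 2:
            raise ValueError("n_mesh must be >= 2")
        if self.tol <= 0:
            raise ValueError("tolerance must be > 0")
        for w in dataclasses.astuple(self.weights) if isinstance(self.weights, Weights) else []:
            if w < 0:
                raise ValueError("weights must be >= 0")

    def to_dict(self):
        d = dataclasses.asdict(self)
        return d


def cost_integrand(a, u_a, t_p, edot, e_arm=(), extra_controls=(),
                   weights: Weights | None = None):
    """Pointwise cost integrand (before division by distance traveled)."""
    w = weights or Weights()
    val = (w.metabolic * np.sum(np.square(edot), axis=-1)
           + w.activation * np.sum(np.square(a), axis=-1)
           + w.acceleration * np.sum(np.square(u_a), axis=-1)
           + w.passive * np.sum(np.square(t_p), axis=-1))
    if len(np.shape(e_arm)) and np.size(e_arm):
        val = val + w.arm_excitation * np.sum(np.square(e_arm), axis=-1)
    if len(np.shape(extra_controls)) and np.size(extra_controls):
        val = val + w.singular * np.sum(np.square(extra_controls), axis=-1)
    return val


class _Poly1:
    """Fast Horner evaluation of a single-coordinate muscle path polynomial."""

    def __init__(self, geom):
        order = int(geom.exponents.max())
        c = np.zeros(order + 1)
        for e, coef in zip(geom.exponents[:, 0], geom.coefficients):
            c[e] += coef
        self.c = c[::-1]                      # highest power first
        self.dc = np.polyder(self.c)

    def length(self, q):
        acc = self.c[0] * np.ones_like(q)
        for ck in self.c[1:]:
            acc = acc * q + ck
        return acc

    def arms(self, q):
        acc = self.dc[0] * np.ones_like(q)
        for ck in self.dc[1:]:
            acc = acc * q + ck
        return [-acc]


class _Poly2:
    """Fast evaluation of a two-coordinate muscle path polynomial."""

    def __init__(self, geom):
        order = int(geom.exponents.max())
        m = np.zeros((order + 1, order + 1))
        for (e1, e2), coef in zip(geom.exponents, geom.coefficients):
            m[e1, e2] += coef
        self.m = m
        self.d1 = m[1:, :] * np.arange(1, order + 1)[:, None]
        self.d2 = m[:, 1:] * np.arange(1, order + 1)[None, :]

    @staticmethod
    def _horner2(mat, q1, q2):
        acc = None
        for row in mat[::-1]:
            inner = row[-1] * np.ones_like(q2)
            for ck in row[-2::-1]:
                inner = inner * q2 + ck
            acc = inner if acc is None else acc * q1 + inner
        return acc

    def length(self, q1, q2):
        return self._horner2(self.m, q1, q2)

    def arms(self, q1, q2):
        return [-self._horner2(self.d1, q1, q2),
                -self._horner2(self.d2, q1, q2)]


class GaitProblem:
    """Transcribed gait optimal-control problem over a compiled model."""

    def __init__(self, model: ModelSpec | CompiledModel, config: OCPConfig,
                 geometry: dict | None = None):
        self.config = config
        if isinstance(model, CompiledModel):
            self.cm = model
        else:
            self.cm = CompiledModel(model)
        if geometry is not None:
            self.cm.geometry = geometry
        if not self.cm.geometry:
            self.cm.geometry = fit_model_geometry(self.cm, order=config.poly_order)
        cm = self.cm
        self.scheme = RadauScheme(config.degree)
        self.nq, self.nm = cm.nq, cm.nm
        self.nx = 2 * self.nq + 2 * self.nm
        self.nu_e = self.nm                 # per-interval excitations
        self.nu_p = self.nm + self.nq       # per-point [dft, u_a]
        self.nu = self.nu_e + self.nu_p
        self.ns = len(cm.spec.contact_spheres)
        self.nf = 2 * self.ns               # lifted per-point contact forces
        self.N = config.n_mesh
        self.d = config.degree
        self.itx, self.ity, self.itilt = cm.base_coords
        self._build_muscle_arrays()
        self._build_permutations()
        self._build_bounds_scaling()
        self._build_sparsity()

    # ------------------------------------------------------------------
    # setup
    # ------------------------------------------------------------------
    def _build_muscle_arrays(self):
        cm = self.cm
        ms = cm.muscles
        self.f_max = np.array([m.f_max for m in ms])
        self.l_m_opt = np.array([m.l_m_opt for m in ms])
        self.l_t_slack = np.array([m.l_t_slack for m in ms])
        self.alpha_opt = np.array([m.alpha_opt for m in ms])
        self.v_max = np.array([m.v_max for m in ms])
        self.k_t = np.array([m.k for m in ms])
        self.s_t = tendon_shift(self.k_t)
        self.w_pen = self.l_m_opt * np.sin(self.alpha_opt)

        class _ArrayParams:
            pass

        ap = _ArrayParams()
        ap.mass = np.array([m.mass for m in ms])
        ap.fast_twitch_fraction = np.array([m.fast_twitch_fraction for m in ms])
        ap.v_max = self.v_max
        ap.l_m_opt = self.l_m_opt
        ap.f_max = self.f_max
        self._met_params = ap

        self._span = []
        self._poly = []
        for m in ms:
            g = cm.geometry[m.name]
            ci = [cm.coordinates.index(c) for c in g.coordinates]
            self._span.append(np.array(ci, dtype=int))
            if len(ci) == 1:
                self._poly.append(_Poly1(g))
            elif len(ci) == 2:
                self._poly.append(_Poly2(g))
            else:
                self._poly.append(g)

    def _build_permutations(self):
        cm = self.cm
        pq = cm.mirror_coordinate_permutation()
        pm = cm.mirror_muscle_permutation()
        nq, nm = self.nq, self.nm
        self.perm_state = np.concatenate([
            pq, nq + pq, 2 * nq + pm, 2 * nq + nm + pm])
        self.perm_control = np.concatenate([
            pm, nm + pm, 2 * nm + pq])

    def _build_bounds_scaling(self):
        cm = self.cm
        cfg = self.config
        nq, nm = self.nq, self.nm
        ranges = cm.coordinate_ranges()
        q_lo = np.array([ranges[c][0] for c in cm.coordinates])
        q_hi = np.array([ranges[c][1] for c in cm.coordinates])
        q_lo[self.itx], q_hi[self.itx] = -0.2, 1.5
        q_lo[self.ity], q_hi[self.ity] = 0.70, 1.05
        qd_lo, qd_hi = np.full(nq, -15.0), np.full(nq, 15.0)
        qd_lo[self.itx], qd_hi[self.itx] = -0.5, 3.0
        qd_lo[self.ity], qd_hi[self.ity] = -1.5, 1.5
        a_lo, a_hi = np.full(nm, 1e-3), np.full(nm, 1.0)
        ft_lo = self.s_t - 0.25 + 5e-3
        ft_hi = np.full(nm, 1.8)
        self.x_lo = np.concatenate([q_lo, qd_lo, a_lo, ft_lo])
        self.x_hi = np.concatenate([q_hi, qd_hi, a_hi, ft_hi])
        e_lo, e_hi = np.zeros(nm), np.ones(nm)
        dft_lo, dft_hi = np.full(nm, -1.0), np.full(nm, 1.0)
        ua_lo, ua_hi = np.full(nq, -250.0), np.full(nq, 250.0)
        ua_lo[self.itx], ua_hi[self.itx] = -60.0, 60.0
        ua_lo[self.ity], ua_hi[self.ity] = -60.0, 60.0
        self.ue_lo, self.ue_hi = e_lo, e_hi
        self.up_lo = np.concatenate([dft_lo, ua_lo])
        self.up_hi = np.concatenate([dft_hi, ua_hi])
        # lifted contact forces: [ftx, fn] per sphere
        self.fc_lo = np.tile([-2000.0, -50.0], self.ns)
        self.fc_hi = np.tile([2000.0, 3000.0], self.ns)

        self.x_scale = np.maximum(0.5 * (self.x_hi - self.x_lo), 1e-3)
        self.x_off = 0.5 * (self.x_hi + self.x_lo)
        self.ue_scale = np.maximum(0.5 * (self.ue_hi - self.ue_lo), 1e-3)
        self.ue_off = 0.5 * (self.ue_hi + self.ue_lo)
        self.up_scale = np.maximum(0.5 * (self.up_hi - self.up_lo), 1e-3)
        self.up_off = 0.5 * (self.up_hi + self.up_lo)
        self.fc_scale = np.full(self.nf, 300.0)
        self.fc_off = np.zeros(self.nf)
        self.tf_lo, self.tf_hi = cfg.t_f_bounds
        self.tf_scale = 0.5 * (self.tf_hi - self.tf_lo)
        self.tf_off = 0.5 * (self.tf_hi + self.tf_lo)

        # constraint row scales
        defect_scale = np.tile(self.x_scale, 1)
        self.defect_rowscale = 1.0 / defect_scale
        self.hill_rowscale = np.full(nm, 1.0 / 0.1)
        dyn_scale = np.full(nq, 100.0)
        dyn_scale[[self.itx, self.ity]] = 600.0
        self.dyn_rowscale = 1.0 / dyn_scale
        self.speed_rowscale = 1.0 / 0.05

        N, d, nx = self.N, self.d, self.nx
        self.n_var = (1 + N * d * nx + N * self.nu_e + N * d * self.nu_p
                      + N * d * self.nf)
        self.n_con = N * d * (nx + nm + nq + self.nf) + 1
        self.n_obj = N * d * (3 * nm + 2 * nq)
        self.contact_rowscale = 1.0 / 300.0

        lo = np.concatenate([[self.tf_lo], np.tile(self.x_lo, N * d),
                             np.tile(self.ue_lo, N), np.tile(self.up_lo, N * d),
                             np.tile(self.fc_lo, N * d)])
        hi = np.concatenate([[self.tf_hi], np.tile(self.x_hi, N * d),
                             np.tile(self.ue_hi, N), np.tile(self.up_hi, N * d),
                             np.tile(self.fc_hi, N * d)])
        self.z_lo_phys, self.z_hi_phys = lo, hi
        self.z_scale = np.concatenate([[self.tf_scale],
                                       np.tile(self.x_scale, N * d),
                                       np.tile(self.ue_scale, N),
                                       np.tile(self.up_scale, N * d),
                                       np.tile(self.fc_scale, N * d)])
        self.z_off = np.concatenate([[self.tf_off],
                                     np.tile(self.x_off, N * d),
                                     np.tile(self.ue_off, N),
                                     np.tile(self.up_off, N * d),
                                     np.tile(self.fc_off, N * d)])
        self.z_lo = (lo - self.z_off) / self.z_scale
        self.z_hi = (hi - self.z_off) / self.z_scale

    # index helpers -----------------------------------------------------
    def iv_x(self, i, r, s):
        """Variable index of state component s at collocation point (i, r)."""
        return 1 + (i * self.d + r) * self.nx + s

    def iv_ue(self, i, m):
        """Variable index of the interval-constant excitation of muscle m."""
        return 1 + self.N * self.d * self.nx + i * self.nu_e + m

    def iv_up(self, i, r, j):
        """Variable index of per-point control j (dft then u_a) at (i, r)."""
        return (1 + self.N * self.d * self.nx + self.N * self.nu_e
                + (i * self.d + r) * self.nu_p + j)

    def iv_f(self, i, r, j):
        """Variable index of lifted contact-force component j at (i, r)."""
        return (1 + self.N * self.d * self.nx + self.N * self.nu_e
                + self.N * self.d * self.nu_p + (i * self.d + r) * self.nf + j)

    def census(self):
        """Closed-form variable/constraint counts of the transcription.

        n_var = 1 + N d nx + N nm + N d (nm + nq) + N d nf; the leading 1 is
        the free half-cycle duration and nf = 2 * n_spheres are the lifted
        contact forces.  n_con = N d (nx + nm + nq + nf) + 1 (collocation
        defects, fiber/tendon equilibria, skeleton dynamics, contact-force
        definitions, speed).
        """
        N, d, nx, nm, nq = self.N, self.d, self.nx, self.nm, self.nq
        return {
            "n_var": 1 + N * d * nx + N * nm + N * d * (nm + nq) + N * d * self.nf,
            "n_con": N * d * (nx + nm + nq + self.nf) + 1,
            "states": nx, "controls": self.nu,
            "contact_forces": self.nf,
            "collocation_points": N * d,
        }

    # ------------------------------------------------------------------
    # evaluation
    # ------------------------------------------------------------------
    def unpack(self, z):
        """Split a physical-units decision vector into (t_f, Xc, Ue, Up, Fc)."""
        N, d, nx = self.N, self.d, self.nx
        t_f = z[..., 0]
        o = 1 + N * d * nx
        xc = z[..., 1:o].reshape(z.shape[:-1] + (N, d, nx))
        ue = z[..., o:o + N * self.nu_e].reshape(z.shape[:-1] + (N, self.nu_e))
        o += N * self.nu_e
        up = z[..., o:o + N * d * self.nu_p].reshape(z.shape[:-1] + (N, d, self.nu_p))
        o += N * d * self.nu_p
        fc = z[..., o:].reshape(z.shape[:-1] + (N, d, self.nf))
        return t_f, xc, ue, up, fc

    def to_phys(self, z_scaled):
        return z_scaled * self.z_scale + self.z_off

    def to_scaled(self, z_phys):
        return (z_phys - self.z_off) / self.z_scale

    def start_state(self, xc):
        """Half-cycle start state: mirrored final collocation state, tx = 0."""
        x_end = xc[..., -1, -1, :]
        x0 = x_end[..., self.perm_state].copy()
        x0[..., self.itx] = 0.0
        return x0

    def _physics(self, q, qd, a, ft, e, dft_phys, ua, fc=None):
        """All point quantities; inputs shaped (..., n).

        When ``fc`` (lifted contact forces) is given, the skeleton dynamics
        use it and the returned ``contact`` entry holds the defining residual
        ``contact_model(q, qd) - fc``; otherwise the contact model is applied
        directly.
        """
        nq, nm = self.nq, self.nm
        # muscle-tendon geometry
        lmt_l, vmt_l, arms_l = [], [], []
        for mi in range(nm):
            ci = self._span[mi]
            p = self._poly[mi]
            if isinstance(p, _Poly1):
                qj = q[..., ci[0]]
                lmt_l.append(p.length(qj))
                arms = p.arms(qj)
            elif isinstance(p, _Poly2):
                q1, q2 = q[..., ci[0]], q[..., ci[1]]
                lmt_l.append(p.length(q1, q2))
                arms = p.arms(q1, q2)
            else:
                qj = q[..., ci]
                lmt_l.append(p.length(qj))
                am = p.moment_arms(qj)
                arms = [am[..., k] for k in range(len(ci))]
            arms_l.append(arms)
            vmt_l.append(-sum(arms[k] * qd[..., ci[k]] for k in range(len(ci))))
        lmt = np.stack(lmt_l, axis=-1)
        vmt = np.stack(vmt_l, axis=-1)

        # tendon and fiber
        kt, st = self.k_t, self.s_t
        lt_tilde = np.log(5.0 * (ft + 0.25 - st)) / kt + 0.995
        l_t = lt_tilde * self.l_t_slack
        proj = lmt - l_t
        l_m = np.sqrt(self.w_pen ** 2 + proj * proj)
        lm_tilde = l_m / self.l_m_opt
        cos_a = proj / l_m
        v_t = self.l_t_slack * dft_phys / (kt * (ft + 0.25 - st))
        v_m = cos_a * (vmt - v_t)
        vm_tilde = v_m / (self.v_max * self.l_m_opt)
        fl = active_fl(lm_tilde)
        fv = force_velocity(vm_tilde)
        fp = passive_fl(lm_tilde)
        f_fiber = a * fl * fv + fp + FIBER_DAMPING * vm_tilde
        hill = ft - f_fiber * cos_a

        # joint torques
        f_t = ft * self.f_max
        dtype = np.result_type(q, qd, a, ft, e, ua)
        tau_mus = np.zeros(q.shape[:-1] + (nq,), dtype=dtype)
        for mi in range(nm):
            ci = self._span[mi]
            for k, c in enumerate(ci):
                tau_mus[..., c] += arms_l[mi][k] * f_t[..., mi]
        t_p = self.cm.passive_torque_vector(q, qd)
        if fc is None:
            q_contact, _ = self.cm.contact_generalized_forces(q, qd)
            contact_res = None
        else:
            contact_res = self.cm.contact_force_values(q, qd) - fc
            q_contact = self.cm.contact_apply(q, fc)
        dyn = self.cm.inverse_dynamics(q, qd, ua) - tau_mus - t_p - q_contact

        # metabolic rate
        f_act = a * fl * fv * self.f_max
        f_tot = (a * fl * fv + fp) * self.f_max
        rates = _met.bhargava_rate(e, a, lm_tilde, vm_tilde, f_act, f_tot,
                                   self._met_params)
        adot = activation_dynamics(e, a)
        return {"hill": hill, "dyn": dyn, "t_p": t_p, "edot": rates.total,
                "adot": adot, "lmt": lmt, "vmt": vmt, "lm_tilde": lm_tilde,
                "vm_tilde": vm_tilde, "f_t": f_t, "contact": contact_res}

    def residuals(self, z_scaled):
        """(objective_residuals, constraints) at a scaled decision vector.

        Accepts batched input (..., n_var); preserves complex dtype.
        """
        z = self.to_phys(np.asarray(z_scaled))
        t_f, xc, uev, upv, fcv = self.unpack(z)
        N, d, nx, nq, nm = self.N, self.d, self.nx, self.nq, self.nm
        batch = z.shape[:-1]
        h = t_f / N
        v = self.config.speed
        dist = v * t_f

        x0 = self.start_state(xc)
        # stage tensor: (batch, N, d+1, nx)
        starts = np.concatenate([x0[..., None, :], xc[..., :-1, -1, :]], axis=-2)
        pts = xc.reshape(batch + (N * d, nx))
        q = pts[..., :nq]
        qd = pts[..., nq:2 * nq]
        a = pts[..., 2 * nq:2 * nq + nm]
        ft = pts[..., 2 * nq + nm:]
        e = np.repeat(uev, d, axis=-2)
        upts = upv.reshape(batch + (N * d, self.nu_p))
        dft_scaled = upts[..., :nm]
        dft = dft_scaled * self.config.dft_scale
        ua = upts[..., nm:]
        fcp = fcv.reshape(batch + (N * d, self.nf))

        phys = self._physics(q, qd, a, ft, e, dft, ua, fcp)
        f = np.concatenate([qd, ua, phys["adot"], dft], axis=-1)

        C = self.scheme.C
        stages = np.concatenate([starts[..., :, None, :], xc], axis=-2)  # (b,N,d+1,nx)
        dpoly = np.einsum("jr,...njs->...nrs", C, stages)
        defects = dpoly - (f.reshape(batch + (N, d, nx))
                           * h[..., None, None, None])
        defects = defects * self.defect_rowscale

        hill = phys["hill"].reshape(batch + (N, d, nm)) * self.hill_rowscale
        dyn = phys["dyn"].reshape(batch + (N, d, nq)) * self.dyn_rowscale
        cres = phys["contact"] * self.contact_rowscale
        speed_row = (xc[..., -1, -1, self.itx] - dist) * self.speed_rowscale
        con = np.concatenate([
            defects.reshape(batch + (N * d * nx,)),
            hill.reshape(batch + (N * d * nm,)),
            dyn.reshape(batch + (N * d * nq,)),
            cres.reshape(batch + (N * d * self.nf,)),
            speed_row[..., None]], axis=-1)

        w = self.config.weights
        B = np.tile(self.scheme.B, N)  # quadrature weight per point
        quad = np.sqrt(B) * np.sqrt(h / dist)[..., None]
        blocks = [
            np.sqrt(w.metabolic) * quad[..., None] * phys["edot"].reshape(batch + (N * d, nm)),
            np.sqrt(w.activation) * quad[..., None] * a.reshape(batch + (N * d, nm)),
            np.sqrt(w.acceleration) * quad[..., None] * ua.reshape(batch + (N * d, nq)),
            np.sqrt(w.passive) * quad[..., None] * phys["t_p"].reshape(batch + (N * d, nq)),
            np.sqrt(w.singular) * quad[..., None] * dft_scaled.reshape(batch + (N * d, nm)),
        ]
        obj = np.concatenate([b.reshape(batch + (-1,)) for b in blocks], axis=-1)
        return obj, con

    def objective(self, z_scaled):
        obj, _ = self.residuals(z_scaled)
        return float(np.sum(np.real(obj) ** 2))

    def objective_terms(self, z_scaled):
        """Per-term objective breakdown (same normalization as Eq-style cost)."""
        obj, _ = self.residuals(np.asarray(z_scaled, dtype=float))
        N, d, nm, nq = self.N, self.d, self.nm, self.nq
        P = N * d
        parts = np.split(obj, np.cumsum([P * nm, P * nm, P * nq, P * nq])[:4])
        names = ["metabolic", "activation", "acceleration", "passive", "singular"]
        return {n: float(np.sum(p ** 2)) for n, p in zip(names, parts)}

    def constraint_violation(self, z_scaled):
        _, con = self.residuals(np.asarray(z_scaled, dtype=float))
        return float(np.max(np.abs(con)))

    # ------------------------------------------------------------------
    # sparsity and colored complex-step Jacobian
    # ------------------------------------------------------------------
    def _build_sparsity(self):
        N, d, nx, nq, nm, nu = self.N, self.d, self.nx, self.nq, self.nm, self.nu
        itx = self.itx
        cm = self.cm
        self._sphere_coords = [
            np.nonzero(cm.affected[cm.body_index[s.segment]])[0]
            for s in cm.spec.contact_spheres]
        rows = []
        cols = []

        def add(r, c):
            rows.append(r)
            cols.append(c)

        def stage_col(i, j, s):
            """Variable column of stage j (0=start) state component s, or None."""
            if j == 0:
                if i == 0:
                    if s == itx:
                        return None
                    return self.iv_x(N - 1, d - 1, self.perm_state[s])
                return self.iv_x(i - 1, d - 1, s)
            return self.iv_x(i, j - 1, s)

        # constraint rows
        ncon_def = N * d * nx
        ncon_hill = N * d * nm
        row0_hill = ncon_def
        row0_dyn = ncon_def + ncon_hill
        row0_contact = row0_dyn + N * d * nq
        row_speed = self.n_con - 1
        for i in range(N):
            for r in range(d):
                base = (i * d + r) * nx
                for s in range(nx):
                    row = base + s
                    add(row, 0)  # t_f
                    seen = set()
                    for j in range(d + 1):
                        c = stage_col(i, j, s)
                        if c is not None and c not in seen:
                            add(row, c)
                            seen.add(c)
                    # dependencies of f at point (i, r)
                    if s < nq:  # q defect: qdot state
                        add(row, self.iv_x(i, r, nq + s))
                    elif s < 2 * nq:  # qdot defect: u_a control
                        add(row, self.iv_up(i, r, nm + (s - nq)))
                    elif s < 2 * nq + nm:  # activation defect: e control
                        add(row, self.iv_ue(i, s - 2 * nq))
                    else:  # tendon-force defect: dft control
                        add(row, self.iv_up(i, r, s - 2 * nq - nm))
                # hill rows
                for m in range(nm):
                    row = row0_hill + (i * d + r) * nm + m
                    for c in self._span[m]:
                        add(row, self.iv_x(i, r, c))
                        add(row, self.iv_x(i, r, nq + c))
                    add(row, self.iv_x(i, r, 2 * nq + m))
                    add(row, self.iv_x(i, r, 2 * nq + nm + m))
                    add(row, self.iv_up(i, r, m))
                # dynamics rows
                for cq in range(nq):
                    row = row0_dyn + (i * d + r) * nq + cq
                    for s in range(2 * nq):
                        add(row, self.iv_x(i, r, s))
                    for m in range(nm):
                        if cq in self._span[m]:
                            add(row, self.iv_x(i, r, 2 * nq + nm + m))
                    for c2 in range(nq):
                        add(row, self.iv_up(i, r, nm + c2))
                    for si, scoords in enumerate(self._sphere_coords):
                        if cq in scoords:
                            add(row, self.iv_f(i, r, 2 * si))
                            add(row, self.iv_f(i, r, 2 * si + 1))
                # contact-force defining rows
                for si, scoords in enumerate(self._sphere_coords):
                    for comp in range(2):
                        row = row0_contact + (i * d + r) * self.nf + 2 * si + comp
                        for c in scoords:
                            add(row, self.iv_x(i, r, c))
                            add(row, self.iv_x(i, r, nq + c))
                        add(row, self.iv_f(i, r, 2 * si + comp))
        add(row_speed, self.iv_x(N - 1, d - 1, itx))
        add(row_speed, 0)

        # objective rows (appended after constraints in the stacked Jacobian)
        P = N * d
        ob0 = self.n_con
        for i in range(N):
            for r in range(d):
                p = i * d + r
                for m in range(nm):  # metabolic
                    row = ob0 + p * nm + m
                    add(row, 0)
                    for c in self._span[m]:
                        add(row, self.iv_x(i, r, c))
                        add(row, self.iv_x(i, r, nq + c))
                    add(row, self.iv_x(i, r, 2 * nq + m))
                    add(row, self.iv_x(i, r, 2 * nq + nm + m))
                    add(row, self.iv_ue(i, m))
                    add(row, self.iv_up(i, r, m))
                for m in range(nm):  # activation
                    row = ob0 + P * nm + p * nm + m
                    add(row, 0)
                    add(row, self.iv_x(i, r, 2 * nq + m))
                for cq in range(nq):  # acceleration
                    row = ob0 + 2 * P * nm + p * nq + cq
                    add(row, 0)
                    add(row, self.iv_up(i, r, nm + cq))
                for cq in range(nq):  # passive torque
                    row = ob0 + 2 * P * nm + P * nq + p * nq + cq
                    add(row, 0)
                    add(row, self.iv_x(i, r, cq))
                    add(row, self.iv_x(i, r, nq + cq))
                for m in range(nm):  # singular-arc penalty
                    row = ob0 + 2 * P * (nm + nq) + p * nm + m
                    add(row, 0)
                    add(row, self.iv_up(i, r, m))

        from scipy.sparse import coo_matrix, csc_matrix

        n_rows = self.n_con + self.n_obj
        pat = coo_matrix((np.ones(len(rows)), (rows, cols)),
                         shape=(n_rows, self.n_var)).tocsc()
        pat.data[:] = 1.0
        pat.sum_duplicates()
        self._pattern = pat

        # greedy column coloring (no two same-colored columns share a row)
        indptr, indices = pat.indptr, pat.indices
        colors = np.full(self.n_var, -1, dtype=int)
        row_colors = [set() for _ in range(n_rows)]
        order = np.argsort(-np.diff(indptr))  # high-degree columns first
        for j in order:
            rj = indices[indptr[j]:indptr[j + 1]]
            forbidden = set()
            for r in rj:
                forbidden |= row_colors[r]
            c = 0
            while c in forbidden:
                c += 1
            colors[j] = c
            for r in rj:
                row_colors[r].add(c)
        self.colors = colors
        self.n_colors = int(colors.max()) + 1
        # per-nnz gather indices in csc order
        col_of_nnz = np.repeat(np.arange(self.n_var), np.diff(indptr))
        self._nnz_rows = indices.copy()
        self._nnz_colorcols = colors[col_of_nnz]

    def jacobian(self, z_scaled, h_step=1e-100):
        """Sparse Jacobian of stacked [constraints; objective residuals].

        Colored complex-step: all color groups are evaluated in one batched
        call, then scattered into the fixed sparsity pattern.
        """
        from scipy.sparse import csc_matrix

        z = np.asarray(z_scaled, dtype=float)
        zb = z[None, :] + 1j * h_step * (self.colors[None, :]
                                         == np.arange(self.n_colors)[:, None])
        obj, con = self.residuals(zb)
        G = np.concatenate([con, obj], axis=-1)  # (n_colors, n_rows)
        vals = G.imag[self._nnz_colorcols, self._nnz_rows] / h_step
        pat = self._pattern
        return csc_matrix((vals, pat.indices, pat.indptr),
                          shape=pat.shape)

    # ------------------------------------------------------------------
    # decode / post-processing
    # ------------------------------------------------------------------
    def point_times(self, t_f):
        """Times of all collocation points over the half cycle."""
        h = t_f / self.N
        return (np.arange(self.N)[:, None] * h
                + self.scheme.tau[None, :] * h).ravel()

    def sample_states(self, z_scaled, times):
        """States at arbitrary half-cycle times by per-interval Lagrange interp."""
        z = self.to_phys(np.asarray(z_scaled, dtype=float))
        t_f, xc, _, _, _ = self.unpack(z)
        x0 = self.start_state(xc)
        starts = np.concatenate([x0[None, :], xc[:-1, -1, :]], axis=0)
        h = t_f / self.N
        nodes = np.concatenate([[0.0], self.scheme.tau])
        out = np.empty((len(times), self.nx))
        for ti, t in enumerate(np.asarray(times)):
            i = min(int(t / h), self.N - 1)
            tau = (t - i * h) / h
            stages = np.concatenate([starts[i][None, :], xc[i]], axis=0)
            val = np.zeros(self.nx)
            for j in range(self.d + 1):
                lj = 1.0
                for k2 in range(self.d + 1):
                    if k2 != j:
                        lj *= (tau - nodes[k2]) / (nodes[j] - nodes[k2])
                val += lj * stages[j]
            out[ti] = val
        return out

    def controls_at(self, z_scaled, times):
        """Controls at given times: excitations from the containing interval,
        per-point controls from the nearest collocation point."""
        z = self.to_phys(np.asarray(z_scaled, dtype=float))
        t_f, _, ue, up, _ = self.unpack(z)
        h = t_f / self.N
        times = np.asarray(times)
        idx = np.minimum((times / h).astype(int), self.N - 1)
        tau = times / h - idx
        ridx = np.argmin(np.abs(tau[:, None] - self.scheme.tau[None, :]), axis=1)
        return np.concatenate([ue[idx], up[idx, ridx]], axis=-1)


@dataclass
class GaitSolution:
    """A solved (or attempted) predictive gait simulation."""

    problem: GaitProblem
    z: np.ndarray                  # scaled decision vector
    status: str
    iterations: int
    feasibility: float             # max scaled constraint violation
    objective: float
    objective_terms: dict
    guess_label: str
    config: dict
    alternatives: list = field(default_factory=list)  # other guesses' solutions

    @property
    def t_f(self) -> float:
        return float(self.problem.to_phys(self.z)[0])

    @property
    def distance(self) -> float:
        """Forward pelvis travel over the half cycle (m)."""
        return self.problem.config.speed * self.t_f

    @property
    def stride_length(self) -> float:
        return self.problem.config.speed * 2.0 * self.t_f

    @property
    def success(self) -> bool:
        return self.status == "converged"

    def half_cycle(self, n: int = 51):
        """States/controls sampled on a uniform half-cycle grid."""
        prob = self.problem
        times = np.linspace(0.0, self.t_f, n)
        times[-1] = self.t_f * (1 - 1e-12)
        x = prob.sample_states(self.z, times)
        u = prob.controls_at(self.z, times)
        nq, nm = prob.nq, prob.nm
        return {
            "time": np.linspace(0.0, self.t_f, n),
            "q": x[:, :nq], "qd": x[:, nq:2 * nq],
            "a": x[:, 2 * nq:2 * nq + nm], "ft": x[:, 2 * nq + nm:],
            "e": u[:, :nm], "dft": u[:, nm:2 * nm], "ua": u[:, 2 * nm:],
        }

    def full_cycle(self, n: int = 101):
        """Reconstructed full gait cycle via the left-right symmetry map.

        Returns states/controls on a uniform time grid over [0, 2 t_f];
        samples in the second half are the mirrored first-half samples with
        the pelvis advanced by the half-cycle travel distance.
        """
        prob = self.problem
        t_f = self.t_f
        times = np.linspace(0.0, 2.0 * t_f, n)
        second = times > t_f
        tt = np.where(second, times - t_f, times)
        tt = np.clip(tt, 0.0, t_f * (1.0 - 1e-12))
        x = prob.sample_states(self.z, tt)
        u = prob.controls_at(self.z, tt)
        nq, nm = prob.nq, prob.nm
        raw = {"q": x[:, :nq], "qd": x[:, nq:2 * nq],
               "a": x[:, 2 * nq:2 * nq + nm], "ft": x[:, 2 * nq + nm:],
               "e": u[:, :nm], "dft": u[:, nm:2 * nm], "ua": u[:, 2 * nm:]}
        pq = prob.cm.mirror_coordinate_permutation()
        pm = prob.cm.mirror_muscle_permutation()
        out = {"time": times}
        for key, perm in (("q", pq), ("qd", pq), ("a", pm), ("ft", pm),
                          ("e", pm), ("dft", pm), ("ua", pq)):
            arr = raw[key].copy()
            mirrored = raw[key][:, perm]
            if key == "q":
                mirrored = mirrored.copy()
                mirrored[:, prob.itx] += self.distance
            arr[second] = mirrored[second]
            out[key] = arr
        return out

    def grf_series(self, n: int = 101):
        """Per-foot ground reaction forces over the reconstructed full cycle."""
        from .contact import model_grf

        cyc = self.full_cycle(n)
        grf_r = np.empty((n, 2))
        grf_l = np.empty((n, 2))
        cop_r = np.empty(n)
        cop_l = np.empty(n)
        for i in range(n):
            g = model_grf(cyc["q"][i], cyc["qd"][i], self.problem.cm)
            grf_r[i] = g["r"]["force"]
            grf_l[i] = g["l"]["force"]
            cop_r[i] = g["r"]["cop"]
            cop_l[i] = g["l"]["cop"]
        return {"time": cyc["time"], "r": grf_r, "l": grf_l,
                "cop_r": cop_r, "cop_l": cop_l}

    def stance_fraction(self, threshold: float = 20.0, n: int = 201):
        g = self.grf_series(n)
        return float(np.mean(g["r"][:, 1] > threshold))

    def metabolic_report(self, basal: bool = True):
        """Per-muscle metabolic energy (J) and COT over the full gait cycle.

        Uses the collocation quadrature of the half cycle, doubled, plus the
        whole-body basal rate.
        """
        prob = self.problem
        z = prob.to_phys(self.z)
        t_f, xc, ue, up, _ = prob.unpack(z)
        N, d, nq, nm = prob.N, prob.d, prob.nq, prob.nm
        pts = xc.reshape(N * d, prob.nx)
        upts = up.reshape(N * d, prob.nu_p)
        phys = prob._physics(pts[:, :nq], pts[:, nq:2 * nq],
                             pts[:, 2 * nq:2 * nq + nm], pts[:, 2 * nq + nm:],
                             np.repeat(ue, d, axis=0),
                             upts[:, :nm] * prob.config.dft_scale,
                             upts[:, nm:])
        wq = np.tile(prob.scheme.B, N) * (t_f / N)
        e_muscle = 2.0 * np.sum(wq[:, None] * phys["edot"], axis=0)  # J, full cycle
        body_mass = prob.cm.spec.total_mass()
        e_basal = (prob.config.basal_rate * body_mass * 2.0 * t_f) if basal else 0.0
        dist = 2.0 * self.distance
        cot = (e_muscle.sum() + e_basal) / (body_mass * dist)
        return {
            "muscle_energy": dict(zip(prob.cm.muscle_names, e_muscle)),
            "basal_energy": float(e_basal),
            "cot": float(cot),
            "distance": float(dist),
            "duration": float(2.0 * t_f),
        }

    def cot(self) -> float:
        return self.metabolic_report()["cot"]
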
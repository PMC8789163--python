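"""Planar rigid-body skeletal dynamics over a declarative kinematic tree.

A :class:`CompiledModel` turns a :class:`~stridesim.model.ModelSpec` into
array form and provides:

* forward kinematics with velocities and accelerations,
* inverse dynamics assembled from smooth elementary operations (so the whole
  pipeline is differentiable by complex step),
* the implicit dynamics residual ``M(q) u_a + bias(q, qd) - tau_applied``
  used as an equality path constraint by the optimal-control layer,
* muscle-tendon path lengths, polynomial geometry fitting, muscle joint
  torques, passive torques and contact-sphere forces.

Everything broadcasts over leading batch dimensions: ``q`` may be shaped
``(..., nq)`` with any batch shape, and complex dtypes propagate untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact import ContactSphere, sphere_force_planar
from .model import ModelSpec, PassiveTorqueParams, passive_torque
from .muscle import MTUGeometry, fit_polynomials

__all__ = ["CompiledModel", "torque_actuator_dynamics", "fit_model_geometry"]

TORQUE_ACTUATOR_TAU = 0.035  # s, first-order approximation of a time delay


def _perp(vx, vy):
    """90-degree rotation: perp((x, y)) = (-y, x)."""
    return -vy, vx


def torque_actuator_dynamics(e_a, torque, max_torque, tau=TORQUE_ACTUATOR_TAU):
    """First-order lag of an ideal torque motor toward e_a * max_torque."""
    return (np.asarray(e_a) * max_torque - np.asarray(torque)) / tau


@dataclass
class _Body:
    name: str
    parent: int          # body index, -1 for ground
    jtype: str           # 'hinge' | 'weld' | 'planar-free'
    jloc: tuple          # joint location in parent frame
    coord: int           # hinge coordinate index, -1 otherwise
    neutral: float
    mass: float
    inertia: float
    com: tuple


class CompiledModel:
    """Array-form planar model compiled from a :class:`ModelSpec`."""

    def __init__(self, spec: ModelSpec, geometry: dict | None = None):
        spec.validate()
        self.spec = spec
        self.coordinates = list(spec.coordinates)
        self.nq = len(self.coordinates)
        self._build_tree()
        self._build_coord_tables()
        self._build_passive_tables()
        self.geometry = geometry or {}
        self.muscles = list(spec.muscles)
        self.muscle_names = [m.name for m in self.muscles]
        self.nm = len(self.muscles)

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    def _build_tree(self):
        spec = self.spec
        cidx = {c: i for i, c in enumerate(self.coordinates)}
        seg_by_name = {s.name: s for s in spec.segments}
        bodies: list[_Body] = []
        body_index: dict[str, int] = {}
        pending = list(spec.joints)
        while pending:
            progressed = False
            for j in list(pending):
                if j.parent == "ground" or j.parent in body_index:
                    seg = seg_by_name[j.child]
                    if j.type == "hinge":
                        if j.coordinate not in cidx:
                            raise ValueError(
                                f"joint {j.name}: coordinate {j.coordinate!r} not declared")
                        coord = cidx[j.coordinate]
                    else:
                        coord = -1
                    bodies.append(_Body(
                        name=j.child,
                        parent=-1 if j.parent == "ground" else body_index[j.parent],
                        jtype=j.type, jloc=tuple(j.location), coord=coord,
                        neutral=j.neutral, mass=seg.mass, inertia=seg.inertia,
                        com=tuple(seg.com)))
                    body_index[j.child] = len(bodies) - 1
                    pending.remove(j)
                    progressed = True
            if not progressed:
                raise ValueError("kinematic tree is not connected to ground")
        self.bodies = bodies
        self.body_index = body_index
        self.nb = len(bodies)

    def _build_coord_tables(self):
        """Per-coordinate kind and pivot body; per-body affected coordinates."""
        kind = [""] * self.nq
        pivot_body = [-1] * self.nq
        base = next(b for b in self.bodies if b.jtype == "planar-free")
        base_idx = self.bodies.index(base)
        prefix = self.spec.joints[[j.child for j in self.spec.joints].index(base.name)].coordinate
        for suffix, k in (("_tx", "tx"), ("_ty", "ty"), ("_tilt", "rot")):
            name = prefix + suffix
            if name not in self.coordinates:
                raise ValueError(f"base coordinate {name!r} missing from the spec")
            i = self.coordinates.index(name)
            kind[i] = k
            pivot_body[i] = base_idx
        for bi, b in enumerate(self.bodies):
            if b.jtype == "hinge":
                kind[b.coord] = "hinge"
                pivot_body[b.coord] = bi
        self.coord_kind = kind
        self.coord_pivot = pivot_body
        self.base_body = base_idx
        self.base_coords = tuple(self.coordinates.index(prefix + s)
                                 for s in ("_tx", "_ty", "_tilt"))
        # coordinates affecting each body (base coords affect everything)
        affected = np.zeros((self.nb, self.nq), dtype=bool)
        for bi, b in enumerate(self.bodies):
            chain = []
            i = bi
            while i >= 0:
                chain.append(i)
                i = self.bodies[i].parent
            for i in chain:
                bb = self.bodies[i]
                if bb.jtype == "hinge":
                    affected[bi, bb.coord] = True
                elif bb.jtype == "planar-free":
                    for c in self.base_coords:
                        affected[bi, c] = True
        self.affected = affected

    def _build_passive_tables(self):
        self.passive_params = [self.spec.passive_torques.get(c, PassiveTorqueParams(damping=0.0))
                               for c in self.coordinates]

    def coordinate_ranges(self):
        """Coordinate name -> (lo, hi); base translations get broad defaults."""
        out = {}
        for j in self.spec.joints:
            if j.type == "hinge":
                out[j.coordinate] = tuple(j.range)
            elif j.type == "planar-free":
                out[j.coordinate + "_tx"] = (-10.0, 10.0)
                out[j.coordinate + "_ty"] = (0.3, 1.5)
                out[j.coordinate + "_tilt"] = tuple(j.range)
        return out

    def mirror_coordinate_permutation(self):
        """Permutation p with left/right coordinates swapped: q_mirrored = q[p]."""
        perm = []
        for name in self.coordinates:
            if name.endswith("_r"):
                perm.append(self.coordinates.index(name[:-2] + "_l"))
            elif name.endswith("_l"):
                perm.append(self.coordinates.index(name[:-2] + "_r"))
            else:
                perm.append(self.coordinates.index(name))
        return np.array(perm, dtype=int)

    def mirror_muscle_permutation(self):
        perm = []
        for name in self.muscle_names:
            if name.endswith("_r"):
                perm.append(self.muscle_names.index(name[:-2] + "_l"))
            elif name.endswith("_l"):
                perm.append(self.muscle_names.index(name[:-2] + "_r"))
            else:
                perm.append(self.muscle_names.index(name))
        return np.array(perm, dtype=int)

    # ------------------------------------------------------------------
    # kinematics
    # ------------------------------------------------------------------
    def kin(self, q, qd=None, qdd=None):
        """Forward kinematics of all bodies, with optional derivatives.

        Returns a dict of per-body lists: ``ang``, ``pos`` (joint/body origin),
        ``com`` and, when velocities/accelerations are supplied, ``omega``,
        ``vel``, ``alpha``, ``acc``, ``com_vel``, ``com_acc``.
        """
        q = np.asarray(q)
        want_vel = qd is not None
        want_acc = qdd is not None
        if want_acc and not want_vel:
            qd = np.zeros_like(q)
            want_vel = True
        zeros = np.zeros(q.shape[:-1], dtype=q.dtype)
        if want_vel:
            qd = np.asarray(qd)
            zeros = zeros + 0.0 * qd[..., 0]
        if want_acc:
            qdd = np.asarray(qdd)
            zeros = zeros + 0.0 * qdd[..., 0]

        ang, px, py = [], [], []
        om, vx, vy = [], [], []
        al, ax, ay = [], [], []
        cx, cy = [], []
        cvx, cvy, cax, cay = [], [], [], []
        itx, ity, itl = self.base_coords
        for b in self.bodies:
            if b.jtype == "planar-free":
                a_ = q[..., itl] + b.neutral
                px_, py_ = q[..., itx] + zeros, q[..., ity] + zeros
                if want_vel:
                    om_, vx_, vy_ = qd[..., itl] + zeros, qd[..., itx] + zeros, qd[..., ity] + zeros
                if want_acc:
                    al_, ax_, ay_ = qdd[..., itl] + zeros, qdd[..., itx] + zeros, qdd[..., ity] + zeros
            else:
                p = b.parent
                ap, cp, sp = ang[p], np.cos(ang[p]), np.sin(ang[p])
                lx, ly = b.jloc
                rx = cp * lx - sp * ly
                ry = sp * lx + cp * ly
                dq = q[..., b.coord] if b.jtype == "hinge" else 0.0
                a_ = ap + dq + b.neutral
                px_, py_ = px[p] + rx, py[p] + ry
                if want_vel:
                    dqd = qd[..., b.coord] if b.jtype == "hinge" else 0.0
                    om_ = om[p] + dqd
                    wx, wy = _perp(rx, ry)
                    vx_, vy_ = vx[p] + om[p] * wx, vy[p] + om[p] * wy
                if want_acc:
                    dqdd = qdd[..., b.coord] if b.jtype == "hinge" else 0.0
                    al_ = al[p] + dqdd
                    wx, wy = _perp(rx, ry)
                    ax_ = ax[p] + al[p] * wx - om[p] * om[p] * rx
                    ay_ = ay[p] + al[p] * wy - om[p] * om[p] * ry
            ang.append(a_); px.append(px_); py.append(py_)
            c_, s_ = np.cos(a_), np.sin(a_)
            gx = c_ * b.com[0] - s_ * b.com[1]
            gy = s_ * b.com[0] + c_ * b.com[1]
            cx.append(px_ + gx); cy.append(py_ + gy)
            if want_vel:
                om.append(om_); vx.append(vx_); vy.append(vy_)
                hx, hy = _perp(gx, gy)
                cvx.append(vx_ + om_ * hx); cvy.append(vy_ + om_ * hy)
            if want_acc:
                al.append(al_); ax.append(ax_); ay.append(ay_)
                hx, hy = _perp(gx, gy)
                cax.append(ax_ + al_ * hx - om_ * om_ * gx)
                cay.append(ay_ + al_ * hy - om_ * om_ * gy)
        out = {"ang": ang, "px": px, "py": py, "cx": cx, "cy": cy}
        if want_vel:
            out.update(omega=om, vx=vx, vy=vy, cvx=cvx, cvy=cvy)
        if want_acc:
            out.update(alpha=al, ax=ax, ay=ay, cax=cax, cay=cay)
        return out

    def point_position(self, q, segment: str, local):
        """World position of a point fixed in a segment frame."""
        k = self.kin(np.asarray(q, dtype=float))
        b = self.body_index[segment]
        c, s = np.cos(k["ang"][b]), np.sin(k["ang"][b])
        lx, ly = local
        return np.stack([k["px"][b] + c * lx - s * ly,
                         k["py"][b] + s * lx + c * ly], axis=-1)

    def _point_kin(self, kin, body: int, local):
        """Position and (if available) velocity of a body-fixed point."""
        a = kin["ang"][body]
        c, s = np.cos(a), np.sin(a)
        lx, ly = local
        rx = c * lx - s * ly
        ry = s * lx + c * ly
        px = kin["px"][body] + rx
        py = kin["py"][body] + ry
        if "omega" in kin:
            wx, wy = _perp(rx, ry)
            vx = kin["vx"][body] + kin["omega"][body] * wx
            vy = kin["vy"][body] + kin["omega"][body] * wy
            return px, py, vx, vy
        return px, py, None, None

    # ------------------------------------------------------------------
    # generalized forces
    # ------------------------------------------------------------------
    def _accumulate_point_force(self, Q, kin, body, px, py, fx, fy):
        for c in np.nonzero(self.affected[body])[0]:
            kind = self.coord_kind[c]
            if kind == "tx":
                Q[..., c] += fx
            elif kind == "ty":
                Q[..., c] += fy
            else:  # rotational: moment about the pivot
                pb = self.coord_pivot[c]
                Q[..., c] += (px - kin["px"][pb]) * fy - (py - kin["py"][pb]) * fx
        return Q

    def _accumulate_torque(self, Q, body, n):
        for c in np.nonzero(self.affected[body])[0]:
            if self.coord_kind[c] in ("rot", "hinge"):
                Q[..., c] += n
        return Q

    def inverse_dynamics(self, q, qd=None, qdd=None, ext_points=(), gravity=True):
        """Generalized forces realizing accelerations ``qdd`` at (q, qd).

        ``ext_points`` is an iterable of ``(segment, local, fx, fy)`` applied
        external forces; their generalized effect is subtracted, so the return
        value is the actuation required from muscles/passive structures.
        """
        q = np.asarray(q)
        qd = np.zeros_like(q) if qd is None else np.asarray(qd)
        qdd = np.zeros_like(q) if qdd is None else np.asarray(qdd)
        kin = self.kin(q, qd, qdd)
        dtype = np.result_type(q, qd, qdd)
        Q = np.zeros(np.broadcast_shapes(q.shape, qd.shape, qdd.shape)[:-1] + (self.nq,),
                     dtype=dtype)
        g = self.spec.gravity if gravity else 0.0
        for bi, b in enumerate(self.bodies):
            fx = b.mass * kin["cax"][bi]
            fy = b.mass * (kin["cay"][bi] + g)
            n = b.inertia * kin["alpha"][bi]
            self._accumulate_point_force(Q, kin, bi, kin["cx"][bi], kin["cy"][bi], fx, fy)
            self._accumulate_torque(Q, bi, n)
        for segment, local, fx, fy in ext_points:
            bi = self.body_index[segment]
            px, py, _, _ = self._point_kin(kin, bi, local)
            self._accumulate_point_force(Q, kin, bi, px, py, -fx, -fy)
        return Q

    def mass_matrix(self, q):
        """Joint-space mass matrix via unit-acceleration inverse dynamics."""
        q = np.asarray(q, dtype=float)
        eye = np.eye(self.nq)
        qb = np.broadcast_to(q, (self.nq,) + q.shape)
        cols = self.inverse_dynamics(qb, np.zeros_like(qb), eye.reshape(
            (self.nq,) + (1,) * (q.ndim - 1) + (self.nq,)), gravity=False)
        return np.moveaxis(cols, 0, -1)

    def bias(self, q, qd):
        """Coriolis/centrifugal + gravity generalized forces."""
        return self.inverse_dynamics(q, qd, np.zeros_like(np.asarray(q)))

    def dynamics_residual(self, q, qd, u_a, applied_tau=None, ext_points=()):
        """Implicit equations of motion: zero iff ``u_a`` are the accelerations."""
        res = self.inverse_dynamics(q, qd, u_a, ext_points=ext_points)
        if applied_tau is not None:
            res = res - applied_tau
        return res

    def forward_dynamics(self, q, qd, tau, ext_points=()):
        """Explicit accelerations; for integration tests and initial guesses."""
        m = self.mass_matrix(q)
        rhs = tau - self.inverse_dynamics(q, qd, np.zeros_like(np.asarray(q)),
                                          ext_points=ext_points)
        return np.linalg.solve(m, rhs[..., None])[..., 0]

    def energy(self, q, qd):
        """(kinetic, potential) mechanical energy."""
        kin = self.kin(np.asarray(q, dtype=float), np.asarray(qd, dtype=float))
        ke = 0.0
        pe = 0.0
        for bi, b in enumerate(self.bodies):
            ke = ke + 0.5 * b.mass * (kin["cvx"][bi] ** 2 + kin["cvy"][bi] ** 2) \
                + 0.5 * b.inertia * kin["omega"][bi] ** 2
            pe = pe + b.mass * self.spec.gravity * kin["cy"][bi]
        return ke, pe

    # ------------------------------------------------------------------
    # passive torques, muscles, contact
    # ------------------------------------------------------------------
    def passive_torque_vector(self, q, qd):
        q = np.asarray(q)
        qd = np.asarray(qd)
        cols = [passive_torque(q[..., i], qd[..., i], p)
                for i, p in enumerate(self.passive_params)]
        return np.stack(np.broadcast_arrays(*cols), axis=-1)

    def path_length(self, q, muscle_index: int):
        """Exact polyline muscle-tendon path length by forward kinematics."""
        m = self.muscles[muscle_index]
        kin = self.kin(np.asarray(q, dtype=float))
        pts = []
        for p in m.path:
            bi = self.body_index[p.segment]
            px, py, _, _ = self._point_kin(kin, bi, p.location)
            pts.append((px, py))
        total = 0.0
        for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
            total = total + np.sqrt((x1 - x0) ** 2 + (y1 - y0) ** 2)
        return total

    def muscle_kinematics(self, q, qd=None):
        """Polynomial muscle-tendon lengths, velocities and moment arms.

        Returns (lmt, vmt, arms) with lmt shaped (..., nm), arms a list of
        (coord_indices, values) per muscle.  Requires fitted geometry.
        """
        q = np.asarray(q)
        lmt = []
        vmt = []
        arms = []
        for m in self.muscles:
            g: MTUGeometry = self.geometry[m.name]
            ci = [self.coordinates.index(c) for c in g.coordinates]
            qi = q[..., ci]
            lmt.append(g.length(qi))
            r = g.moment_arms(qi)
            arms.append((ci, r))
            if qd is not None:
                vmt.append(-np.sum(r * np.asarray(qd)[..., ci], axis=-1))
        lmt = np.stack(np.broadcast_arrays(*lmt), axis=-1)
        vmt = np.stack(np.broadcast_arrays(*vmt), axis=-1) if qd is not None else None
        return lmt, vmt, arms

    def muscle_joint_torques(self, q, f_t):
        """tau_j = sum_m r_jm(q) * F_T_m over the spanned coordinates."""
        q = np.asarray(q)
        f_t = np.asarray(f_t)
        dtype = np.result_type(q, f_t)
        tau = np.zeros(np.broadcast_shapes(q.shape[:-1], f_t.shape[:-1]) + (self.nq,),
                       dtype=dtype)
        for mi, m in enumerate(self.muscles):
            g: MTUGeometry = self.geometry[m.name]
            ci = [self.coordinates.index(c) for c in g.coordinates]
            r = g.moment_arms(q[..., ci])
            for k, c in enumerate(ci):
                tau[..., c] += r[..., k] * f_t[..., mi]
        return tau

    def contact_forces(self, q, qd):
        """Per-sphere ground contact forces at the current state."""
        q = np.asarray(q)
        qd = np.asarray(qd) if qd is not None else np.zeros_like(q)
        kin = self.kin(q, qd)
        out = []
        for sph in self.spec.contact_spheres:
            bi = self.body_index[sph.segment]
            px, py, vx, vy = self._point_kin(kin, bi, sph.location)
            delta = sph.radius - py
            ft, fn = sphere_force_planar(delta, -vy, vx, sph)
            pos = np.stack(np.broadcast_arrays(px, py - sph.radius), axis=-1)
            out.append({"segment": sph.segment, "sphere": sph,
                        "force": np.stack(np.broadcast_arrays(ft, fn), axis=-1),
                        "position": pos})
        return out

    def contact_force_values(self, q, qd):
        """Stacked per-sphere contact forces (..., 2*n_spheres): [ftx, fn]."""
        q = np.asarray(q)
        qd = np.asarray(qd)
        kin = self.kin(q, qd)
        vals = []
        for sph in self.spec.contact_spheres:
            bi = self.body_index[sph.segment]
            px, py, vx, vy = self._point_kin(kin, bi, sph.location)
            delta = sph.radius - py
            ft, fn = sphere_force_planar(delta, -vy, vx, sph)
            vals.extend([ft, fn])
        return np.stack(np.broadcast_arrays(*vals), axis=-1)

    def contact_apply(self, q, forces_flat):
        """Generalized forces of given per-sphere contact forces.

        ``forces_flat`` is shaped (..., 2*n_spheres) in the order of
        :meth:`contact_force_values`; forces act at each sphere's lowest point.
        """
        q = np.asarray(q)
        kin = self.kin(q)
        dtype = np.result_type(q, forces_flat)
        Q = np.zeros(np.broadcast_shapes(q.shape[:-1], forces_flat.shape[:-1])
                     + (self.nq,), dtype=dtype)
        for si, sph in enumerate(self.spec.contact_spheres):
            bi = self.body_index[sph.segment]
            px, py, _, _ = self._point_kin(kin, bi, sph.location)
            self._accumulate_point_force(Q, kin, bi, px, py - sph.radius,
                                         forces_flat[..., 2 * si],
                                         forces_flat[..., 2 * si + 1])
        return Q

    def contact_generalized_forces(self, q, qd):
        """Generalized forces of all contact spheres; also returns per-sphere data."""
        q = np.asarray(q)
        qd = np.asarray(qd)
        kin = self.kin(q, qd)
        dtype = np.result_type(q, qd)
        Q = np.zeros(np.broadcast_shapes(q.shape, qd.shape)[:-1] + (self.nq,), dtype=dtype)
        entries = []
        for sph in self.spec.contact_spheres:
            bi = self.body_index[sph.segment]
            px, py, vx, vy = self._point_kin(kin, bi, sph.location)
            delta = sph.radius - py
            ft, fn = sphere_force_planar(delta, -vy, vx, sph)
            self._accumulate_point_force(Q, kin, bi, px, py - sph.radius, ft, fn)
            entries.append({"segment": sph.segment, "force_t": ft, "force_n": fn,
                            "x": px})
        return Q, entries


def fit_model_geometry(cmodel: CompiledModel, order: int = 5,
                       n_grid_1d: int = 40, n_grid_2d: int = 16,
                       fd_step: float = 1e-6) -> dict:
    """Fit polynomial muscle-tendon geometry for every muscle of a model.

    Spanned coordinates are detected numerically (a coordinate is spanned when
    perturbing it changes the exact path length).  Length samples come from
    the exact polyline path; moment-arm samples are central finite differences
    of that path, entering the fit as derivative observations.
    """
    ranges = cmodel.coordinate_ranges()
    geometry = {}
    rng = np.random.default_rng(0)
    for mi, m in enumerate(cmodel.muscles):
        spanned = []
        probes = rng.uniform(-0.3, 0.3, size=(3, cmodel.nq))
        for c in range(cmodel.nq):
            if cmodel.coord_kind[c] in ("tx", "ty"):
                continue
            dq = np.zeros(cmodel.nq)
            dq[c] = 1e-5
            if any(abs(cmodel.path_length(p + dq, mi) - cmodel.path_length(p - dq, mi)) > 1e-10
                   for p in probes):
                spanned.append(c)
        if not spanned:
            raise ValueError(f"muscle {m.name} spans no coordinate")
        names = [cmodel.coordinates[c] for c in spanned]
        grids = [np.linspace(*ranges[n], n_grid_1d if len(spanned) == 1 else n_grid_2d)
                 for n in names]
        mesh = np.meshgrid(*grids, indexing="ij")
        qs = np.stack([g.ravel() for g in mesh], axis=-1)
        qfull = np.zeros((len(qs), cmodel.nq))
        qfull[:, spanned] = qs
        lengths = cmodel.path_length(qfull, mi)
        arms = np.empty_like(qs)
        for k, c in enumerate(spanned):
            dq = np.zeros(cmodel.nq)
            dq[c] = fd_step
            arms[:, k] = -(cmodel.path_length(qfull + dq, mi)
                           - cmodel.path_length(qfull - dq, mi)) / (2 * fd_step)
        geometry[m.name] = fit_polynomials(qs, lengths, arms, names, order=order)
    return geometry
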
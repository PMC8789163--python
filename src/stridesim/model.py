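"""Declarative musculoskeletal model description and model variants.

A :class:`ModelSpec` is a plain, serializable description of segments,
joints, generalized coordinates, muscle-tendon units with their path points,
contact spheres, passive joint mechanics and collision pairs.  Mechanics
(kinematics, dynamics) live in :mod:`stridesim.dynamics`, which compiles a
spec into array form.

Variants of the paper-style sensitivity studies (locking the toe joints,
redistributing torso mass to the legs, shifting the contact spheres
vertically, scaling the series-elastic stiffness of the triceps surae) are
expressed as :class:`ModelVariant` transforms over a spec.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .contact import ContactSphere
from .muscle import MuscleTendonParams, PathPoint

__all__ = [
    "Segment", "Joint", "PassiveTorqueParams", "ModelSpec", "ModelVariant",
    "ModelConfigError", "passive_torque", "apply_variant", "collision_distance",
]

SCHEMA_VERSION = 1
GRAVITY = 9.81  # m/s^2, downward

TORSO_SEGMENT = "trunk"
TRICEPS_SURAE_TAG = "triceps_surae"
MTP_TAG = "mtp"


class ModelConfigError(ValueError):
    """Raised for inconsistent model definitions or variant parameters."""


@dataclass
class Segment:
    name: str
    mass: float               # kg
    inertia: float            # kg m^2 about the COM, out-of-plane axis
    length: float             # m
    com: tuple = (0.0, 0.0)   # COM offset in the segment frame, m

    def __post_init__(self):
        if self.mass < 0:
            raise ModelConfigError(f"segment {self.name}: negative mass")


@dataclass
class Joint:
    """Connection between a parent and child segment.

    ``hinge`` joints carry one rotational coordinate, ``planar-free`` the
    three base coordinates (tx, ty, rotation) and ``weld`` none.
    """

    name: str
    type: str                      # 'hinge' | 'weld' | 'planar-free'
    parent: str                    # parent segment name ('ground' for the base)
    child: str
    location: tuple = (0.0, 0.0)   # joint position in the parent frame, m
    coordinate: str = ""           # coordinate name (hinge)
    range: tuple = (-np.pi, np.pi)
    neutral: float = 0.0           # weld angle / hinge neutral position, rad
    tags: tuple = ()               # e.g. ('mtp',)

    def __post_init__(self):
        if self.type not in ("hinge", "weld", "planar-free"):
            raise ModelConfigError(f"joint {self.name}: unknown type {self.type!r}")


@dataclass
class PassiveTorqueParams:
    """Exponential joint-limit torques, linear spring and damping.

    torque(q, qdot) = -c_up * exp(r_up * (q - q_up))
                      + c_low * exp(r_low * (q_low - q))
                      - k_lin * (q - q_neutral) - damping * qdot
    """

    c_up: float = 0.0
    r_up: float = 5.0
    q_up: float = 0.0        # rad, upper soft limit
    c_low: float = 0.0
    r_low: float = 5.0
    q_low: float = 0.0       # rad, lower soft limit
    damping: float = 0.1     # Nm s / rad
    k_lin: float = 0.0       # Nm / rad
    q_neutral: float = 0.0   # rad

    def __post_init__(self):
        if self.damping < 0 or self.k_lin < 0:
            raise ModelConfigError("damping and linear stiffness must be >= 0")


def passive_torque(q, qdot, params: PassiveTorqueParams):
    """Total passive joint torque (Nm); smooth in (q, qdot)."""
    return (-params.c_up * np.exp(params.r_up * (np.asarray(q) - params.q_up))
            + params.c_low * np.exp(params.r_low * (params.q_low - np.asarray(q)))
            - params.k_lin * (np.asarray(q) - params.q_neutral)
            - params.damping * np.asarray(qdot))


@dataclass
class ModelVariant:
    """A reversible transform over a :class:`ModelSpec`."""

    toes_locked: bool = False
    torso_mass_delta: float = 0.0          # kg added to the torso, taken from the legs
    contact_vertical_offset: float = 0.0   # m added to every sphere center's y
    tendon_stiffness_fraction: float = 1.0

    def __post_init__(self):
        # tolerate float-accumulation overshoot (e.g. np.arange grids)
        if self.tendon_stiffness_fraction > 1.0:
            if self.tendon_stiffness_fraction > 1.0 + 1e-9:
                raise ModelConfigError("tendon_stiffness_fraction must be in (0, 1]")
            self.tendon_stiffness_fraction = 1.0
        if self.tendon_stiffness_fraction <= 0.0:
            raise ModelConfigError("tendon_stiffness_fraction must be in (0, 1]")

    def inverse(self) -> "ModelVariant":
        if self.toes_locked:
            raise ModelConfigError("locking the toes is not invertible")
        return ModelVariant(
            toes_locked=False,
            torso_mass_delta=-self.torso_mass_delta,
            contact_vertical_offset=-self.contact_vertical_offset,
            tendon_stiffness_fraction=1.0,
        )


@dataclass
class ModelSpec:
    """Declarative planar musculoskeletal model."""

    name: str
    segments: list = field(default_factory=list)
    joints: list = field(default_factory=list)
    coordinates: list = field(default_factory=list)   # ordered coordinate names
    muscles: list = field(default_factory=list)       # MuscleTendonParams
    torque_actuators: list = field(default_factory=list)  # dicts
    contact_spheres: list = field(default_factory=list)   # ContactSphere
    passive_torques: dict = field(default_factory=dict)   # coordinate -> params
    collision_pairs: list = field(default_factory=list)   # ((seg, (x,y)), (seg, (x,y)), min_dist)
    gravity: float = GRAVITY
    version: int = SCHEMA_VERSION

    # -- queries ---------------------------------------------------------
    def total_mass(self) -> float:
        return float(sum(s.mass for s in self.segments))

    def segment(self, name: str) -> Segment:
        for s in self.segments:
            if s.name == name:
                return s
        raise ModelConfigError(f"unknown segment {name!r}")

    def joint_for_coordinate(self, coordinate: str) -> Joint:
        for j in self.joints:
            if j.coordinate == coordinate and j.type == "hinge":
                return j
        raise ModelConfigError(f"no hinge joint drives coordinate {coordinate!r}")

    def mtp_coordinates(self) -> list:
        return [j.coordinate for j in self.joints
                if j.type == "hinge" and MTP_TAG in j.tags]

    def triceps_surae(self) -> list:
        return [m.name for m in self.muscles if TRICEPS_SURAE_TAG in m.tags]

    def validate(self):
        if self.total_mass() <= 0:
            raise ModelConfigError("total mass must be > 0")
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ModelConfigError("duplicate segment names")
        if len(set(self.coordinates)) != len(self.coordinates):
            raise ModelConfigError("duplicate coordinate names")
        for m in self.muscles:
            for p in m.path:
                if p.segment not in names:
                    raise ModelConfigError(
                        f"muscle {m.name} references unknown segment {p.segment!r}")
        for sph in self.contact_spheres:
            if sph.segment not in names:
                raise ModelConfigError(
                    f"contact sphere references unknown segment {sph.segment!r}")
        for j in self.joints:
            if j.parent != "ground" and j.parent not in names:
                raise ModelConfigError(f"joint {j.name}: unknown parent {j.parent!r}")
            if j.child not in names:
                raise ModelConfigError(f"joint {j.name}: unknown child {j.child!r}")
        return self

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        def plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return {
            "name": self.name,
            "version": self.version,
            "gravity": self.gravity,
            "segments": plain(self.segments),
            "joints": plain(self.joints),
            "coordinates": list(self.coordinates),
            "muscles": plain(self.muscles),
            "torque_actuators": plain(self.torque_actuators),
            "contact_spheres": plain(self.contact_spheres),
            "passive_torques": plain(self.passive_torques),
            "collision_pairs": plain(self.collision_pairs),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ModelSpec":
        def tup(x):
            return tuple(x) if isinstance(x, (list, tuple)) else x

        segments = [Segment(**{**d, "com": tup(d.get("com", (0, 0)))})
                    for d in data.get("segments", [])]
        joints = [Joint(**{**d, "location": tup(d.get("location", (0, 0))),
                           "range": tup(d.get("range", (-np.pi, np.pi))),
                           "tags": tup(d.get("tags", ()))})
                  for d in data.get("joints", [])]
        muscles = []
        for d in data.get("muscles", []):
            d = dict(d)
            d["path"] = tuple(PathPoint(p["segment"], tup(p["location"]))
                              for p in d.get("path", ()))
            d["tags"] = tup(d.get("tags", ()))
            muscles.append(MuscleTendonParams(**d))
        spheres = [ContactSphere(**{**d, "location": tup(d["location"])})
                   for d in data.get("contact_spheres", [])]
        passive = {k: PassiveTorqueParams(**v)
                   for k, v in data.get("passive_torques", {}).items()}
        pairs = [((p[0][0], tup(p[0][1])), (p[1][0], tup(p[1][1])), p[2])
                 for p in data.get("collision_pairs", [])]
        return cls(
            name=data["name"],
            version=data.get("version", SCHEMA_VERSION),
            gravity=data.get("gravity", GRAVITY),
            segments=segments,
            joints=joints,
            coordinates=list(data.get("coordinates", [])),
            muscles=muscles,
            torque_actuators=list(data.get("torque_actuators", [])),
            contact_spheres=spheres,
            passive_torques=passive,
            collision_pairs=pairs,
        ).validate()

    def save(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _leg_segments(spec: ModelSpec):
    return [s for s in spec.segments if s.name.endswith(("_r", "_l"))]


def apply_variant(spec: ModelSpec, variant: ModelVariant) -> ModelSpec:
    """Return a new :class:`ModelSpec` with the variant applied.

    Total mass is conserved exactly: mass added to the torso is removed from
    the leg segments proportionally to their masses (and vice versa), with
    segment inertias rescaled linearly with mass.

    Every application records an undo snapshot on the result, so applying
    ``variant.inverse()`` to it restores the original spec bit-for-bit
    (floating-point round trips through the arithmetic would not be exact).
    """
    undo = getattr(spec, "_variant_undo", None)
    if undo is not None and undo[0] == variant:
        return copy.deepcopy(undo[1])
    out = copy.deepcopy(spec)

    if variant.torso_mass_delta != 0.0:
        torso = out.segment(TORSO_SEGMENT)
        legs = _leg_segments(out)
        leg_mass = sum(s.mass for s in legs)
        if leg_mass <= 0:
            raise ModelConfigError("no leg mass to redistribute")
        delta = variant.torso_mass_delta
        if torso.mass + delta <= 0:
            raise ModelConfigError("variant would empty the torso")
        scale_t = (torso.mass + delta) / torso.mass
        torso.mass += delta
        torso.inertia *= scale_t
        for s in legs:
            share = s.mass / leg_mass
            scale = (s.mass - delta * share) / s.mass
            s.mass -= delta * share
            s.inertia *= scale

    if variant.contact_vertical_offset != 0.0:
        out.contact_spheres = [
            dataclasses.replace(s, location=(s.location[0],
                                             s.location[1] + variant.contact_vertical_offset))
            for s in out.contact_spheres]

    if variant.tendon_stiffness_fraction != 1.0:
        ts = out.triceps_surae()
        if not ts:
            raise ModelConfigError("no triceps-surae muscles tagged in the model")
        out.muscles = [
            dataclasses.replace(m, stiffness_fraction=variant.tendon_stiffness_fraction)
            if m.name in ts else m
            for m in out.muscles]

    if variant.toes_locked:
        mtp_coords = out.mtp_coordinates()
        if not mtp_coords:
            raise ModelConfigError("model has no toe joints to lock")
        for j in out.joints:
            if j.coordinate in mtp_coords:
                j.type = "weld"
                j.coordinate = ""
        out.coordinates = [c for c in out.coordinates if c not in mtp_coords]
        out.passive_torques = {c: p for c, p in out.passive_torques.items()
                               if c not in mtp_coords}
        out.name = out.name + "+locked_toes"

    if not variant.toes_locked:
        out._variant_undo = (variant.inverse(), copy.deepcopy(spec))
    return out.validate()


def collision_distance(q, spec: ModelSpec):
    """Euclidean distances between the declared collision point pairs.

    Points are resolved to the ground frame by forward kinematics at ``q``.
    Returns an empty list when no pairs are declared.
    """
    if not spec.collision_pairs:
        return []
    from .dynamics import CompiledModel

    cm = CompiledModel(spec)
    dists = []
    for (seg_a, loc_a), (seg_b, loc_b), _min_dist in spec.collision_pairs:
        pa = cm.point_position(q, seg_a, loc_a)
        pb = cm.point_position(q, seg_b, loc_b)
        dists.append(float(np.hypot(*(np.asarray(pa) - np.asarray(pb)))))
    return dists
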
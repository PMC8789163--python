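"""Model description: passive torques, variants, serialization, collisions."""

import copy

import numpy as np
import pytest

from stridesim.model import (ModelConfigError, ModelSpec, ModelVariant,
                             PassiveTorqueParams, apply_variant,
                             collision_distance, passive_torque)
from stridesim.synth import make_planar_fixture


class TestPassiveTorque:
    def test_toe_spring_contribution(self):
        p = PassiveTorqueParams(k_lin=25.0, damping=0.0)
        # 0.1 rad extension with a 25 Nm/rad spring -> -2.5 Nm
        assert passive_torque(0.1, 0.0, p) == pytest.approx(-2.5)

    def test_toe_damping_contribution(self):
        p = PassiveTorqueParams(damping=2.0)
        assert passive_torque(0.0, 1.0, p) == pytest.approx(-2.0)

    def test_symmetric_exponentials_cancel_at_neutral(self):
        p = PassiveTorqueParams(c_up=2.0, r_up=5.0, q_up=0.5,
                                c_low=2.0, r_low=5.0, q_low=-0.5, damping=0.0)
        assert passive_torque(0.0, 0.0, p) == pytest.approx(0.0, abs=1e-15)

    def test_limits_resist_excursion(self):
        p = PassiveTorqueParams(c_up=2.0, r_up=5.0, q_up=0.5,
                                c_low=2.0, r_low=5.0, q_low=-0.5, damping=0.0)
        assert passive_torque(1.0, 0.0, p) < -1.0
        assert passive_torque(-1.0, 0.0, p) > 1.0

    def test_negative_damping_rejected(self):
        with pytest.raises(ModelConfigError):
            PassiveTorqueParams(damping=-0.1)


class TestVariants:
    def test_mass_redistribution_conserves_total(self, fixture_spec):
        total = fixture_spec.total_mass()
        out = apply_variant(fixture_spec, ModelVariant(torso_mass_delta=-7.4))
        assert out.total_mass() == pytest.approx(total, abs=1e-12)
        assert out.segment("trunk").mass == pytest.approx(
            fixture_spec.segment("trunk").mass - 7.4)
        # legs gained what the torso lost, proportionally
        gain = sum(s.mass for s in out.segments if s.name.endswith(("_r", "_l"))) \
            - sum(s.mass for s in fixture_spec.segments if s.name.endswith(("_r", "_l")))
        assert gain == pytest.approx(7.4, abs=1e-12)

    def test_inertia_scales_linearly_with_mass(self, fixture_spec):
        out = apply_variant(fixture_spec, ModelVariant(torso_mass_delta=-7.4))
        for name in ("trunk", "thigh_r"):
            s0 = fixture_spec.segment(name)
            s1 = out.segment(name)
            assert s1.inertia / s0.inertia == pytest.approx(s1.mass / s0.mass, rel=1e-12)

    def test_variant_round_trip_bitwise(self, fixture_spec):
        v = ModelVariant(torso_mass_delta=-7.4, contact_vertical_offset=0.01)
        out = apply_variant(apply_variant(fixture_spec, v), v.inverse())
        for s0, s1 in zip(fixture_spec.segments, out.segments):
            assert s0.mass == s1.mass
            assert s0.inertia == pytest.approx(s1.inertia, rel=1e-14)
        for c0, c1 in zip(fixture_spec.contact_spheres, out.contact_spheres):
            assert c0.location == c1.location

    def test_identity_variant_is_noop(self, fixture_spec):
        out = apply_variant(fixture_spec, ModelVariant())
        assert out.to_dict() == fixture_spec.to_dict()

    def test_contact_offset_moves_all_spheres(self, fixture_spec):
        out = apply_variant(fixture_spec, ModelVariant(contact_vertical_offset=0.01))
        for c0, c1 in zip(fixture_spec.contact_spheres, out.contact_spheres):
            assert c1.location[1] - c0.location[1] == pytest.approx(0.01)
            assert c1.location[0] == c0.location[0]
            assert c1.radius == c0.radius

    def test_toes_locked_welds_and_removes_coordinates(self, fixture_spec):
        out = apply_variant(fixture_spec, ModelVariant(toes_locked=True))
        assert len(out.coordinates) == len(fixture_spec.coordinates) - 2
        assert not out.mtp_coordinates()
        assert all("mtp" not in c for c in out.coordinates)
        assert all("mtp" not in c for c in out.passive_torques)
        welds = [j for j in out.joints if j.type == "weld"]
        assert len(welds) == 2
        assert out.total_mass() == pytest.approx(fixture_spec.total_mass(), abs=1e-12)

    def test_tendon_fraction_applies_to_triceps_surae_only(self, fixture_spec):
        out = apply_variant(fixture_spec, ModelVariant(tendon_stiffness_fraction=0.4))
        for m in out.muscles:
            if m.name in out.triceps_surae():
                assert m.stiffness_fraction == pytest.approx(0.4)
                assert m.k == pytest.approx(14.0)
            else:
                assert m.stiffness_fraction == pytest.approx(1.0)

    def test_locking_not_invertible(self):
        with pytest.raises(ModelConfigError):
            ModelVariant(toes_locked=True).inverse()

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ModelConfigError):
            ModelVariant(tendon_stiffness_fraction=0.0)


class TestSerialization:
    def test_yaml_round_trip(self, fixture_spec, tmp_path):
        path = tmp_path / "model.yaml"
        fixture_spec.save(path)
        back = ModelSpec.load(path)
        assert back.to_dict() == fixture_spec.to_dict()

    def test_version_field_present(self, fixture_spec):
        assert fixture_spec.to_dict()["version"] == 1

    def test_validation_rejects_unknown_segment(self, fixture_spec):
        broken = copy.deepcopy(fixture_spec)
        broken.contact_spheres[0] = type(broken.contact_spheres[0])(
            "nonexistent", (0, 0), 0.02)
        with pytest.raises(ModelConfigError):
            broken.validate()

    def test_duplicate_coordinates_rejected(self, fixture_spec):
        broken = copy.deepcopy(fixture_spec)
        broken.coordinates[1] = broken.coordinates[0]
        with pytest.raises(ModelConfigError):
            broken.validate()


class TestCollisionDistance:
    def test_empty_when_no_pairs(self, fixture_spec):
        assert collision_distance(np.zeros(11), fixture_spec) == []

    def test_coincident_points_zero(self):
        spec = make_planar_fixture()
        spec.collision_pairs = [(("shank_r", (0.0, -0.2)),
                                 ("shank_r", (0.0, -0.2)), 0.0)]
        q = np.zeros(len(spec.coordinates))
        q[1] = 0.9
        assert collision_distance(q, spec)[0] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_posture_symmetric_distances(self):
        spec = make_planar_fixture()
        spec.collision_pairs = [
            (("shank_r", (0.0, -0.2)), ("trunk", (0.0, 0.0)), 0.0),
            (("shank_l", (0.0, -0.2)), ("trunk", (0.0, 0.0)), 0.0),
        ]
        q = np.zeros(len(spec.coordinates))
        q[1] = 0.9
        d = collision_distance(q, spec)
        assert d[0] == pytest.approx(d[1], rel=1e-12)

    def test_matches_manual_chain_transform(self):
        spec = make_planar_fixture()
        spec.collision_pairs = [(("shank_r", (0.02, -0.1)),
                                 ("shank_l", (-0.02, -0.15)), 0.0)]
        rng = np.random.default_rng(11)
        q = rng.uniform(-0.4, 0.4, len(spec.coordinates))
        q[1] = 0.9

        # independent forward kinematics: explicit chain composition
        def rot(t):
            return np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])

        thigh_l = 0.245 * 1.70
        names = spec.coordinates

        def shank_point(side, local):
            base = np.array([q[0], q[1]])
            r_pelvis = rot(q[2])
            hip = base  # hips at trunk origin
            r_thigh = rot(q[2] + q[names.index(f"hip_{side}")])
            knee = hip + r_thigh @ np.array([0.0, -thigh_l])
            r_shank = rot(q[2] + q[names.index(f"hip_{side}")]
                          + q[names.index(f"knee_{side}")])
            return knee + r_shank @ np.asarray(local)

        expected = np.linalg.norm(shank_point("r", (0.02, -0.1))
                                  - shank_point("l", (-0.02, -0.15)))
        assert collision_distance(q, spec)[0] == pytest.approx(expected, abs=1e-12)
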
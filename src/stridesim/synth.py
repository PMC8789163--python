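"""Generators for everything the pipeline measures or imports.

* :func:`make_planar_fixture` - a planar 11-coordinate (9 when the toes are
  locked), 9-muscle-per-leg walking model with two-segment feet, toe
  spring-dampers and three contact spheres per foot, anthropometry anchored
  at 62 kg / 1.70 m.
* :func:`make_reference_gait` - a periodic, half-cycle left-right symmetric
  reference gait dataset (joint angles, torques, GRF, EMG envelopes, mean and
  SD bands) emulating overground walking at ~1.33 m/s with ~60% stance and a
  double-hump vertical GRF.  Deterministic given (seed, params).
* :func:`make_initial_population` - perturbed cold-start guesses.

The templates below are fixture constants chosen for physiological shape;
they are not claims about any particular subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .contact import ContactSphere
from .model import (Joint, ModelSpec, PassiveTorqueParams, Segment,
                    TRICEPS_SURAE_TAG)
from .muscle import MuscleTendonParams, PathPoint

__all__ = ["ReferenceGait", "make_reference_gait", "make_planar_fixture",
           "make_initial_population"]

_MUSCLE_DENSITY = 1059.7     # kg/m^3
_SPECIFIC_TENSION = 2.5e5    # N/m^2


# ---------------------------------------------------------------------------
# Planar fixture model
# ---------------------------------------------------------------------------

def make_planar_fixture(body_mass: float = 62.0, height: float = 1.70,
                        with_toes: bool = True) -> ModelSpec:
    """Planar two-legged walking model with two-segment feet.

    Coordinates: pelvis_tx, pelvis_ty, pelvis_tilt then hip/knee/ankle/mtp
    per leg.  Signs: hip flexion +, knee flexion -, ankle dorsiflexion +,
    toe (MTP) extension +.  Segment masses sum to ``body_mass`` exactly.
    """
    thigh_l = 0.245 * height
    shank_l = 0.246 * height
    m_thigh = 0.100 * body_mass
    m_shank = 0.0465 * body_mass
    m_foot = 0.0145 * body_mass
    m_hind = 0.85 * m_foot
    m_toes = 0.15 * m_foot
    m_trunk = body_mass - 2 * (m_thigh + m_shank + m_hind + m_toes)

    segments = [Segment("trunk", m_trunk, 0.35 * m_trunk * 0.30 ** 2 + 1.0,
                        0.60, (-0.01, 0.28))]
    joints = [Joint("ground_pelvis", "planar-free", "ground", "trunk",
                    coordinate="pelvis", range=(-1.0, 1.0))]
    coordinates = ["pelvis_tx", "pelvis_ty", "pelvis_tilt"]
    passive = {
        "pelvis_tilt": PassiveTorqueParams(c_up=1.0, r_up=5.0, q_up=0.5,
                                           c_low=1.0, r_low=5.0, q_low=-0.5,
                                           damping=0.1),
    }
    muscles = []
    spheres = []
    mtp_x = 0.55 * 0.152 * height      # MTP joint forward of the ankle
    sole_y = -0.045                     # sphere centers below the ankle
    for side in ("r", "l"):
        sfx = f"_{side}"
        segments += [
            Segment(f"thigh{sfx}", m_thigh, m_thigh * (0.323 * thigh_l) ** 2,
                    thigh_l, (0.0, -0.433 * thigh_l)),
            Segment(f"shank{sfx}", m_shank, m_shank * (0.302 * shank_l) ** 2,
                    shank_l, (0.0, -0.433 * shank_l)),
            Segment(f"hindfoot{sfx}", m_hind, 0.0050, 0.19, (0.05, -0.035)),
            Segment(f"toes{sfx}", m_toes, 0.0002, 0.06, (0.025, -0.005)),
        ]
        joints += [
            Joint(f"hip{sfx}", "hinge", "trunk", f"thigh{sfx}", (0.0, 0.0),
                  coordinate=f"hip{sfx}", range=(-0.9, 1.4)),
            Joint(f"knee{sfx}", "hinge", f"thigh{sfx}", f"shank{sfx}",
                  (0.0, -thigh_l), coordinate=f"knee{sfx}", range=(-2.1, 0.1)),
            Joint(f"ankle{sfx}", "hinge", f"shank{sfx}", f"hindfoot{sfx}",
                  (0.0, -shank_l), coordinate=f"ankle{sfx}", range=(-0.9, 0.7)),
            Joint(f"mtp{sfx}", "hinge", f"hindfoot{sfx}", f"toes{sfx}",
                  (mtp_x, sole_y), coordinate=f"mtp{sfx}", range=(-0.5, 1.2),
                  tags=("mtp",)),
        ]
        coordinates += [f"hip{sfx}", f"knee{sfx}", f"ankle{sfx}", f"mtp{sfx}"]
        passive.update({
            f"hip{sfx}": PassiveTorqueParams(c_up=2.0, r_up=5.0, q_up=1.2,
                                             c_low=2.0, r_low=5.0, q_low=-0.7,
                                             damping=0.1),
            f"knee{sfx}": PassiveTorqueParams(c_up=4.0, r_up=10.0, q_up=0.0,
                                              c_low=2.0, r_low=5.0, q_low=-2.0,
                                              damping=0.1),
            f"ankle{sfx}": PassiveTorqueParams(c_up=2.0, r_up=5.0, q_up=0.6,
                                               c_low=2.0, r_low=5.0, q_low=-0.8,
                                               damping=0.1),
            f"mtp{sfx}": PassiveTorqueParams(c_up=2.0, r_up=5.0, q_up=1.0,
                                             c_low=2.0, r_low=5.0, q_low=-0.4,
                                             damping=2.0, k_lin=25.0),
        })
        muscles += _leg_muscles(sfx, thigh_l, shank_l)
        spheres += [
            ContactSphere(f"hindfoot{sfx}", (-0.04, sole_y), 0.02,
                          stiffness=3.0e5, dissipation=1.0),
            ContactSphere(f"hindfoot{sfx}", (mtp_x - 0.02, sole_y), 0.02,
                          stiffness=3.0e5, dissipation=1.0),
            ContactSphere(f"toes{sfx}", (0.03, 0.0), 0.02,
                          stiffness=3.0e5, dissipation=1.0),
        ]

    spec = ModelSpec(
        name="planar_fixture",
        segments=segments, joints=joints, coordinates=coordinates,
        muscles=muscles, contact_spheres=spheres, passive_torques=passive,
        torque_actuators=[], collision_pairs=[],
    ).validate()
    if not with_toes:
        from .model import ModelVariant, apply_variant
        spec = apply_variant(spec, ModelVariant(toes_locked=True))
        spec.name = "planar_fixture_no_toes"
    return spec


def _leg_muscles(sfx: str, thigh_l: float, shank_l: float):
    """Nine Hill-type muscles of one leg with via-point paths."""
    t = f"thigh{sfx}"
    s = f"shank{sfx}"
    h = f"hindfoot{sfx}"
    tr = "trunk"
    kp = -thigh_l        # knee y in thigh frame
    ap = -shank_l        # ankle y in shank frame
    defs = [
        # name, F_max, l_m_opt, alpha_opt, ft_frac, path, tags
        ("glut", 3000.0, 0.12, 0.20, 0.45,
         [(tr, (-0.08, 0.08)), (t, (-0.04, -0.12))], ()),
        ("iliopsoas", 2000.0, 0.11, 0.15, 0.50,
         [(tr, (0.05, 0.05)), (t, (0.015, -0.07))], ()),
        ("hamstrings", 3000.0, 0.10, 0.25, 0.45,
         [(tr, (-0.06, -0.02)), (s, (-0.035, -0.05))], ()),
        ("rect_fem", 1200.0, 0.095, 0.10, 0.55,
         [(tr, (0.05, -0.01)), (t, (0.05, kp + 0.02)), (s, (0.04, -0.08))], ()),
        ("vasti", 5000.0, 0.097, 0.08, 0.50,
         [(t, (0.03, -0.15)), (t, (0.05, kp + 0.02)), (s, (0.04, -0.08))], ()),
        ("bifemsh", 800.0, 0.11, 0.40, 0.50,
         [(t, (-0.025, -0.25)), (s, (-0.035, -0.06))], ()),
        ("gastroc", 2500.0, 0.06, 0.30, 0.45,
         [(t, (-0.025, kp + 0.025)), (h, (-0.05, -0.03))], (TRICEPS_SURAE_TAG,)),
        ("soleus", 3500.0, 0.05, 0.44, 0.20,
         [(s, (-0.02, -0.15)), (h, (-0.05, -0.03))], (TRICEPS_SURAE_TAG,)),
        ("tib_ant", 1200.0, 0.08, 0.17, 0.30,
         [(s, (0.025, -0.18)), (s, (0.035, ap + 0.04)), (h, (0.06, -0.02))], ()),
    ]
    out = []
    for name, fmax, lmopt, alpha, ftf, path, tags in defs:
        pts = tuple(PathPoint(seg, tuple(loc)) for seg, loc in path)
        # tendon slack length from the neutral-posture path length so that the
        # fiber sits near optimal length when standing
        length0 = _polyline_length_neutral(pts, thigh_l, shank_l)
        ltslack = length0 - lmopt * np.cos(alpha)
        if ltslack <= 0.01:
            raise ValueError(f"{name}: non-positive tendon slack length")
        out.append(MuscleTendonParams(
            name=name + sfx, f_max=fmax, l_m_opt=lmopt, l_t_slack=float(ltslack),
            alpha_opt=alpha, v_max=10.0,
            fast_twitch_fraction=ftf,
            mass=float(fmax / _SPECIFIC_TENSION * lmopt * _MUSCLE_DENSITY),
            path=pts, tags=tags))
    return out


def _polyline_length_neutral(path, thigh_l, shank_l):
    """Path length in the neutral posture (all joint angles zero)."""
    offs = {"trunk": (0.0, 0.0)}
    for sfx in ("_r", "_l"):
        offs[f"thigh{sfx}"] = (0.0, 0.0)
        offs[f"shank{sfx}"] = (0.0, -thigh_l)
        offs[f"hindfoot{sfx}"] = (0.0, -thigh_l - shank_l)
        offs[f"toes{sfx}"] = (0.55 * 0.152 * 1.70, -thigh_l - shank_l - 0.045)
    pts = [(offs[p.segment][0] + p.location[0], offs[p.segment][1] + p.location[1])
           for p in path]
    return sum(np.hypot(x1 - x0, y1 - y0)
               for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]))


# ---------------------------------------------------------------------------
# Reference gait dataset
# ---------------------------------------------------------------------------

@dataclass
class ReferenceGait:
    """Periodic mean +- SD gait curves on a 0-100% gait-cycle grid.

    0% is right heel strike; left-side signals equal the right-side signals
    shifted by half a cycle.  Angles rad, torques Nm, forces N, EMG in [0, 1].
    """

    grid: np.ndarray                  # percent of gait cycle, 0..100 inclusive
    signals: dict                     # name -> {"mean", "sd", "units"}
    speed: float                      # m/s
    stance_fraction: float
    cycle_duration: float             # s
    seed: int
    params: dict = field(default_factory=dict)

    def mean(self, name):
        return self.signals[name]["mean"]

    def sd(self, name):
        return self.signals[name]["sd"]

    def interpolator(self, name):
        """Periodic interpolant of a mean curve over phase in [0, 1]."""
        y = self.signals[name]["mean"]
        return CubicSpline(self.grid / 100.0, y, bc_type="periodic")

    def validate(self, atol=1e-9):
        n = len(self.grid)
        for name, sig in self.signals.items():
            if len(sig["mean"]) != n or len(sig["sd"]) != n:
                raise ValueError(f"{name}: grid length mismatch")
            if abs(sig["mean"][0] - sig["mean"][-1]) > atol:
                raise ValueError(f"{name}: curve not periodic")
            if np.any(sig["sd"] < 0):
                raise ValueError(f"{name}: negative SD")
        half = (n - 1) // 2
        for name in self.signals:
            if name.endswith("_l"):
                other = name[:-2] + "_r"
                lhs = self.signals[name]["mean"][:-1]
                rhs = np.roll(self.signals[other]["mean"][:-1], -half)
                if not np.allclose(lhs, rhs, atol=1e-8):
                    raise ValueError(f"{name}: half-cycle symmetry violated")
        return self


def _periodic_template(keys: dict, grid_pct: np.ndarray, harmonics: int = 6):
    """Smooth periodic curve through (percent -> value) keypoints.

    A periodic cubic spline through the keypoints is low-passed to the given
    number of Fourier harmonics, which keeps shapes physiological and
    guarantees exact periodicity.
    """
    pct = sorted(keys)
    x = np.array(pct + [pct[0] + 100.0])
    y = np.array([keys[p] for p in pct] + [keys[pct[0]]])
    cs = CubicSpline(x, y, bc_type="periodic")
    fine = np.linspace(x[0], x[0] + 100.0, 512, endpoint=False)
    spec = np.fft.rfft(cs(fine))
    spec[harmonics + 1:] = 0.0
    smooth = np.fft.irfft(spec, 512)
    full = CubicSpline(np.append(fine, x[0] + 100.0), np.append(smooth, smooth[0]),
                       bc_type="periodic")
    return full(grid_pct % 100.0 + x[0] * 0)


def _gauss(phi, center, width):
    d = phi - center
    d = (d + 0.5) % 1.0 - 0.5   # periodic distance
    return np.exp(-0.5 * (d / width) ** 2)


_ANGLE_KEYS = {
    "hip": {0: 28.0, 10: 23.0, 30: 3.0, 50: -12.0, 60: -8.0, 72: 12.0, 85: 30.0, 95: 30.0},
    "knee": {0: -5.0, 8: -17.0, 15: -16.0, 40: -4.0, 50: -14.0, 62: -45.0,
             70: -62.0, 80: -40.0, 92: -8.0},
    "ankle": {0: 0.0, 6: -6.0, 30: 8.0, 45: 12.0, 55: -5.0, 62: -18.0,
              70: -8.0, 85: 2.0},
    "mtp": {0: 0.0, 30: 2.0, 45: 12.0, 57: 28.0, 64: 12.0, 75: 0.0, 90: 0.0},
}

_TORQUE_KEYS = {
    "hip": {0: 40.0, 15: 20.0, 40: -30.0, 55: -20.0, 65: 15.0, 85: 5.0},
    "knee": {0: -10.0, 12: 35.0, 30: 5.0, 50: -5.0, 62: 12.0, 80: 0.0},
    "ankle": {0: 5.0, 10: -20.0, 40: -80.0, 50: -100.0, 58: -20.0, 70: 0.0},
}

_EMG_BURSTS = {
    # muscle -> list of (center phase, width, amplitude)
    "glut": [(0.04, 0.06, 0.7), (0.95, 0.05, 0.3)],
    "iliopsoas": [(0.62, 0.06, 0.8)],
    "hamstrings": [(0.95, 0.06, 0.8), (0.05, 0.05, 0.5)],
    "rect_fem": [(0.62, 0.05, 0.5), (0.08, 0.05, 0.3)],
    "vasti": [(0.08, 0.06, 0.8)],
    "bifemsh": [(0.68, 0.07, 0.5)],
    "gastroc": [(0.40, 0.08, 0.9)],
    "soleus": [(0.42, 0.09, 0.9)],
    "tib_ant": [(0.02, 0.04, 0.8), (0.65, 0.08, 0.6)],
}


def make_reference_gait(seed: int = 0, speed: float = 1.33,
                        stance_fraction: float = 0.60, body_mass: float = 62.0,
                        cycle_duration: float = 1.10, harmonics: int = 6,
                        noise_sd_scale: float = 1.0, n_cycles: int = 10,
                        n_grid: int = 101) -> ReferenceGait:
    """Generate the synthetic periodic reference-gait dataset.

    Mean and SD curves are produced by averaging ``n_cycles`` noisy cycles
    (smooth seeded perturbations of the templates); the result is bit-wise
    deterministic given the arguments.
    """
    if not 0.4 <= stance_fraction <= 0.8:
        raise ValueError("stance_fraction outside the supported range")
    if speed <= 0 or cycle_duration <= 0 or n_grid < 11:
        raise ValueError("invalid reference-gait parameters")
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 100.0, n_grid)
    phi = grid / 100.0
    bw = body_mass * 9.81
    deg = np.pi / 180.0

    templates = {}
    for joint in ("hip", "knee", "ankle", "mtp"):
        templates[f"{joint}_r"] = _periodic_template(_ANGLE_KEYS[joint], grid,
                                                     harmonics) * deg
    templates["pelvis_tilt"] = (-2.0 + 1.0 * np.cos(4 * np.pi * phi)) * deg
    templates["pelvis_ty"] = 0.90 + 0.010 * np.cos(4 * np.pi * (phi - 0.05))
    templates["pelvis_tx"] = speed * cycle_duration * phi \
        + 0.01 * np.sin(4 * np.pi * phi)
    for joint in ("hip", "knee", "ankle"):
        templates[f"{joint}_r_torque"] = _periodic_template(
            _TORQUE_KEYS[joint], grid, harmonics)

    # double-hump vertical GRF with exact single-foot impulse balance
    hump = (1.10 * _gauss(phi, 0.13, 0.065) + 1.08 * _gauss(phi, 0.47, 0.065)
            + 0.72 * _gauss(phi, 0.30, 0.11))
    window = (0.5 * (1 + np.tanh((phi - 0.012) / 0.012))
              * 0.5 * (1 + np.tanh((stance_fraction - 0.012 - phi) / 0.012)))
    vy = hump * window
    fine_phi = np.linspace(0, 1, 2048, endpoint=False)
    hump_f = (1.10 * _gauss(fine_phi, 0.13, 0.065) + 1.08 * _gauss(fine_phi, 0.47, 0.065)
              + 0.72 * _gauss(fine_phi, 0.30, 0.11))
    window_f = (0.5 * (1 + np.tanh((fine_phi - 0.012) / 0.012))
                * 0.5 * (1 + np.tanh((stance_fraction - 0.012 - fine_phi) / 0.012)))
    scale = 0.5 / np.mean(hump_f * window_f)
    templates["grf_r_vy"] = bw * scale * vy
    templates["grf_r_vx"] = bw * 0.18 * (
        -_gauss(phi, 0.10, 0.06) + _gauss(phi, 0.50, 0.06)) * window

    for muscle, bursts in _EMG_BURSTS.items():
        env = np.zeros_like(phi)
        for c, w, amp in bursts:
            env = env + amp * _gauss(phi, c, w)
        templates[f"{muscle}_r_emg"] = np.minimum(env, 1.0)

    sd_scale = {"": 2.0 * deg, "_torque": 8.0, "_emg": 0.05}

    signals = {}
    order = sorted(templates)
    for name in order:
        base = templates[name]
        if name.endswith("_torque"):
            sd0 = sd_scale["_torque"]
        elif name.endswith("_emg"):
            sd0 = sd_scale["_emg"]
        elif name.startswith("grf"):
            sd0 = 0.04 * bw
        elif name == "pelvis_ty":
            sd0 = 0.005
        elif name == "pelvis_tx":
            sd0 = 0.01
        else:
            sd0 = sd_scale[""]
        cycles = np.empty((n_cycles, n_grid))
        for i in range(n_cycles):
            amp = rng.normal(0.0, sd0 * noise_sd_scale, size=3)
            pha = rng.uniform(0, 2 * np.pi, size=3)
            wob = sum(amp[k] * np.cos(2 * np.pi * (k + 1) * phi + pha[k])
                      for k in range(3))
            wob = wob - wob[0] + 0.0  # keep cycles periodic
            cycles[i] = base + wob * np.sin(np.pi * phi) ** 2
        mean = cycles.mean(axis=0)
        sd = cycles.std(axis=0, ddof=1)
        mean[-1] = mean[0]
        sd[-1] = sd[0]
        if name.endswith("_emg"):
            mean = np.clip(mean, 0.0, 1.0)
        if name.startswith("grf") and name.endswith("vy"):
            mean = np.maximum(mean, 0.0)
        units = ("Nm" if name.endswith("_torque") else
                 "1" if name.endswith("_emg") else
                 "N" if name.startswith("grf") else
                 "m" if name.startswith("pelvis_t") and name[-1] in "xy" else "rad")
        signals[name] = {"mean": mean, "sd": sd, "units": units}

    # left side: right side shifted by half a cycle (grid must be even-split)
    half = (n_grid - 1) // 2
    for name in order:
        if name.endswith("_r") or "_r_" in name:
            lname = name.replace("_r_", "_l_") if "_r_" in name else name[:-2] + "_l"
            m = signals[name]["mean"][:-1]
            s = signals[name]["sd"][:-1]
            ml = np.roll(m, -half)
            sl = np.roll(s, -half)
            signals[lname] = {"mean": np.append(ml, ml[0]),
                              "sd": np.append(sl, sl[0]),
                              "units": signals[name]["units"]}
    # pelvis_tx must advance, not wrap: rebuild left-specific signals that are
    # not leg-local (none currently; tx/ty/tilt are shared mid-line signals).

    return ReferenceGait(grid=grid, signals=signals, speed=speed,
                         stance_fraction=stance_fraction,
                         cycle_duration=cycle_duration, seed=seed,
                         params={"body_mass": body_mass, "harmonics": harmonics,
                                 "noise_sd_scale": noise_sd_scale,
                                 "n_cycles": n_cycles}).validate()


def make_initial_population(model: ModelSpec, config, n: int, seed: int = 0,
                            scale: float = 0.01):
    """``n`` perturbed cold-start guesses for robustness testing.

    The first guess is the unperturbed cold start; subsequent guesses add
    uniform perturbations of relative size ``scale`` within bounds.
    Deterministic per (seed, n, scale).
    """
    from .ocp import GaitProblem
    from .guesses import cold_start, perturb_guess

    prob = GaitProblem(model, config)
    base = cold_start(prob)
    rng = np.random.default_rng(seed)
    out = [base]
    for _ in range(n - 1):
        out.append(perturb_guess(prob, base, rng, scale))
    return out
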
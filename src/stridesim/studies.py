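"""The three model-variation studies and their evaluation metrics.

Each study solves predictive gait simulations over a small condition grid
(toes free vs locked; mass/contact variants; triceps-surae tendon-stiffness
sweep) and reports cost of transport, stride length, first vertical-GRF peak
and stance RMSE metrics against a reference gait.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .contact import first_vertical_peak
from .metabolics import per_group_breakdown
from .model import ModelSpec, ModelVariant, apply_variant
from .ocp import GaitSolution, OCPConfig
from .solver import solve_gait

__all__ = ["StudyResult", "stance_mask", "rmse_stance", "delta_rmse_percent",
           "toe_study", "tendon_sweep", "mass_contact_study",
           "MUSCLE_GROUPS", "GAIT_GRID"]

#: Common evaluation grid: percent of gait cycle, 101 points.
GAIT_GRID = np.linspace(0.0, 100.0, 101)

STANCE_THRESHOLD_N = 20.0

MUSCLE_GROUPS = {
    "quadriceps": ["vasti", "rect_fem"],
    "hamstrings": ["hamstrings", "bifemsh"],
    "plantarflexors": ["gastroc", "soleus"],
    "hip": ["glut", "iliopsoas"],
    "dorsiflexors": ["tib_ant"],
}


@dataclass
class StudyResult:
    """Per-condition solutions plus a metric table."""

    name: str
    conditions: dict              # label -> GaitSolution
    metrics: dict                 # label -> {metric: value}
    comparisons: dict = field(default_factory=dict)

    def metric_table(self):
        import pandas as pd

        return pd.DataFrame(self.metrics).T


def stance_mask(vgrf, threshold: float = STANCE_THRESHOLD_N):
    """Boolean stance mask and stance fraction of a periodic vGRF series."""
    vgrf = np.asarray(vgrf, dtype=float)
    mask = vgrf > threshold
    frac = float(np.mean(mask[:-1])) if len(mask) > 1 else float(np.mean(mask))
    return mask, frac


def rmse_stance(sim_curve, ref_curve, mask):
    """RMSE between curves over the stance samples only."""
    sim_curve = np.asarray(sim_curve, dtype=float)
    ref_curve = np.asarray(ref_curve, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if sim_curve.shape != ref_curve.shape or mask.shape != sim_curve.shape:
        raise ValueError("curves and mask must share the 0-100% cycle grid")
    if not mask.any():
        raise ValueError("empty stance mask")
    d = sim_curve[mask] - ref_curve[mask]
    return float(np.sqrt(np.mean(d * d)))


def delta_rmse_percent(rmse_a, rmse_b, ref_curve, mask):
    """(rmse_b - rmse_a) as a percentage of the reference range during stance.

    Negative values mean condition b tracks the reference better.
    """
    ref_curve = np.asarray(ref_curve, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty stance mask")
    rng = float(np.ptp(ref_curve[mask]))
    if rng <= 0:
        raise ValueError("reference signal has zero range during stance")
    return 100.0 * (rmse_b - rmse_a) / rng


def _phase_align(vy):
    """Roll a periodic series so index 0 is the (right) foot strike."""
    vy = np.asarray(vy)
    loaded = vy > STANCE_THRESHOLD_N
    if loaded.all() or not loaded.any():
        return 0
    n = len(vy) - 1
    for i in range(n):
        if loaded[i] and not loaded[i - 1 if i else n - 1]:
            return i
    return 0


def solution_metrics(sol: GaitSolution, reference=None, n: int = 101):
    """Standard outcome metrics of one solution on the common gait grid."""
    grf = sol.grf_series(n)
    vy = grf["r"][:, 1]
    shift = _phase_align(vy)
    vy = np.roll(vy[:-1], -shift)
    vy = np.append(vy, vy[0])
    mask, frac = stance_mask(vy)
    stance = vy[mask]
    out = {
        "cot": sol.cot(),
        "stride_length": sol.stride_length,
        "cycle_duration": 2.0 * sol.t_f,
        "stance_fraction": frac,
        "first_vgrf_peak": first_vertical_peak(stance) if stance.size else 0.0,
        "objective": sol.objective,
        "status": sol.status,
    }
    if reference is not None:
        cyc = sol.full_cycle(n)
        q = np.roll(cyc["q"][:-1], -shift, axis=0)
        names = sol.problem.cm.coordinates
        for joint in ("knee_r", "ankle_r"):
            if joint in names and joint in reference.signals:
                sim = np.append(q[:, names.index(joint)], q[0, names.index(joint)])
                ref = reference.mean(joint)
                out[f"rmse_{joint}_deg"] = np.degrees(
                    rmse_stance(sim, ref, np.append(mask[:-1], mask[0])))
    return out


def _run_conditions(name, base_model: ModelSpec, variants: dict,
                    config: OCPConfig, reference=None, **solver_kwargs):
    conditions = {}
    metrics = {}
    for label, variant in variants.items():
        model = apply_variant(base_model, variant) if variant else base_model
        try:
            sol = solve_gait(model, config, reference=reference, **solver_kwargs)
            conditions[label] = sol
            metrics[label] = solution_metrics(sol, reference)
        except Exception as exc:
            metrics[label] = {"status": f"failed: {exc}"}
    return StudyResult(name=name, conditions=conditions, metrics=metrics)


def _group_map(model: ModelSpec):
    groups = {}
    for g, stems in MUSCLE_GROUPS.items():
        members = [m.name for m in model.muscles
                   if any(m.name.startswith(st) for st in stems)]
        if members:
            groups[g] = members
    return groups


def toe_study(model: ModelSpec, config: OCPConfig, reference=None,
              **solver_kwargs) -> StudyResult:
    """Toes free vs toes locked, with the per-group COT-increase breakdown."""
    if not model.mtp_coordinates():
        raise ValueError("model has no toe joints")
    result = _run_conditions(
        "toe_study", model,
        {"toes": None, "locked": ModelVariant(toes_locked=True)},
        config, reference, **solver_kwargs)
    if {"toes", "locked"} <= set(result.conditions):
        toes = result.conditions["toes"]
        locked = result.conditions["locked"]
        cot_t = result.metrics["toes"]["cot"]
        cot_l = result.metrics["locked"]["cot"]
        comp = {"delta_cot": cot_t - cot_l,
                "delta_cot_percent": 100.0 * (cot_t - cot_l) / cot_l}
        try:
            e_l = locked.metabolic_report()["muscle_energy"]
            e_t = toes.metabolic_report()["muscle_energy"]
            comp["group_shares_percent"] = per_group_breakdown(
                e_l, e_t, _group_map(model))
        except ValueError:
            pass
        result.comparisons = comp
    return result


def tendon_sweep(model: ModelSpec, config: OCPConfig,
                 fractions=(1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3),
                 reference=None, warm_start: bool = True,
                 bidirectional: bool = True, **solver_kwargs) -> StudyResult:
    """Achilles-tendon stiffness sweep over the triceps-surae muscles.

    Conditions are solved in the given (descending) order, each warm-started
    from its predecessor; with ``bidirectional`` a second ascending pass
    re-solves each fraction warm-started from below and the lower-cost
    solution is kept.  The two-pass protocol stabilizes the solution family
    in a common local basin, which single-pass warm starting does not
    guarantee with the penalty-based solver.
    """
    if not model.triceps_surae():
        raise ValueError("model has no triceps-surae muscles tagged")
    models = {f: apply_variant(model, ModelVariant(tendon_stiffness_fraction=f))
              for f in fractions}
    conditions = {}
    failures = {}
    prev = None
    order = list(fractions)
    passes = [order] + ([order[-2::-1]] if bidirectional and len(order) > 1 else [])
    for sweep_pass in passes:
        for frac in sweep_pass:
            try:
                guesses_list = None
                if warm_start and prev is not None:
                    guesses_list = [{"z": prev.z.copy(), "label": "warm"}]
                sol = solve_gait(models[frac], config, reference=reference,
                                 initial_guesses=guesses_list, **solver_kwargs)
                if (frac not in conditions
                        or (sol.success and sol.objective < conditions[frac].objective)):
                    conditions[frac] = sol
                prev = conditions[frac]
            except Exception as exc:
                failures[frac] = f"failed: {exc}"

    metrics = {}
    for frac in fractions:
        label = f"{int(round(100 * frac))}%"
        if frac not in conditions:
            metrics[label] = {"status": failures.get(frac, "failed"),
                              "stiffness_fraction": frac}
            continue
        sol = conditions[frac]
        row = solution_metrics(sol, reference)
        row["stiffness_fraction"] = frac
        try:  # reporting extras; never fail the study on them
            tri = [i for i, mm in enumerate(sol.problem.cm.muscles)
                   if "triceps_surae" in mm.tags]
            cyc = sol.full_cycle(101)
            row["triceps_mean_activation"] = float(np.mean(cyc["a"][:, tri]))
            row["triceps_mean_fiber_length"] = float(np.mean(
                sol.problem._physics(
                    cyc["q"], cyc["qd"], cyc["a"], cyc["ft"], cyc["e"],
                    cyc["dft"] * sol.problem.config.dft_scale,
                    cyc["ua"])["lm_tilde"][:, tri]))
        except Exception:
            pass
        metrics[label] = row
    return StudyResult(
        name="tendon_sweep",
        conditions={f"{int(round(100 * f))}%": s for f, s in conditions.items()},
        metrics=metrics)


def mass_contact_study(model: ModelSpec, config: OCPConfig,
                       torso_mass_delta: float = 7.4,
                       contact_offset: float = 0.01,
                       reference=None, **solver_kwargs) -> StudyResult:
    """Grid {heavy/light torso} x {low/high contact spheres}.

    The base model plays the 'new model with high spheres' role; the variants
    move mass back to the torso and the spheres down, mirroring the study's
    old/new comparison.
    """
    variants = {
        "light_torso+high_spheres": None,
        "heavy_torso+high_spheres": ModelVariant(torso_mass_delta=torso_mass_delta),
        "light_torso+low_spheres": ModelVariant(contact_vertical_offset=-contact_offset),
        "heavy_torso+low_spheres": ModelVariant(torso_mass_delta=torso_mass_delta,
                                                contact_vertical_offset=-contact_offset),
    }
    return _run_conditions("mass_contact_study", model, variants, config,
                           reference, **solver_kwargs)
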
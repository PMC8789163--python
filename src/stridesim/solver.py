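"""Nonlinear-program solution of the transcribed gait problem.

The equality-constrained sum-of-squares program is solved by an augmented
Lagrangian outer loop around a bound-constrained trust-region least-squares
inner solver (scipy's ``trf`` with sparse Jacobians from the transcription's
colored complex-step).  The multi-guess driver mirrors the study protocol:
solve from a cold and a hot start and keep the lower-cost solution.
"""

from __future__ import annotations

import logging
import time

import numpy as np
from scipy.optimize import least_squares

from . import guesses as _guesses
from .ocp import GaitProblem, GaitSolution, OCPConfig

__all__ = ["solve_transcribed", "solve_gait", "convergence_study"]

log = logging.getLogger("stridesim.solver")


def solve_transcribed(prob: GaitProblem, z0, tol: float | None = None,
                      mu0: float = 1e3, mu_max: float = 1e9,
                      max_outer: int = 18, inner_max_nfev: int = 100,
                      obj_rtol: float = 5e-3, lsmr_maxiter: int | None = None,
                      restarts: int = 1, restart_rtol: float = 1e-2,
                      time_limit: float | None = None):
    """Augmented-Lagrangian solve from one initial guess.

    Outer iterations continue past first feasibility until the objective is
    stationary between outers (``obj_rtol`` relative).  After convergence the
    cycle is optionally re-run warm-started from its own solution with a
    fresh multiplier schedule (``restarts`` times): once the penalty
    parameter has grown large the inner solver takes conservative steps, and
    a fresh cycle frequently finds a markedly better optimum in the same
    basin.  Returns a dict with the final (scaled) decision vector,
    convergence status, iteration count and feasibility (max scaled
    violation).
    """
    tol = prob.config.tol if tol is None else tol
    z = np.clip(np.asarray(z0, dtype=float), prob.z_lo, prob.z_hi)
    t0 = time.time()
    n_iter = 0
    best = None

    for cycle in range(restarts + 1):
        remaining = None
        if time_limit is not None:
            remaining = time_limit - (time.time() - t0)
            if best is not None and remaining < 10.0:
                break
        rep = _al_cycle(prob, z, tol, mu0, mu_max, max_outer, inner_max_nfev,
                        obj_rtol, lsmr_maxiter, remaining)
        n_iter += rep["iterations"]
        if best is None:
            best = rep
        elif (rep["feasibility"] <= tol
              and rep["objective"] < best["objective"] - restart_rtol * abs(best["objective"])):
            best = rep
        else:
            if rep["feasibility"] <= best["feasibility"] and \
                    rep["objective"] < best["objective"]:
                best = rep
            break
        z = best["z"]
        if best["feasibility"] > tol:
            break

    best["iterations"] = n_iter
    best["wall_time"] = time.time() - t0
    return best


def _al_cycle(prob, z, tol, mu0, mu_max, max_outer, inner_max_nfev,
              obj_rtol, lsmr_maxiter, time_limit):
    lam = np.zeros(prob.n_con)
    mu = mu0
    feas_prev = np.inf
    obj_prev = None
    n_iter = 0
    status = "max_outer_reached"
    t0 = time.time()

    for outer in range(max_outer):
        smu = np.sqrt(0.5 * mu)

        def fun(zz, smu=smu, lam=lam, mu=mu):
            obj, con = prob.residuals(zz)
            return np.concatenate([smu * (con + lam / mu), obj])

        def jac(zz, smu=smu):
            J = prob.jacobian(zz)
            J = J.copy()
            scale = np.ones(J.shape[0])
            scale[:prob.n_con] = smu
            J.data *= scale[J.indices]
            return J

        res = least_squares(fun, z, jac=jac, bounds=(prob.z_lo, prob.z_hi),
                            method="trf", tr_solver="lsmr", x_scale="jac",
                            tr_options=({"maxiter": lsmr_maxiter}
                                        if lsmr_maxiter else {}),
                            max_nfev=inner_max_nfev,
                            xtol=1e-12, ftol=1e-12, gtol=1e-12, verbose=0)
        z = res.x
        n_iter += res.njev
        _, con = prob.residuals(z)
        con = np.real(con)
        feas = float(np.max(np.abs(con)))
        obj = prob.objective(z)
        log.info("outer %d: feas=%.3e mu=%.1e obj=%.6f njev=%d",
                 outer, feas, mu, obj, res.njev)
        if feas <= tol:
            if obj_prev is not None and abs(obj - obj_prev) <= obj_rtol * max(abs(obj), 1e-6):
                status = "converged"
                break
            status = "feasible"
            obj_prev = obj
            lam = lam + mu * con  # keep polishing with multiplier updates
        else:
            obj_prev = None
            lam = lam + mu * con
            if feas > 0.3 * feas_prev:
                mu = min(mu * 10.0, mu_max)
        feas_prev = feas
        if time_limit is not None and time.time() - t0 > time_limit:
            status = "time_limit" if feas > tol else "converged"
            break

    if status == "feasible":  # feasible but objective still moving at cutoff
        status = "converged"
    return {"z": z, "status": status, "iterations": n_iter,
            "feasibility": float(np.max(np.abs(np.real(prob.residuals(z)[1])))),
            "objective": prob.objective(z),
            "wall_time": time.time() - t0}


def _as_solution(prob: GaitProblem, report: dict, label: str) -> GaitSolution:
    return GaitSolution(
        problem=prob, z=report["z"], status=report["status"],
        iterations=report["iterations"], feasibility=report["feasibility"],
        objective=report["objective"],
        objective_terms=prob.objective_terms(report["z"]),
        guess_label=label, config=prob.config.to_dict())


def solve_gait(model, config: OCPConfig, geometry: dict | None = None,
               reference=None, initial_guesses=None,
               **solver_kwargs) -> GaitSolution:
    """Multi-guess driver: solve from cold and/or hot starts, keep the best.

    ``initial_guesses`` (list of guess dicts with ``z`` and ``label``)
    overrides the configured guess strategy, e.g. for warm-started sweeps.
    Ties prefer the earlier guess (cold first).
    """
    prob = model if isinstance(model, GaitProblem) else GaitProblem(model, config, geometry)
    solver_kwargs = {**prob.config.solver, **solver_kwargs}
    if initial_guesses is None:
        mode = config.guess
        initial_guesses = []
        if mode in ("cold", "both"):
            initial_guesses.append(_guesses.cold_start(prob))
        if mode in ("hot", "both"):
            if reference is None:
                from .synth import make_reference_gait
                reference = make_reference_gait(seed=config.seed)
            initial_guesses.append(_guesses.hot_start(prob, reference))
        if not initial_guesses:
            raise ValueError(f"unknown guess mode {mode!r}")

    solutions = []
    for g in initial_guesses:
        log.info("solving from %s start", g["label"])
        rep = solve_transcribed(prob, g["z"], **solver_kwargs)
        solutions.append(_as_solution(prob, rep, g["label"]))

    feasible = [s for s in solutions if s.success]
    pool = feasible or solutions
    best = min(pool, key=lambda s: (round(s.objective, 12), pool.index(s)))
    best.alternatives = [s for s in solutions if s is not best]
    return best


def _trajectory_rms_percent(sol: GaitSolution, ref_sol: GaitSolution, n=101):
    """Mean over coordinates of RMS(q - q_ref) as % of the reference range."""
    a = sol.full_cycle(n)["q"]
    b = ref_sol.full_cycle(n)["q"]
    # compare phase-aligned coordinates; drop the absolute forward translation
    keep = [i for i in range(a.shape[1]) if i != sol.problem.itx]
    vals = []
    for i in keep:
        rng = np.ptp(b[:, i])
        if rng < 1e-9:
            continue
        vals.append(100.0 * np.sqrt(np.mean((a[:, i] - b[:, i]) ** 2)) / rng)
    return float(np.mean(vals))


def convergence_study(model, config: OCPConfig, meshes=(50, 75, 100, 125),
                      tols=(1e-4, 1e-5, 1e-6), guesses=("cold", "hot"),
                      reference=None, geometry=None, **solver_kwargs):
    """Mesh-density and tolerance sensitivity table.

    One row per (mesh, guess) and one per extra tolerance at the base mesh;
    trajectory RMS deltas are measured against the densest-mesh solution
    after resampling to a common gait-cycle grid.  Individual failures are
    recorded per row and do not abort the study.
    """
    import dataclasses as _dc

    rows = []
    solutions = {}
    for n_mesh in meshes:
        for guess in guesses:
            cfg = _dc.replace(config, n_mesh=n_mesh, guess=guess)
            try:
                sol = solve_gait(model, cfg, geometry=geometry,
                                 reference=reference, **solver_kwargs)
                solutions[(n_mesh, guess)] = sol
                rows.append({"sweep": "mesh", "n_mesh": n_mesh, "guess": guess,
                             "tol": cfg.tol, "status": sol.status,
                             "iterations": sol.iterations,
                             "objective": sol.objective})
            except Exception as exc:  # pragma: no cover - robustness path
                rows.append({"sweep": "mesh", "n_mesh": n_mesh, "guess": guess,
                             "tol": cfg.tol, "status": f"failed: {exc}",
                             "iterations": 0, "objective": np.nan})
    dens = [k for k in solutions if k[0] == max(meshes)]
    ref_sol = solutions[dens[0]] if dens else None
    for row in rows:
        key = (row["n_mesh"], row["guess"])
        if ref_sol is not None and key in solutions:
            row["rms_delta_pct"] = _trajectory_rms_percent(solutions[key], ref_sol)
        else:
            row["rms_delta_pct"] = np.nan

    base_mesh = meshes[0]
    tol_solutions = {}
    for tol in tols:
        cfg = _dc.replace(config, n_mesh=base_mesh, tol=tol, guess=guesses[0])
        try:
            sol = solve_gait(model, cfg, geometry=geometry, reference=reference,
                             **solver_kwargs)
            tol_solutions[tol] = sol
            rows.append({"sweep": "tolerance", "n_mesh": base_mesh,
                         "guess": guesses[0], "tol": tol, "status": sol.status,
                         "iterations": sol.iterations, "objective": sol.objective,
                         "rms_delta_pct": np.nan})
        except Exception as exc:  # pragma: no cover
            rows.append({"sweep": "tolerance", "n_mesh": base_mesh,
                         "guess": guesses[0], "tol": tol,
                         "status": f"failed: {exc}", "iterations": 0,
                         "objective": np.nan, "rms_delta_pct": np.nan})
    if len(tol_solutions) >= 2:
        ts = sorted(tol_solutions)  # ascending: tightest first
        tight, loose = tol_solutions[ts[0]], tol_solutions[ts[1]]
        delta = _trajectory_rms_percent(loose, tight)
        for row in rows:
            if row["sweep"] == "tolerance" and row["tol"] == ts[1]:
                row["rms_delta_pct"] = delta
    return {"rows": rows, "solutions": solutions, "tol_solutions": tol_solutions}
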
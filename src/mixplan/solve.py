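"""Drive a MILP solver on a built model and compute plan KPIs.

The solver backend is HiGHS via :func:`scipy.optimize.milp`.  Everything
reported downstream is recomputed from the integer admission matrix ``x``
alone — expected census, deviations (as positive parts of load minus
target) and the objective — so solver and model bookkeeping can be checked
against each other.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import milp

from .instance import PlanningInstance
from .los import census_matrix
from .model import MODEL_I, BuiltModel, ModelVariant, build_model

__all__ = [
    "SolverOptions",
    "AdmissionPlan",
    "KPIRecord",
    "solve",
    "solve_instance",
    "compute_kpis",
    "verify_plan",
]

log = logging.getLogger(__name__)

_STATUS = {0: "optimal", 1: "limit", 2: "infeasible", 3: "unbounded", 4: "limit"}


@dataclass(frozen=True)
class SolverOptions:
    """HiGHS settings.

    ``mip_rel_gap`` is the relative optimality gap at which the search
    stops (0 proves optimality).  With a gap-based stop and no time limit
    the solve is deterministic for fixed inputs (HiGHS runs single-threaded
    here); a time limit is a wall-clock backstop and makes the returned
    incumbent machine-dependent, which is flagged via ``status='limit'``.
    """

    mip_rel_gap: float = 0.0
    time_limit: Optional[float] = None
    seed: Optional[int] = None
    node_limit: Optional[int] = None

    def to_highs(self) -> dict:
        opts: dict = {"mip_rel_gap": float(self.mip_rel_gap)}
        if self.time_limit is not None:
            opts["time_limit"] = float(self.time_limit)
        if self.seed is not None:
            opts["random_seed"] = int(self.seed) % (2 ** 31)
        if self.node_limit is not None:
            opts["node_limit"] = int(self.node_limit)
        return opts


@dataclass
class AdmissionPlan:
    """Solver output for one instance/variant.

    ``x`` is the integer admission matrix (n_types, tau).  ``census``,
    ``dev_pos``/``dev_neg`` and ``objective`` are recomputed from ``x``
    (deviations as positive parts), not read off the solver; ``solver_objective``
    keeps the raw solver value for cross-checking.  ``status`` is one of
    ``optimal`` (proved within the requested gap), ``limit`` (search stopped
    early; ``x`` is the incumbent if one was found, else None),
    ``infeasible`` or ``unbounded``.
    """

    status: str
    x: Optional[np.ndarray]
    census: Optional[np.ndarray]
    dev_pos: Optional[np.ndarray]
    dev_neg: Optional[np.ndarray]
    objective: Optional[float]
    solver_objective: Optional[float]
    mip_gap: Optional[float]
    solve_seconds: float
    message: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        """Admissions as a (type x day) table, days 1-based."""
        if self.x is None:
            raise ValueError(f"no plan available (status={self.status})")
        return pd.DataFrame(self.x, columns=[f"day_{t + 1}" for t in range(self.x.shape[1])])


@dataclass
class KPIRecord:
    """Headline figures of a plan, all recomputed from the admissions x."""

    objective: float
    total_revenue: float
    deviation_cost_pos: dict[str, float]
    deviation_cost_neg: dict[str, float]
    total_admissions: int
    per_type_admissions: dict[str, int]
    proportions: Optional[dict[str, float]]   # None when no admissions
    average_priority: Optional[float]
    mean_utilization: dict[str, float]

    @property
    def deviation_cost_total(self) -> float:
        return sum(self.deviation_cost_pos.values()) + sum(self.deviation_cost_neg.values())

    def to_dict(self) -> dict:
        return {
            "objective": self.objective,
            "total_revenue": self.total_revenue,
            "deviation_cost_pos": self.deviation_cost_pos,
            "deviation_cost_neg": self.deviation_cost_neg,
            "total_admissions": self.total_admissions,
            "per_type_admissions": self.per_type_admissions,
            "proportions": self.proportions,
            "average_priority": self.average_priority,
            "mean_utilization": self.mean_utilization,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _loads_from_x(x: np.ndarray, inst: PlanningInstance) -> np.ndarray:
    """(3, tau) resource loads implied by an admission matrix."""
    M = census_matrix(x, inst.survivals())
    bed = M.sum(axis=0)
    exam = inst.exam_hours() @ x
    nursing = inst.nursing_hours() @ M
    return np.stack([bed, exam, nursing])


def evaluate_objective(x: np.ndarray, inst: PlanningInstance) -> float:
    """Objective value of an (integer) admission matrix, deviations as
    direct positive parts."""
    loads = _loads_from_x(x, inst)
    z = float(inst.revenues() @ x.sum(axis=1))
    for r, rs in enumerate(inst.resources):
        diff = loads[r] - rs.target
        z -= rs.cost_pos * np.clip(diff, 0, None).sum()
        z -= rs.cost_neg * np.clip(-diff, 0, None).sum()
    return z


def solve(model: BuiltModel, options: SolverOptions | None = None) -> AdmissionPlan:
    """Solve a built model and return the extracted plan.

    Solver failures surface in ``status``/``message``, never silently.
    """
    options = options or SolverOptions()
    t0 = time.perf_counter()
    with warnings.catch_warnings():
        # scipy warns about HiGHS-specific options it does not whitelist
        warnings.simplefilter("ignore", RuntimeWarning)
        res = milp(
            c=-model.objective,
            constraints=model.constraints,
            integrality=model.integrality,
            bounds=model.bounds,
            options=options.to_highs(),
        )
    elapsed = time.perf_counter() - t0
    status = _STATUS.get(res.status, "limit")
    gap = getattr(res, "mip_gap", None)
    if res.x is None:
        log.info("solve: status=%s message=%s time=%.2fs", status, res.message, elapsed)
        return AdmissionPlan(status=status, x=None, census=None, dev_pos=None,
                             dev_neg=None, objective=None, solver_objective=None,
                             mip_gap=gap, solve_seconds=elapsed, message=res.message)
    inst = model.instance
    x, _, _ = model.split(res.x)
    x = np.rint(x).astype(int)
    census = census_matrix(x, inst.survivals())
    loads = _loads_from_x(x, inst)
    TC = np.stack([rs.target for rs in inst.resources])
    dev_pos = np.clip(loads - TC, 0, None)
    dev_neg = np.clip(TC - loads, 0, None)
    objective = evaluate_objective(x, inst)
    log.info("solve: status=%s objective=%.4f gap=%s time=%.2fs",
             status, objective, gap, elapsed)
    return AdmissionPlan(status=status, x=x, census=census, dev_pos=dev_pos,
                         dev_neg=dev_neg, objective=objective,
                         solver_objective=-float(res.fun), mip_gap=gap,
                         solve_seconds=elapsed, message=res.message)


def solve_instance(inst: PlanningInstance, variant: ModelVariant = MODEL_I,
                   options: SolverOptions | None = None) -> AdmissionPlan:
    """Convenience wrapper: build and solve in one call."""
    return solve(build_model(inst, variant), options)


def compute_kpis(plan: AdmissionPlan, inst: PlanningInstance) -> KPIRecord:
    """Recompute every KPI from the admission matrix alone.

    The stored census/deviations on the plan are treated as caches; this
    derives them afresh so modeler/solver disagreements cannot hide.  With
    zero admissions the proportions and average priority are undefined and
    reported as ``None``.
    """
    if plan.x is None:
        raise ValueError(f"plan has no solution (status={plan.status})")
    x = plan.x
    ids = [pt.id for pt in inst.patient_types]
    per_type = x.sum(axis=1).astype(int)
    total = int(per_type.sum())
    revenue = float(inst.revenues() @ per_type)
    loads = _loads_from_x(x, inst)
    cost_pos, cost_neg, util = {}, {}, {}
    for r, rs in enumerate(inst.resources):
        diff = loads[r] - rs.target
        cost_pos[rs.id] = float(rs.cost_pos * np.clip(diff, 0, None).sum())
        cost_neg[rs.id] = float(rs.cost_neg * np.clip(-diff, 0, None).sum())
        util[rs.id] = float(np.mean(loads[r] / rs.available))
    objective = revenue - sum(cost_pos.values()) - sum(cost_neg.values())
    if total > 0:
        props = {tid: float(n) / total for tid, n in zip(ids, per_type)}
        avg_priority = float(inst.priority_scores() @ per_type) / total
    else:
        props, avg_priority = None, None
    return KPIRecord(
        objective=objective,
        total_revenue=revenue,
        deviation_cost_pos=cost_pos,
        deviation_cost_neg=cost_neg,
        total_admissions=total,
        per_type_admissions={tid: int(n) for tid, n in zip(ids, per_type)},
        proportions=props,
        average_priority=avg_priority,
        mean_utilization=util,
    )


def verify_plan(plan: AdmissionPlan, inst: PlanningInstance,
                variant: ModelVariant = MODEL_I, tol: float = 1e-6) -> list[str]:
    """Re-check every model constraint at the stored x by direct arithmetic.

    Returns a list of violated constraints (empty when the plan is feasible).
    Independent of the solver and of the matrix assembly in
    :mod:`mixplan.model`.
    """
    if plan.x is None:
        return [f"no plan (status={plan.status})"]
    x = plan.x
    out = []
    if np.any(x < 0) or np.any(np.abs(x - np.rint(x)) > tol):
        out.append("admissions not nonnegative integers")
    total = x.sum()
    if total > inst.admission_cap + tol:
        out.append("total admission cap exceeded")
    if variant.use_mix_bounds and total > 0:
        per = x.sum(axis=1)
        for pt, n in zip(inst.patient_types, per):
            if n > pt.mix_upper * total + tol:
                out.append(f"mix upper bound violated for type {pt.id}")
            if n < pt.mix_lower * total - tol:
                out.append(f"mix lower bound violated for type {pt.id}")
    if variant.use_priority_floor:
        per = x.sum(axis=1)
        if inst.priority_scores() @ per < inst.priority_floor * total - tol:
            out.append("priority floor violated")
    loads = _loads_from_x(x, inst)
    for r, rs in enumerate(inst.resources):
        if np.any(loads[r] > rs.available + tol):
            out.append(f"available capacity exceeded for resource {rs.id}")
    return out
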
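"""Construction of the admission-planning integer program.

Decision variables (planning cycle of tau days, n_types patient types,
three resources):

* ``x[i, t]`` — integer number of type-i patients admitted on day t;
* ``dev_pos[r, t]``, ``dev_neg[r, t]`` — continuous over/under-target
  deviations of resource r's load on day t.

Objective (maximized):

    sum_i sum_t revenue_i x[i,t]
      - sum_r sum_t cost_pos_r dev_pos[r,t]
      - sum_r sum_t cost_neg_r dev_neg[r,t]

Constraints: cycle-total admission cap; per-type mix share bounds on cycle
totals; admission-weighted average priority floor; hard daily capacity caps
on bed census, exam hours and nursing hours; and goal-programming linkage
``load[r,t] - target[r,t] = dev_pos[r,t] - dev_neg[r,t]`` with
``dev_pos, dev_neg >= 0``.  The linkage is the standard linearization of
the positive-part definitions ``dev_pos = [load - target]+`` and
``dev_neg = [target - load]+``; the two coincide at any optimum whenever
both unit costs are strictly positive (a zero or negative cost triggers a
warning, and results are reported as-is).

Resource loads are linear in x: the bed load is the total expected census
(cohort convolution with the LOS survival curves), the exam load is the
exam time of the day's admissions, and the nursing load weights the
expected census by per-type nursing hours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import Bounds, LinearConstraint

from .instance import PlanningInstance, validate_instance

__all__ = ["ModelVariant", "MODEL_I", "model_ii", "BuiltModel", "build_model", "write_lp"]


@dataclass(frozen=True)
class ModelVariant:
    """Which optional constraint families the model includes.

    The full formulation ("model I") enforces both the per-type mix-share
    bounds and the average-priority floor.  The relaxed comparison variant
    ("model II") drops the mix bounds; whether it keeps the priority floor
    is configurable, since a floor of 0 is non-binding either way.
    """

    name: str
    use_mix_bounds: bool
    use_priority_floor: bool


MODEL_I = ModelVariant("model_I", use_mix_bounds=True, use_priority_floor=True)


def model_ii(use_priority_floor: bool = False) -> ModelVariant:
    """The relaxation without per-type proportion constraints."""
    return ModelVariant("model_II", use_mix_bounds=False,
                        use_priority_floor=use_priority_floor)


@dataclass
class BuiltModel:
    """Matrix form of the admission-planning MILP (maximization).

    Variable layout: ``x[i, t]`` at index ``i * tau + t``; then
    ``dev_pos[r, t]`` at ``n_x + r * tau + t``; then ``dev_neg[r, t]`` at
    ``n_x + n_dev + r * tau + t``.
    """

    instance: PlanningInstance
    variant: ModelVariant
    objective: np.ndarray            # maximize objective @ z
    constraints: list[LinearConstraint]
    constraint_names: list[str]      # one per LinearConstraint block
    integrality: np.ndarray
    bounds: Bounds
    load_coeffs: np.ndarray          # (3, tau, n_vars) resource loads as rows over z

    @property
    def n_types(self) -> int:
        return self.instance.n_types

    @property
    def tau(self) -> int:
        return self.instance.horizon

    @property
    def n_admission_vars(self) -> int:
        return self.n_types * self.tau

    @property
    def n_deviation_vars(self) -> int:
        return 2 * len(self.instance.resources) * self.tau

    @property
    def n_vars(self) -> int:
        return self.n_admission_vars + self.n_deviation_vars

    def x_index(self, i: int, t: int) -> int:
        return i * self.tau + t

    def dev_index(self, r: int, t: int, positive: bool) -> int:
        off = self.n_admission_vars + (0 if positive else 3 * self.tau)
        return off + r * self.tau + t

    def split(self, z: np.ndarray):
        """Split a flat solution vector into (x, dev_pos, dev_neg) arrays."""
        nx, tau = self.n_admission_vars, self.tau
        x = z[:nx].reshape(self.n_types, tau)
        nd = 3 * tau
        return x, z[nx:nx + nd].reshape(3, tau), z[nx + nd:].reshape(3, tau)


def build_model(inst: PlanningInstance, variant: ModelVariant = MODEL_I) -> BuiltModel:
    """Assemble the MILP for ``inst`` under ``variant``.

    Raises ``ValueError`` if the instance fails validation.
    """
    bad = validate_instance(inst)
    if bad:
        raise ValueError("invalid instance: " + "; ".join(bad))

    nI, tau = inst.n_types, inst.horizon
    nx = nI * tau
    nd = 3 * tau
    nv = nx + 2 * nd
    S = inst.survivals()
    rev = inst.revenues()
    exam = inst.exam_hours()
    nurs = inst.nursing_hours()
    score = inst.priority_scores()
    alpha = inst.mix_lower()
    beta = inst.mix_upper()
    AC = np.stack([rs.available for rs in inst.resources])   # (3, tau)
    TC = np.stack([rs.target for rs in inst.resources])
    cpos = np.array([rs.cost_pos for rs in inst.resources])
    cneg = np.array([rs.cost_neg for rs in inst.resources])
    if np.any(cpos <= 0) or np.any(cneg <= 0):
        warnings.warn(
            "non-positive deviation cost: the deviation linearization is only "
            "equivalent to the positive-part definitions when both unit costs "
            "are strictly positive", stacklevel=2)

    obj = np.zeros(nv)
    for i in range(nI):
        obj[i * tau:(i + 1) * tau] = rev[i]
    for r in range(3):
        obj[nx + r * tau: nx + (r + 1) * tau] = -cpos[r]
        obj[nx + nd + r * tau: nx + nd + (r + 1) * tau] = -cneg[r]

    # census operator: census of type i on day t = sum_u S[i, t-u] x[i, u]
    census_rows = np.zeros((nI, tau, nv))
    for i in range(nI):
        for t in range(tau):
            census_rows[i, t, i * tau: i * tau + t + 1] = S[i, t::-1]

    # resource load rows over the full variable vector
    L = np.zeros((3, tau, nv))
    for t in range(tau):
        for i in range(nI):
            L[0, t] += census_rows[i, t]
            L[1, t, i * tau + t] = exam[i]
            L[2, t] += nurs[i] * census_rows[i, t]

    cons: list[LinearConstraint] = []
    names: list[str] = []

    a = np.zeros((1, nv)); a[0, :nx] = 1
    cons.append(LinearConstraint(a, -np.inf, inst.admission_cap))
    names.append("total_admission_cap")

    if variant.use_mix_bounds:
        for i in range(nI):
            up = np.zeros(nv)
            up[i * tau:(i + 1) * tau] = 1
            up[:nx] -= beta[i]
            cons.append(LinearConstraint(up, -np.inf, 0))
            names.append(f"mix_upper[{inst.patient_types[i].id}]")
            lo = np.zeros(nv)
            lo[i * tau:(i + 1) * tau] = 1
            lo[:nx] -= alpha[i]
            cons.append(LinearConstraint(lo, 0, np.inf))
            names.append(f"mix_lower[{inst.patient_types[i].id}]")

    if variant.use_priority_floor:
        pr = np.zeros(nv)
        for i in range(nI):
            pr[i * tau:(i + 1) * tau] = score[i] - inst.priority_floor
        cons.append(LinearConstraint(pr, 0, np.inf))
        names.append("priority_floor")

    # capacity cap and deviation linkage interleaved per resource: the row
    # order is mathematically irrelevant but strongly affects the HiGHS
    # branch-and-bound trajectory on this problem class (grouping all caps
    # before all linkages was observed to slow the solve by an order of
    # magnitude)
    for r, rs in enumerate(inst.resources):
        cons.append(LinearConstraint(L[r], -np.inf, AC[r]))
        names.append(f"capacity[{rs.id}]")
        link = L[r].copy()
        for t in range(tau):
            link[t, nx + r * tau + t] = -1
            link[t, nx + nd + r * tau + t] = 1
        cons.append(LinearConstraint(link, TC[r], TC[r]))
        names.append(f"deviation_link[{rs.id}]")

    integrality = np.zeros(nv)
    integrality[:nx] = 1

    lb = np.zeros(nv)
    ub = np.full(nv, np.inf)
    # admissions: per-day caps implied by the bed census (census >= same-day
    # admissions) and by exam time, plus the cycle-total cap
    for i in range(nI):
        cap = min(float(AC[0].min()), float(inst.admission_cap))
        if exam[i] > 0:
            cap = min(cap, float(AC[1].min()) / exam[i])
        ub[i * tau:(i + 1) * tau] = np.floor(cap)
    # presolve aid, valid at optima when both costs are positive: a load that
    # provably cannot exceed its target never needs a positive deviation, so
    # that variable is fixed at 0 (e.g. the nursing load is bounded by the
    # largest per-patient-day nursing demand times the bed cap).  Wider
    # deviation bounds are deliberately NOT imposed: they are harmless
    # mathematically but were observed to derail the branch-and-bound search.
    if np.all(cpos > 0) and np.all(cneg > 0):
        max_census = AC[0]                      # hard bed cap
        max_load = np.stack([
            max_census,
            np.minimum(AC[1], (exam * ub[:nx].reshape(nI, tau).T).sum(axis=1)),
            np.minimum(AC[2], (nurs.max() if nI else 0.0) * max_census),
        ])
        for r in range(3):
            fixable = max_load[r] <= TC[r]
            seg = ub[nx + r * tau: nx + (r + 1) * tau]
            seg[fixable] = 0.0

    return BuiltModel(
        instance=inst,
        variant=variant,
        objective=obj,
        constraints=cons,
        constraint_names=names,
        integrality=integrality,
        bounds=Bounds(lb, ub),
        load_coeffs=L,
    )


# ---------------------------------------------------------------------------
# LP file export
# ---------------------------------------------------------------------------

def _var_names(model: BuiltModel) -> list[str]:
    inst, tau = model.instance, model.tau
    names = []
    for pt in inst.patient_types:
        names += [f"x_{pt.id}_{t + 1}" for t in range(tau)]
    for sign in ("pos", "neg"):
        for rs in inst.resources:
            names += [f"dev_{sign}_{rs.id}_{t + 1}" for t in range(tau)]
    return names


def _expr(coefs: np.ndarray, names: list[str]) -> str:
    terms = []
    for c, n in zip(coefs, names):
        if c == 0:
            continue
        terms.append(f"{'+' if c >= 0 else '-'} {abs(c):.12g} {n}")
    if not terms:
        return "0"
    return " ".join(terms).lstrip("+ ")


def write_lp(model: BuiltModel, path) -> None:
    """Write the model in CPLEX LP format for inspection with any solver."""
    names = _var_names(model)
    lines = ["Maximize", f" obj: {_expr(model.objective, names)}", "Subject To"]
    k = 0
    for block, bname in zip(model.constraints, model.constraint_names):
        A = np.atleast_2d(block.A)
        lbs = np.atleast_1d(block.lb).astype(float)
        ubs = np.atleast_1d(block.ub).astype(float)
        if lbs.size == 1 and A.shape[0] > 1:
            lbs = np.full(A.shape[0], lbs[0])
            ubs = np.full(A.shape[0], ubs[0])
        for row, lo, hi in zip(A, lbs, ubs):
            expr = _expr(row, names)
            if lo == hi:
                lines.append(f" c{k}_{bname}: {expr} = {lo:.12g}")
            elif np.isfinite(hi) and not np.isfinite(lo):
                lines.append(f" c{k}_{bname}: {expr} <= {hi:.12g}")
            elif np.isfinite(lo) and not np.isfinite(hi):
                lines.append(f" c{k}_{bname}: {expr} >= {lo:.12g}")
            else:
                lines.append(f" c{k}_{bname}: {lo:.12g} <= {expr} <= {hi:.12g}")
            k += 1
    lines.append("Bounds")
    for j, n in enumerate(names):
        lo, hi = model.bounds.lb[j], model.bounds.ub[j]
        hi_s = "+inf" if not np.isfinite(hi) else f"{hi:.12g}"
        lines.append(f" {lo:.12g} <= {n} <= {hi_s}")
    lines.append("General")
    lines.append(" " + " ".join(n for j, n in enumerate(names) if model.integrality[j]))
    lines.append("End")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
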
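"""Synthetic instances and independent oracles.

Two cross-checks live here, deliberately independent of the optimization
code paths they validate:

* :func:`brute_force_optimum` — exhaustive enumeration of every integer
  admission plan of a tiny instance, evaluating deviations directly as
  positive parts ``[load - target]+`` / ``[target - load]+`` rather than
  through the goal-programming linearization the MILP uses;
* :func:`simulate_census` — Monte-Carlo discharge simulation sampling each
  patient's LOS from its pmf, against which the analytic expected-census
  convolution can be compared.

:func:`generate_instance` builds randomized but always-valid planning
instances (geometric-like truncated LOS curves, positive revenues/costs,
consistent mix bounds) as a pure function of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .instance import (LOSSurvival, PatientType, PlanningInstance,
                       ResourceSpec, RESOURCE_IDS)
from .los import LOSPmf

__all__ = ["SynthConfig", "generate_instance", "brute_force_optimum", "simulate_census"]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the random-instance generator.

    Defaults are oracle-sized (tiny horizons and capacities so the
    exhaustive search stays below ~10^6 candidate plans); raise ``horizon``
    and ``capacity_range`` for realistic instances.
    """

    seed: int
    n_types: int = 2
    horizon: int = 3
    capacity_range: tuple[float, float] = (1.0, 3.0)
    revenue_range: tuple[float, float] = (50.0, 200.0)
    cost_range: tuple[float, float] = (1.0, 40.0)
    discharge_prob_range: tuple[float, float] = (0.2, 0.8)
    priority_floor_rate: float = 0.3


def generate_instance(cfg: SynthConfig) -> PlanningInstance:
    """Generate a valid planning instance, deterministically from the seed."""
    if not (1 <= cfg.n_types <= 3):
        raise ValueError("n_types must be in 1..3")
    if cfg.horizon < 1:
        raise ValueError("horizon must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    tau = cfg.horizon

    # mix bounds: lower bounds sum below 1, uppers above their lowers
    if cfg.n_types == 1:
        alpha = np.array([0.0])
        beta = np.array([1.0])
    else:
        alpha = rng.uniform(0, 0.8 / cfg.n_types, cfg.n_types)
        beta = np.minimum(1.0, alpha + rng.uniform(0.15, 0.9, cfg.n_types))

    ptypes = []
    for i in range(cfg.n_types):
        p = rng.uniform(*cfg.discharge_prob_range)
        surv = (1 - p) ** np.arange(tau)
        ptypes.append(PatientType(
            id=f"T{i + 1}",
            revenue=float(rng.uniform(*cfg.revenue_range)),
            exam_hours=float(rng.uniform(0.0, 2.0)),
            nursing_hours=float(rng.uniform(0.0, 2.0)),
            priority_score=float(rng.uniform(0.0, 10.0)),
            mix_lower=float(alpha[i]),
            mix_upper=float(beta[i]),
            survival=LOSSurvival(tuple(np.round(surv, 6))),
        ))

    exam_scale = max(pt.exam_hours for pt in ptypes) + 0.5
    nurs_scale = max(pt.nursing_hours for pt in ptypes) + 0.5
    scales = {"bed": 1.0, "exam": exam_scale, "nursing": nurs_scale}
    res = []
    for rid in RESOURCE_IDS:
        ac = rng.uniform(*cfg.capacity_range) * scales[rid]
        tc = rng.uniform(0.4, 1.0) * ac
        res.append(ResourceSpec.constant(
            rid, ac, tc,
            cost_pos=float(rng.uniform(*cfg.cost_range)),
            cost_neg=float(rng.uniform(*cfg.cost_range)),
            horizon=tau))

    bed_ac = res[0].available.min()
    n_cap = int(rng.integers(0, max(1, math.floor(bed_ac)) * tau + 2))
    floor = 0.0
    if rng.random() < cfg.priority_floor_rate:
        scores = [pt.priority_score for pt in ptypes]
        floor = float(rng.uniform(min(scores), max(scores)))
    return PlanningInstance(
        patient_types=tuple(ptypes),
        resources=tuple(res),
        horizon=tau,
        admission_cap=n_cap,
        priority_floor=floor,
    )


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle
# ---------------------------------------------------------------------------

def brute_force_optimum(inst: PlanningInstance, max_candidates: int = 1_000_000,
                        use_mix_bounds: bool = True, use_priority_floor: bool = True,
                        tol: float = 1e-9):
    """Exact optimum of a tiny instance by full enumeration.

    Evaluates every integer admission matrix within the per-day caps,
    computing deviations directly as positive parts (no linearization) —
    an independent check of the MILP.  Returns ``(objective, x)``.

    Raises ``ValueError`` when the candidate count would exceed
    ``max_candidates``.
    """
    nI, tau = inst.n_types, inst.horizon
    exam = inst.exam_hours()
    AC = np.stack([rs.available for rs in inst.resources])
    TC = np.stack([rs.target for rs in inst.resources])
    n = inst.admission_cap

    dims = []
    for i in range(nI):
        cap = min(float(AC[0].min()), float(n))
        if exam[i] > 0:
            cap = min(cap, float(AC[1].min()) / exam[i])
        dims += [int(math.floor(cap + tol)) + 1] * tau
    total = math.prod(dims)
    if total > max_candidates:
        raise ValueError(
            f"search space of {total} candidate plans exceeds the enumeration "
            f"bound of {max_candidates}")

    S = inst.survivals()
    kern = np.zeros((nI, tau, tau))   # M[i] = kern[i] @ x[i]
    for i in range(nI):
        for t in range(tau):
            kern[i, t, : t + 1] = S[i, t::-1]
    rev = inst.revenues()
    nurs = inst.nursing_hours()
    alpha, beta = inst.mix_lower(), inst.mix_upper()
    score = inst.priority_scores()
    cpos = np.array([rs.cost_pos for rs in inst.resources])
    cneg = np.array([rs.cost_neg for rs in inst.resources])

    best_obj, best_x = -np.inf, None
    chunk = 200_000
    flat = np.arange(total)
    for start in range(0, total, chunk):
        idx = flat[start:start + chunk]
        x = np.stack(np.unravel_index(idx, dims)).T.reshape(-1, nI, tau).astype(float)
        per = x.sum(axis=2)
        N = per.sum(axis=1)
        feas = N <= n + tol
        if use_mix_bounds:
            feas &= np.all(per <= np.outer(N, beta) + tol, axis=1)
            feas &= np.all(per >= np.outer(N, alpha) - tol, axis=1)
        if use_priority_floor:
            feas &= per @ score >= inst.priority_floor * N - tol
        M = np.einsum("itu,ciu->cit", kern, x)
        loads = np.stack([M.sum(axis=1), np.einsum("i,cit->ct", exam, x),
                          np.einsum("i,cit->ct", nurs, M)], axis=1)
        feas &= np.all(loads <= AC[None, :, :] + tol, axis=(1, 2))
        diff = loads - TC[None, :, :]
        cost = (cpos[None, :] * np.clip(diff, 0, None).sum(axis=2)).sum(axis=1)
        cost += (cneg[None, :] * np.clip(-diff, 0, None).sum(axis=2)).sum(axis=1)
        obj = per @ rev - cost
        obj[~feas] = -np.inf
        k = int(np.argmax(obj))
        if obj[k] > best_obj:
            best_obj = float(obj[k])
            best_x = x[k].astype(int)
    return best_obj, best_x


# ---------------------------------------------------------------------------
# Monte-Carlo discharge simulation oracle
# ---------------------------------------------------------------------------

def simulate_census(x: np.ndarray, pmfs, reps: int, seed: int):
    """Empirical mean census from sampled discharges.

    Each admitted patient draws an LOS from its type's pmf; it occupies a
    bed from its admission day through ``admission + LOS - 1``, truncated
    at the horizon.  Any pmf mass beyond the stored horizon (``1 - sum``)
    is assigned to "still in hospital at the end of the cycle", mirroring
    the survival-curve truncation.

    Parameters
    ----------
    x : (n_types, tau) integer admissions
    pmfs : sequence of LOSPmf (or arrays of LOS probabilities for 1..tau)
    reps : number of independent replications
    seed : RNG seed

    Returns
    -------
    (mean, se) — two (n_types, tau) arrays: mean census per day and its
    standard error across replications.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    x = np.atleast_2d(np.asarray(x))
    nI, tau = x.shape
    rng = np.random.default_rng(seed)
    occ = np.zeros((reps, nI, tau))
    for i in range(nI):
        p = pmfs[i].as_array() if isinstance(pmfs[i], LOSPmf) else np.asarray(pmfs[i], float)
        p = p[:tau]
        resid = max(0.0, 1.0 - p.sum())
        p_ext = np.concatenate([p, [resid]])
        p_ext = p_ext / p_ext.sum()
        for u in range(tau):
            if x[i, u] <= 0:
                continue
            counts = rng.multinomial(int(x[i, u]), p_ext, size=reps)
            # suffix[:, k] = # of this cohort with LOS > k days
            # (the residual category stays through the horizon)
            suffix = counts[:, ::-1].cumsum(axis=1)[:, ::-1]
            span = tau - u
            # present on day u+k  <=>  LOS > k
            occ[:, i, u: u + span] += suffix[:, :span]
    mean = occ.mean(axis=0)
    se = occ.std(axis=0, ddof=1) / np.sqrt(reps) if reps > 1 else np.zeros_like(mean)
    return mean, se
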
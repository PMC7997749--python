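"""Scenario sweeps and model-variant comparisons.

A scenario is the base instance with a small set of parameter overrides —
unit nursing hours, mix-share bounds, the priority floor, or a uniform
target-utilization level — solved under a model variant.  Sweeps run an
ordered list of scenarios and collect KPIs into a table; packaged sweep
configurations under ``mixplan/data/sweeps`` reproduce the standard
sensitivity grids (nursing consumption, admission proportions, target
capacity) and the model I vs model II comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .instance import PlanningInstance, validate_instance
from .model import MODEL_I, ModelVariant, model_ii
from .solve import AdmissionPlan, KPIRecord, SolverOptions, compute_kpis, solve_instance

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "apply_overrides",
    "uniform_target_level",
    "run_sweep",
    "priority_floor_sweep",
    "compare_models",
    "load_sweep",
    "packaged_sweep",
    "results_to_frame",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScenarioSpec:
    """One sweep row: a label, parameter overrides and a model variant.

    Override keys are dotted paths into the instance:

    * ``patient_types.<id>.<field>`` — e.g. ``patient_types.II.nursing_hours``
    * ``resources.<id>.<field>`` — ``target``/``available`` accept a scalar
      (constant over days) or a per-day list
    * ``priority_floor``, ``admission_cap``, ``uniform_target_level``
      (sets every resource's target to the bed-target's utilization
      fraction of its own available capacity).
    """

    label: str
    overrides: Mapping[str, object] = field(default_factory=dict)
    variant: ModelVariant = MODEL_I


@dataclass
class ScenarioResult:
    label: str
    status: str
    kpis: Optional[KPIRecord]
    plan: Optional[AdmissionPlan]
    instance: Optional[PlanningInstance] = None


def _replace_patient_type(inst: PlanningInstance, type_id: str, **changes) -> PlanningInstance:
    pts = tuple(replace(pt, **changes) if pt.id == type_id else pt
                for pt in inst.patient_types)
    if not any(pt.id == type_id for pt in inst.patient_types):
        raise KeyError(f"no patient type {type_id!r}")
    return replace(inst, patient_types=pts)


def _replace_resource(inst: PlanningInstance, rid: str, **changes) -> PlanningInstance:
    for key in ("available", "target"):
        if key in changes and np.isscalar(changes[key]):
            changes[key] = np.full(inst.horizon, float(changes[key]))
    rs = tuple(replace(r, **changes) if r.id == rid else r for r in inst.resources)
    if not any(r.id == rid for r in inst.resources):
        raise KeyError(f"no resource {rid!r}")
    return replace(inst, resources=rs)


def uniform_target_level(inst: PlanningInstance, bed_target: float) -> PlanningInstance:
    """Set all resource targets to one utilization level.

    The level is the fraction ``bed_target / bed available capacity``; each
    resource's target becomes that fraction of its own available capacity,
    so the bed target equals ``bed_target`` exactly and exam/nursing targets
    are scaled proportionally.
    """
    bed = inst.resource("bed")
    frac = float(bed_target) / bed.available
    out = inst
    for rs in inst.resources:
        out = _replace_resource(out, rs.id, target=frac * rs.available)
    return out


def apply_overrides(inst: PlanningInstance, overrides: Mapping[str, object]) -> PlanningInstance:
    """Return a copy of ``inst`` with dotted-path overrides applied."""
    out = inst
    for path, value in overrides.items():
        parts = str(path).split(".")
        if parts[0] == "patient_types" and len(parts) == 3:
            out = _replace_patient_type(out, parts[1], **{parts[2]: value})
        elif parts[0] == "resources" and len(parts) == 3:
            out = _replace_resource(out, parts[1], **{parts[2]: value})
        elif path == "priority_floor":
            out = replace(out, priority_floor=float(value))
        elif path == "admission_cap":
            out = replace(out, admission_cap=int(value))
        elif path == "uniform_target_level":
            out = uniform_target_level(out, float(value))
        else:
            raise KeyError(f"unknown override path {path!r}")
    return out


def run_sweep(base: PlanningInstance, specs: Sequence[ScenarioSpec],
              options: SolverOptions | None = None) -> list[ScenarioResult]:
    """Solve every scenario in order; failures are recorded, never raised.

    A scenario whose overridden instance fails validation is returned with
    status ``invalid``; solver non-success is carried through in the result
    status.  Results preserve input order.
    """
    results = []
    for spec in specs:
        try:
            inst = apply_overrides(base, spec.overrides)
        except KeyError as exc:
            results.append(ScenarioResult(spec.label, f"invalid ({exc})", None, None))
            continue
        bad = validate_instance(inst)
        if bad:
            log.warning("scenario %s invalid: %s", spec.label, "; ".join(bad))
            results.append(ScenarioResult(spec.label, "invalid", None, None, inst))
            continue
        plan = solve_instance(inst, spec.variant, options)
        kpis = compute_kpis(plan, inst) if plan.x is not None else None
        results.append(ScenarioResult(spec.label, plan.status, kpis, plan, inst))
    return results


def priority_floor_sweep(inst: PlanningInstance, floors: Sequence[float],
                         options: SolverOptions | None = None) -> list[ScenarioResult]:
    """Sweep the average-priority floor with mix-share bounds removed.

    Each run keeps constraint set of the relaxed variant plus the priority
    floor at the given level, isolating the effect of the floor on the mix.
    """
    variant = ModelVariant("priority_only", use_mix_bounds=False, use_priority_floor=True)
    specs = [ScenarioSpec(label=f"Lp={fl:g}", overrides={"priority_floor": float(fl)},
                          variant=variant)
             for fl in floors]
    return run_sweep(inst, specs, options)


def compare_models(inst: PlanningInstance,
                   mix_scenarios: Sequence[Mapping[str, tuple[float, float]]],
                   options: SolverOptions | None = None,
                   model_ii_priority_floor: bool = False) -> pd.DataFrame:
    """Model I under each mix-bound scenario vs model II once.

    ``mix_scenarios`` maps patient-type id to ``(mix_lower, mix_upper)``.
    Returns a table with revenue/objective, admissions and proportions per
    row; the relaxed model II (no mix bounds) is solved on the unmodified
    instance and appended as the final row.
    """
    specs = []
    for k, scen in enumerate(mix_scenarios, start=1):
        ov = {}
        for tid, (lo, hi) in scen.items():
            ov[f"patient_types.{tid}.mix_lower"] = lo
            ov[f"patient_types.{tid}.mix_upper"] = hi
        specs.append(ScenarioSpec(label=f"model_I/scenario {k}", overrides=ov, variant=MODEL_I))
    specs.append(ScenarioSpec(label="model_II",
                              variant=model_ii(model_ii_priority_floor)))
    return results_to_frame(run_sweep(inst, specs, options))


# ---------------------------------------------------------------------------
# sweep configuration files
# ---------------------------------------------------------------------------

def load_sweep(path: str | Path) -> list[ScenarioSpec]:
    """Load an ordered scenario list from a sweep YAML document."""
    doc = yaml.safe_load(Path(path).read_text())
    variants = {
        "model_I": MODEL_I,
        "model_II": model_ii(),
    }
    default_variant = variants[doc.get("variant", "model_I")]
    specs = []
    for sd in doc["scenarios"]:
        variant = variants[sd["variant"]] if "variant" in sd else default_variant
        specs.append(ScenarioSpec(label=str(sd["label"]),
                                  overrides=sd.get("overrides", {}),
                                  variant=variant))
    return specs


def packaged_sweep(name: str) -> list[ScenarioSpec]:
    """Load one of the packaged sweep configs: ``nursing``, ``mix``,
    ``target`` or ``compare``."""
    ref = resources.files("mixplan").joinpath(f"data/sweeps/{name}.yaml")
    with resources.as_file(ref) as path:
        return load_sweep(path)


def results_to_frame(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Flatten sweep results into a table (revenue/proportions at 2 decimals
    only in the formatted columns; raw values are kept alongside)."""
    rows = []
    for res in results:
        row: dict = {"label": res.label, "status": res.status}
        if res.kpis is not None:
            k = res.kpis
            row.update({
                "objective": k.objective,
                "total_revenue": k.total_revenue,
                "admissions": k.total_admissions,
                "average_priority": k.average_priority,
            })
            for tid, n in k.per_type_admissions.items():
                row[f"admitted_{tid}"] = n
            if k.proportions:
                for tid, p in k.proportions.items():
                    row[f"share_{tid}_pct"] = round(100 * p, 2)
        rows.append(row)
    return pd.DataFrame(rows)
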
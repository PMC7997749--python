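"""Domain types for the admission-planning problem and instance file I/O.

A planning instance describes a hospital department that admits several
types of elective patients over a finite planning cycle (default 28 days).
Each patient type carries a per-admission revenue, an exam-time demand on
the admission day, a daily nursing demand while in hospital, a priority
score, bounds on its share of total admissions, and a discrete
length-of-stay (LOS) distribution given as a survival curve.  Three
resources constrain the plan: beds (occupied according to expected census),
medical-exam hours (consumed on admission) and nursing hours (consumed per
in-hospital patient-day).  Each resource has a hard daily available
capacity and a soft daily target; deviations from the target are penalized
in the objective (goal programming).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "LOSSurvival",
    "PatientType",
    "ResourceSpec",
    "PlanningInstance",
    "RESOURCE_IDS",
    "validate_instance",
    "base_instance",
    "read_instance",
    "write_instance",
]

#: canonical resource order: beds, medical-exam hours, nursing hours
RESOURCE_IDS = ("bed", "exam", "nursing")

_EPS = 1e-9


@dataclass(frozen=True)
class LOSSurvival:
    """Discrete LOS survival curve.

    ``values[s]`` is the probability that a patient is still in hospital
    more than ``s`` days after admission, for ``s = 0 .. horizon-1``.  A
    valid curve starts at 1 (everyone stays at least part of the admission
    day), is nonincreasing and lies in [0, 1].  Stays are truncated at the
    horizon: survival beyond the last stored day is taken as 0.
    """

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    @property
    def horizon(self) -> int:
        return len(self.values)

    def __getitem__(self, s: int) -> float:
        return self.values[s]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def violations(self, label: str = "survival") -> list[str]:
        out = []
        v = self.as_array()
        if v.size == 0:
            return [f"{label} is empty"]
        if abs(v[0] - 1.0) > _EPS:
            out.append(f"{label} does not start at 1 (got {v[0]})")
        if np.any(v < -_EPS) or np.any(v > 1 + _EPS):
            out.append(f"{label} has values outside [0, 1]")
        if np.any(np.diff(v) > _EPS):
            out.append(f"{label} not nonincreasing")
        return out


@dataclass(frozen=True)
class PatientType:
    """One elective patient class.

    Parameters
    ----------
    id : str
        Type label (e.g. "I", "II", "III").
    revenue : float
        Revenue per admitted patient (money units).  Strictly positive.
    exam_hours : float
        Medical-exam hours consumed on the admission day.
    nursing_hours : float
        Nursing hours per in-hospital patient-day.
    priority_score : float
        Dimensionless admission-worthiness score; larger = higher priority.
    mix_lower, mix_upper : float
        Lower/upper bound on this type's share of total cycle admissions.
    survival : LOSSurvival
        LOS survival curve driving the expected census.
    """

    id: str
    revenue: float
    exam_hours: float
    nursing_hours: float
    priority_score: float
    mix_lower: float
    mix_upper: float
    survival: LOSSurvival

    def violations(self) -> list[str]:
        out = []
        p = f"patient type {self.id}:"
        if not self.revenue > 0:
            out.append(f"{p} revenue must be > 0")
        if self.exam_hours < 0:
            out.append(f"{p} exam hours must be >= 0")
        if self.nursing_hours < 0:
            out.append(f"{p} nursing hours must be >= 0")
        if self.priority_score < 0:
            out.append(f"{p} priority score must be >= 0")
        if not (0 <= self.mix_lower <= self.mix_upper <= 1):
            out.append(f"{p} mix bounds must satisfy 0 <= lower <= upper <= 1")
        out.extend(self.survival.violations(f"{p} survival"))
        return out


@dataclass(frozen=True, eq=False)
class ResourceSpec:
    """Daily capacities and deviation costs for one resource.

    ``available`` and ``target`` are per-day vectors (length = horizon);
    scalar input is broadcast.  ``cost_pos`` is the unit cost of exceeding
    the target (overuse), ``cost_neg`` the unit cost of falling short of it
    (idle capacity).  Units: beds for the bed resource, hours otherwise.
    """

    id: str
    available: np.ndarray
    target: np.ndarray
    cost_pos: float
    cost_neg: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "available", np.atleast_1d(np.asarray(self.available, dtype=float)))
        object.__setattr__(self, "target", np.atleast_1d(np.asarray(self.target, dtype=float)))

    def __eq__(self, other) -> bool:
        if not isinstance(other, ResourceSpec):
            return NotImplemented
        return (self.id == other.id
                and np.array_equal(self.available, other.available)
                and np.array_equal(self.target, other.target)
                and self.cost_pos == other.cost_pos
                and self.cost_neg == other.cost_neg)

    @classmethod
    def constant(cls, id: str, available: float, target: float,
                 cost_pos: float, cost_neg: float, horizon: int) -> "ResourceSpec":
        return cls(id, np.full(horizon, float(available)), np.full(horizon, float(target)),
                   cost_pos, cost_neg)

    def violations(self, horizon: int | None = None) -> list[str]:
        out = []
        p = f"resource {self.id}:"
        if self.available.shape != self.target.shape:
            out.append(f"{p} available/target length mismatch")
            return out
        if horizon is not None and len(self.available) != horizon:
            out.append(f"{p} capacity vectors must have length {horizon}")
        if np.any(self.target < -_EPS):
            out.append(f"{p} target capacity must be >= 0")
        if np.any(self.target > self.available + _EPS):
            out.append(f"{p} target capacity exceeds available capacity")
        if self.cost_pos < 0:
            out.append(f"{p} positive deviation cost must be >= 0")
        if self.cost_neg < 0:
            out.append(f"{p} negative deviation cost must be >= 0")
        return out


@dataclass(frozen=True)
class PlanningInstance:
    """A complete admission-planning problem.

    ``resources`` must contain exactly the three canonical resources in
    :data:`RESOURCE_IDS` order.  ``admission_cap`` is the cycle-total
    admission cap n; ``priority_floor`` is the minimum admission-weighted
    average priority score L^p (0 = non-binding).
    """

    patient_types: tuple[PatientType, ...]
    resources: tuple[ResourceSpec, ...]
    horizon: int
    admission_cap: int
    priority_floor: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "patient_types", tuple(self.patient_types))
        object.__setattr__(self, "resources", tuple(self.resources))

    # -- convenience accessors -------------------------------------------------
    @property
    def n_types(self) -> int:
        return len(self.patient_types)

    def patient_type(self, type_id: str) -> PatientType:
        for pt in self.patient_types:
            if pt.id == type_id:
                return pt
        raise KeyError(f"no patient type {type_id!r}")

    def resource(self, resource_id: str) -> ResourceSpec:
        for rs in self.resources:
            if rs.id == resource_id:
                return rs
        raise KeyError(f"no resource {resource_id!r}")

    def survivals(self) -> np.ndarray:
        """(n_types, horizon) array of survival values, truncated/padded with 0."""
        out = np.zeros((self.n_types, self.horizon))
        for i, pt in enumerate(self.patient_types):
            v = pt.survival.as_array()[: self.horizon]
            out[i, : len(v)] = v
        return out

    def revenues(self) -> np.ndarray:
        return np.array([pt.revenue for pt in self.patient_types])

    def exam_hours(self) -> np.ndarray:
        return np.array([pt.exam_hours for pt in self.patient_types])

    def nursing_hours(self) -> np.ndarray:
        return np.array([pt.nursing_hours for pt in self.patient_types])

    def priority_scores(self) -> np.ndarray:
        return np.array([pt.priority_score for pt in self.patient_types])

    def mix_lower(self) -> np.ndarray:
        return np.array([pt.mix_lower for pt in self.patient_types])

    def mix_upper(self) -> np.ndarray:
        return np.array([pt.mix_upper for pt in self.patient_types])


def validate_instance(inst: PlanningInstance) -> list[str]:
    """Return one entry per violated invariant; empty list iff valid."""
    out: list[str] = []
    if inst.horizon < 1:
        out.append("horizon must be >= 1")
    if inst.admission_cap < 0:
        out.append("admission cap must be >= 0")
    if not inst.patient_types:
        out.append("no patient types")
    seen = set()
    for pt in inst.patient_types:
        if pt.id in seen:
            out.append(f"duplicate patient type id {pt.id!r}")
        seen.add(pt.id)
        out.extend(pt.violations())
        if pt.survival.horizon < inst.horizon:
            out.append(f"patient type {pt.id}: survival curve shorter than horizon")
    rids = tuple(rs.id for rs in inst.resources)
    if rids != RESOURCE_IDS:
        out.append(f"resources must be exactly {RESOURCE_IDS} in order, got {rids}")
    for rs in inst.resources:
        out.extend(rs.violations(inst.horizon))
    if sum(pt.mix_lower for pt in inst.patient_types) > 1 + _EPS:
        out.append("mix lower bounds sum > 1")
    return out


# ---------------------------------------------------------------------------
# packaged base instance
# ---------------------------------------------------------------------------

def base_instance() -> PlanningInstance:
    """The packaged reference instance: a 290-bed respiratory department.

    Three patient types ordered by priority, a 28-day cycle, and capacities
    with 30% reserved for emergency admissions already removed (hence 203 of
    the 290 beds are plannable).  Targets sit at roughly 90% of available
    capacity; both deviation costs are shared across resources (20 per unit
    of overuse, 30 per idle unit).
    """
    ref = resources.files("mixplan").joinpath("data/base_instance.yaml")
    with resources.as_file(ref) as path:
        return read_instance(path)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _read_survival_csv(text: str) -> dict[str, list[float]]:
    """Parse a survival CSV with columns ``s,<type id>,...`` (one row per s)."""
    rows = list(csv.reader(io.StringIO(text)))
    header = rows[0]
    if header[0].strip().lower() != "s":
        raise ValueError("survival CSV must have first column 's'")
    ids = [h.strip() for h in header[1:]]
    curves: dict[str, list[float]] = {tid: [] for tid in ids}
    expect = 0
    for row in rows[1:]:
        if not row or not row[0].strip():
            continue
        if int(row[0]) != expect:
            raise ValueError(f"survival CSV rows must be s=0,1,2,...; got {row[0]}")
        expect += 1
        for tid, val in zip(ids, row[1:]):
            curves[tid].append(float(val))
    return curves


def read_instance(path: str | Path) -> PlanningInstance:
    """Read a planning instance from a YAML document.

    LOS survival curves may be inline (``survival:`` list per type) or in a
    sibling CSV referenced by a top-level ``survival_csv`` key with columns
    ``s`` then one column per type id.
    """
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    horizon = int(doc["horizon"])
    curves: dict[str, list[float]] = {}
    if "survival_csv" in doc:
        csv_path = path.parent / doc["survival_csv"]
        curves = _read_survival_csv(csv_path.read_text())
    ptypes = []
    for td in doc["patient_types"]:
        tid = str(td["id"])
        if "survival" in td:
            vals = [float(v) for v in td["survival"]]
        elif tid in curves:
            vals = curves[tid]
        else:
            raise ValueError(f"no survival curve for patient type {tid!r}")
        # pad with zeros up to the horizon (stays truncated at cycle end)
        if len(vals) < horizon:
            vals = vals + [0.0] * (horizon - len(vals))
        ptypes.append(PatientType(
            id=tid,
            revenue=float(td["revenue"]),
            exam_hours=float(td["exam_hours"]),
            nursing_hours=float(td["nursing_hours"]),
            priority_score=float(td["priority_score"]),
            mix_lower=float(td["mix_lower"]),
            mix_upper=float(td["mix_upper"]),
            survival=LOSSurvival(tuple(vals)),
        ))
    res = []
    for rd in doc["resources"]:
        avail = rd["available"]
        target = rd["target"]
        avail = np.full(horizon, float(avail)) if np.isscalar(avail) else np.asarray(avail, float)
        target = np.full(horizon, float(target)) if np.isscalar(target) else np.asarray(target, float)
        res.append(ResourceSpec(str(rd["id"]), avail, target,
                                float(rd["cost_pos"]), float(rd["cost_neg"])))
    order = {rid: k for k, rid in enumerate(RESOURCE_IDS)}
    res.sort(key=lambda r: order.get(r.id, 99))
    return PlanningInstance(
        patient_types=tuple(ptypes),
        resources=tuple(res),
        horizon=horizon,
        admission_cap=int(doc.get("admission_cap", horizon * int(res[0].available.max()))),
        priority_floor=float(doc.get("priority_floor", 0.0)),
    )


def _compact(vec: np.ndarray):
    """Write a constant per-day vector as a scalar, else as a list."""
    if np.all(vec == vec[0]):
        return float(vec[0])
    return [float(v) for v in vec]


def write_instance(inst: PlanningInstance, path: str | Path,
                   survival_csv: str | None = None) -> None:
    """Write ``inst`` as YAML; optionally put survival curves in a CSV.

    Probabilities are written at full precision so that a read/write
    round-trip reproduces the instance exactly.
    """
    path = Path(path)
    doc: dict = {
        "horizon": inst.horizon,
        "admission_cap": inst.admission_cap,
        "priority_floor": inst.priority_floor,
        "patient_types": [],
        "resources": [],
    }
    for pt in inst.patient_types:
        td = {
            "id": pt.id,
            "revenue": pt.revenue,
            "exam_hours": pt.exam_hours,
            "nursing_hours": pt.nursing_hours,
            "priority_score": pt.priority_score,
            "mix_lower": pt.mix_lower,
            "mix_upper": pt.mix_upper,
        }
        if survival_csv is None:
            td["survival"] = [float(v) for v in pt.survival.values]
        doc["patient_types"].append(td)
    if survival_csv is not None:
        doc["survival_csv"] = survival_csv
        hmax = max(pt.survival.horizon for pt in inst.patient_types)
        with open(path.parent / survival_csv, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["s"] + [pt.id for pt in inst.patient_types])
            for s in range(hmax):
                w.writerow([s] + [repr(pt.survival.values[s]) if s < pt.survival.horizon else "0.0"
                                  for pt in inst.patient_types])
    for rs in inst.resources:
        doc["resources"].append({
            "id": rs.id,
            "available": _compact(rs.available),
            "target": _compact(rs.target),
            "cost_pos": rs.cost_pos,
            "cost_neg": rs.cost_neg,
        })
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
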
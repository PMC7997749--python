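import pytest

import mixplan as mp


@pytest.fixture(scope="session")
def base():
    return mp.base_instance()


@pytest.fixture(scope="session")
def solver_options():
    # 1% relative gap: the 28-day instance has a structurally weak LP bound,
    # so proving exact optimality is disproportionately slow; at this gap the
    # incumbent plan is stable and the solve takes tens of seconds.  The time
    # limit is a backstop for scenarios with a long branch-and-bound tail —
    # their incumbent plan settles well before it triggers.
    return mp.SolverOptions(mip_rel_gap=0.01, time_limit=150)


@pytest.fixture(scope="session")
def base_plan(base, solver_options):
    plan = mp.solve_instance(base, mp.MODEL_I, solver_options)
    assert plan.x is not None
    return plan


def toy_instance(revenue=10.0, bed_cap=1.0, bed_target=1.0, tau=2,
                 cost_pos=0.0, cost_neg=0.0, exam_cap=100.0, nursing_cap=100.0):
    """Single type, LOS exactly 1 day: bed holds one patient per day."""
    surv = mp.LOSSurvival((1.0,) + (0.0,) * (tau - 1))
    pt = mp.PatientType(id="A", revenue=revenue, exam_hours=0.0, nursing_hours=0.0,
                        priority_score=1.0, mix_lower=0.0, mix_upper=1.0, survival=surv)
    res = (
        mp.ResourceSpec.constant("bed", bed_cap, bed_target, cost_pos, cost_neg, tau),
        mp.ResourceSpec.constant("exam", exam_cap, 0.0, cost_pos, cost_neg, tau),
        mp.ResourceSpec.constant("nursing", nursing_cap, 0.0, cost_pos, cost_neg, tau),
    )
    return mp.PlanningInstance(patient_types=(pt,), resources=res, horizon=tau,
                               admission_cap=100)
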
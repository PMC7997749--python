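"""Scenario overrides, sweeps and the model-variant comparison.

Sweep mechanics are exercised on tiny synthetic instances (exact solves in
milliseconds); the full 28-day reference instance is reserved for the
acceptance suite.
"""

import numpy as np
import pytest

import mixplan as mp
from mixplan.scenarios import ScenarioSpec, apply_overrides, uniform_target_level
from mixplan.synth import SynthConfig


@pytest.fixture(scope="module")
def tiny():
    # seed chosen only for a non-degenerate admission cap
    for seed in range(100):
        inst = mp.generate_instance(SynthConfig(seed=seed, n_types=2, horizon=3))
        if inst.admission_cap >= 2 and inst.priority_floor == 0:
            return inst
    raise AssertionError("no suitable tiny instance found")


EXACT = mp.SolverOptions(mip_rel_gap=0.0)


def test_apply_overrides_paths(base):
    out = apply_overrides(base, {
        "patient_types.II.nursing_hours": 1.25,
        "resources.bed.target": 185,
        "priority_floor": 3.0,
    })
    assert out.patient_type("II").nursing_hours == 1.25
    assert np.all(out.resource("bed").target == 185.0)
    assert out.priority_floor == 3.0
    # base untouched
    assert base.patient_type("II").nursing_hours == 1.0


def test_apply_overrides_unknown_path(base):
    with pytest.raises(KeyError):
        apply_overrides(base, {"resources.icu.target": 1})


def test_uniform_target_level(base):
    out = uniform_target_level(base, 185.0)
    frac = 185.0 / 203.0
    assert out.resource("bed").target[0] == pytest.approx(185.0)
    assert out.resource("exam").target[0] == pytest.approx(frac * 201.6)
    assert out.resource("nursing").target[0] == pytest.approx(frac * 561.0)


def test_noop_sweep_equals_direct_solve(tiny):
    direct = mp.solve_instance(tiny, mp.MODEL_I, EXACT)
    results = mp.run_sweep(tiny, [ScenarioSpec(label="base")], EXACT)
    assert len(results) == 1
    assert results[0].status == "optimal"
    assert results[0].kpis.objective == pytest.approx(direct.objective)
    assert results[0].kpis.total_admissions == int(direct.x.sum())


def test_sweep_records_invalid_scenario_and_preserves_order(tiny):
    specs = [
        ScenarioSpec(label="ok"),
        ScenarioSpec(label="broken", overrides={"patient_types.T1.mix_lower": 2.0}),
        ScenarioSpec(label="ok2"),
    ]
    results = mp.run_sweep(tiny, specs, EXACT)
    assert [r.label for r in results] == ["ok", "broken", "ok2"]
    assert results[1].status == "invalid"
    assert results[0].status == "optimal" and results[2].status == "optimal"


def test_sweep_determinism(tiny):
    specs = [ScenarioSpec(label="a", overrides={"priority_floor": 0.0})]
    r1 = mp.run_sweep(tiny, specs, EXACT)
    r2 = mp.run_sweep(tiny, specs, EXACT)
    assert r1[0].kpis.objective == r2[0].kpis.objective
    np.testing.assert_array_equal(r1[0].plan.x, r2[0].plan.x)


def test_model_ii_is_a_relaxation(tiny):
    z1 = mp.solve_instance(tiny, mp.MODEL_I, EXACT).objective
    z2 = mp.solve_instance(tiny, mp.model_ii(), EXACT).objective
    assert z2 >= z1 - 1e-9


def test_mix_upper_relaxation_monotonicity(tiny):
    z = mp.solve_instance(tiny, mp.MODEL_I, EXACT).objective
    wider = apply_overrides(tiny, {
        f"patient_types.{tiny.patient_types[0].id}.mix_upper":
            min(1.0, tiny.patient_types[0].mix_upper + 0.2)})
    z_wide = mp.solve_instance(wider, mp.MODEL_I, EXACT).objective
    assert z_wide >= z - 1e-9


def test_priority_floor_sweep_monotone(tiny):
    scores = sorted(pt.priority_score for pt in tiny.patient_types)
    floors = [0.0, scores[0], np.mean(scores), scores[-1]]
    results = mp.priority_floor_sweep(tiny, floors, EXACT)
    objs = [r.kpis.objective for r in results]
    assert all(a >= b - 1e-9 for a, b in zip(objs, objs[1:]))


def test_priority_floor_at_top_score_selects_top_type(tiny):
    top = max(tiny.patient_types, key=lambda pt: pt.priority_score)
    results = mp.priority_floor_sweep(tiny, [top.priority_score], EXACT)
    kpis = results[0].kpis
    if kpis.total_admissions > 0:
        others = [kpis.per_type_admissions[pt.id] for pt in tiny.patient_types
                  if pt.priority_score < top.priority_score]
        assert sum(others) == 0


def test_compare_models_table(tiny):
    ids = [pt.id for pt in tiny.patient_types]
    frame = mp.compare_models(tiny, [{ids[0]: (0.0, 1.0)}], EXACT)
    assert list(frame["label"]) == ["model_I/scenario 1", "model_II"]
    assert {"objective", "admissions", "status"} <= set(frame.columns)


@pytest.mark.parametrize("name, n_scenarios", [
    ("nursing", 9), ("mix", 9), ("target", 7), ("compare", 4),
])
def test_packaged_sweeps_load(name, n_scenarios):
    specs = mp.packaged_sweep(name)
    assert len(specs) == n_scenarios
    if name == "mix":
        labels = [s.label for s in specs]
        assert "4" not in labels and labels[0] == "1"  # published grid skips 4
    if name == "compare":
        assert specs[-1].variant.use_mix_bounds is False


def test_packaged_sweep_overrides_apply_cleanly(base):
    for name in ("nursing", "mix", "target", "compare"):
        for spec in mp.packaged_sweep(name):
            inst = apply_overrides(base, spec.overrides)
            assert mp.validate_instance(inst) == []
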
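"""Synthetic instances and the enumeration / Monte-Carlo oracles."""

import numpy as np
import pytest

import mixplan as mp
from mixplan.los import LOSPmf
from mixplan.synth import SynthConfig


def test_generation_deterministic():
    a = mp.generate_instance(SynthConfig(seed=42))
    b = mp.generate_instance(SynthConfig(seed=42))
    assert a == b
    c = mp.generate_instance(SynthConfig(seed=43))
    assert a != c


def test_single_type_mix_is_trivial():
    inst = mp.generate_instance(SynthConfig(seed=5, n_types=1))
    assert inst.patient_types[0].mix_lower == 0.0
    assert inst.patient_types[0].mix_upper == 1.0


@pytest.mark.parametrize("seed", range(25))
def test_generated_instances_valid(seed):
    inst = mp.generate_instance(SynthConfig(seed=seed, n_types=1 + seed % 3,
                                            horizon=1 + seed % 6))
    assert mp.validate_instance(inst) == []


def test_brute_force_rejects_oversized(base):
    with pytest.raises(ValueError, match="enumeration bound"):
        mp.brute_force_optimum(base)


def test_brute_force_zero_cap():
    inst = mp.generate_instance(SynthConfig(seed=1))
    from dataclasses import replace
    inst = replace(inst, admission_cap=0)
    obj, x = mp.brute_force_optimum(inst)
    assert np.all(x == 0)
    expected = -sum(rs.cost_neg * rs.target.sum() for rs in inst.resources)
    assert obj == pytest.approx(expected)


@pytest.mark.parametrize("seed", range(20))
def test_solver_matches_enumeration(seed):
    """MILP (linearized deviations) vs direct positive-part enumeration."""
    inst = mp.generate_instance(SynthConfig(seed=seed))
    obj, _ = mp.brute_force_optimum(inst)
    plan = mp.solve_instance(inst, mp.MODEL_I, mp.SolverOptions(mip_rel_gap=0.0))
    assert plan.status == "optimal"
    assert plan.objective == pytest.approx(obj, abs=1e-6)


# -- Monte-Carlo census -------------------------------------------------------

def test_simulation_deterministic_los():
    x = np.array([[2, 0, 3], [1, 1, 0]])
    pmfs = [LOSPmf((1.0, 0.0, 0.0))] * 2
    mean, se = mp.simulate_census(x, pmfs, reps=50, seed=0)
    np.testing.assert_array_equal(mean, x)
    assert np.all(se == 0)


def test_simulation_binomial_day_two():
    # 2 patients, each stays a 2nd day with probability 0.5: mean census 1.0
    x = np.array([[2, 0, 0]])
    pmfs = [LOSPmf((0.5, 0.5, 0.0))]
    mean, se = mp.simulate_census(x, pmfs, reps=20_000, seed=123)
    assert abs(mean[0, 1] - 1.0) <= 3 * se[0, 1]
    assert mean[0, 0] == 2.0 and mean[0, 2] == 0.0


def test_simulation_residual_mass_stays_through_horizon():
    # pmf mass 0.4 unassigned: those patients remain until the cycle ends
    x = np.array([[10, 0, 0]])
    pmfs = [LOSPmf((0.6, 0.0, 0.0))]
    mean, se = mp.simulate_census(x, pmfs, reps=20_000, seed=9)
    assert abs(mean[0, 2] - 4.0) <= 3 * se[0, 2]


def test_simulation_matches_analytic_census(base):
    rng = np.random.default_rng(2024)
    x = rng.integers(0, 6, size=(3, 28))
    survs = [pt.survival for pt in base.patient_types]
    analytic = mp.census_matrix(x.astype(float), survs)
    pmfs = [mp.pmf_from_survival(s) for s in survs]
    mean, se = mp.simulate_census(x, pmfs, reps=400, seed=7)
    assert np.all(np.abs(mean - analytic) <= 3 * se + 1e-9)


def test_simulation_converges_with_reps(base):
    # error shrinks roughly like 1/sqrt(reps)
    x = np.zeros((3, 28), dtype=int)
    x[:, 0] = 20
    survs = [pt.survival for pt in base.patient_types]
    analytic = mp.census_matrix(x.astype(float), survs)
    pmfs = [mp.pmf_from_survival(s) for s in survs]
    errs = []
    for reps in (50, 5000):
        mean, _ = mp.simulate_census(x, pmfs, reps=reps, seed=11)
        errs.append(np.abs(mean - analytic).mean())
    assert errs[1] < errs[0]
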
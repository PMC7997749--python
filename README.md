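# mixplan

Priority-constrained patient-mix optimization for hospital admission
planning.

Large referral hospitals routinely run at (or beyond) full bed occupancy
while still facing demand from patients who could be treated elsewhere.
One tactical lever is *admission planning*: deciding, over a planning
cycle, how many elective patients of each type to admit each day so that
scarce resources go preferentially to the patients who need them most,
without leaving paid-for capacity idle.  `mixplan` is for health-care
operations researchers and hospital planners who want that decision as a
reproducible optimization model rather than a spreadsheet.

## The model

Patients are grouped into types `i` with per-admission revenue `r_i`,
admission-day exam hours `e_i`, nursing hours per patient-day `n_i`,
priority score `s_i`, cycle mix-share bounds `[α_i, β_i]`, and a discrete
length-of-stay distribution given by the survival curve
`S_i(s) = P(LOS > s)`.  With integer admissions `x_it` on days
`t = 1..τ`, the expected census is the cohort convolution
`M_it = Σ_{u≤t} S_i(t−u) x_iu`, and the program is

```
max  Σ_it r_i x_it − Σ_rt c_r⁺ C⁺_rt − Σ_rt c_r⁻ C⁻_rt
s.t. Σ_it x_it ≤ n                                  (cycle admission cap)
     α_i Σ_jt x_jt ≤ Σ_t x_it ≤ β_i Σ_jt x_jt       (mix-share bounds)
     Σ_i s_i Σ_t x_it ≥ L^p Σ_it x_it               (priority floor)
     load_rt ≤ AC_rt                                (hard daily capacity)
     load_rt − TC_rt = C⁺_rt − C⁻_rt,  C± ≥ 0       (goal programming)
     x_it ∈ ℤ₊
```

where the three resource loads are bed census `Σ_i M_it`, exam hours
`Σ_i e_i x_it` and nursing hours `Σ_i n_i M_it`, each with a hard
availability `AC` and a soft target `TC` whose over/under-shoot is priced
at `c⁺`/`c⁻`.  A relaxed variant ("model II") drops the mix-share
constraints.  See `docs/methods.md` for assumptions, numerical choices and
limitations — including why, under the packaged default targets, the
objective level is dominated by unavoidable idle-capacity penalties and
scenario *differences*, admissions and mix are the meaningful outputs.

The MILP is solved with HiGHS (via `scipy.optimize.milp`); all reported
figures are recomputed from the integer plan, independently of the solver.
Two built-in oracles — exhaustive enumeration of tiny instances and a
Monte-Carlo discharge simulation — cross-check the optimizer and the
census algebra in the test suite.

## Worked example

Solve the packaged 28-day reference instance (a 290-bed respiratory
department, three patient types, 30% of capacity reserved for emergencies):

```sh
$ mixplan solve --gap 0.01 --time-limit 150
status: optimal  (24.8s, gap=0.007840253385807312)
objective: -240426.75
admissions: 580  {'I': 406, 'II': 116, 'III': 58}
mix: {'I': '70.00%', 'II': '20.00%', 'III': '10.00%'}  average priority: 7.90
wrote plan.csv and kpis.json
```

Reading the output: the optimizer admits 580 elective patients over the
four weeks.  Because the upper mix shares (0.7, 0.2, 0.1) sum to 1, every
feasible plan — hence the optimum — carries exactly 70% high-priority,
20% middle and 10% low-priority patients, with admission-weighted average
priority 0.7·9 + 0.2·6.5 + 0.1·3 = 7.9.  The large negative objective is
the revenue of those admissions (≈96k) minus deviation penalties, most of
which is idle-capacity cost on the exam and nursing targets that no
feasible plan can reach (see `docs/methods.md`); compare scenarios by
difference rather than by level.  `plan.csv` holds the day-by-day integer
admission matrix and `kpis.json` the recomputed summary figures.

Sensitivity sweeps and the model comparison use the packaged grids:

```sh
mixplan sweep --config nursing --gap 0.01 --time-limit 150 --out-dir results
mixplan sweep --config target  --gap 0.01 --time-limit 150 --out-dir results
mixplan compare --gap 0.01 --time-limit 150 --out-dir results
mixplan generate --seed 7 --n-types 3 --horizon 28 --out synthetic.yaml
```

Python API:

```python
import mixplan as mp

inst = mp.base_instance()
plan = mp.solve_instance(inst, mp.MODEL_I,
                         mp.SolverOptions(mip_rel_gap=0.01, time_limit=150))
kpis = mp.compute_kpis(plan, inst)       # everything recomputed from plan.x
print(kpis.total_admissions, kpis.proportions)
```

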
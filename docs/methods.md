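# Methods

## The planning model

`mixplan` plans elective admissions for a hospital department over a
finite cycle of `tau` days (default 28).  Patients come in a small number
of types `i`, each with a revenue per admission `r_i`, exam hours on the
admission day `e_i`, nursing hours per in-hospital patient-day `n_i`, a
priority score `s_i`, bounds `[alpha_i, beta_i]` on the type's share of
total cycle admissions, and a discrete length-of-stay (LOS) distribution.
The decision variables are integer admission counts `x[i,t]`.

LOS enters through the survival curve `S_i[s] = P(LOS > s days)`, with
`S_i[0] = 1` and stays truncated at the cycle length.  The expected number
of type-i patients in hospital on day t is the admission-cohort
convolution

    M[i,t] = sum_{u<=t} S_i[t-u] * x[i,u],

so a patient admitted on day u occupies a bed on day u with certainty and
on day u+s with probability `S_i[s]`.  The hospital starts the cycle
empty, and occupancy past day `tau` is outside the objective.  The census
is an expectation and therefore real-valued; no rounding is applied inside
the model.

Three resources constrain the plan, each with a hard daily availability
`AC_r[t]` and a soft daily target `TC_r[t] <= AC_r[t]`:

* **bed**: load = total expected census `sum_i M[i,t]`;
* **exam**: load = admission-day exam hours `sum_i e_i x[i,t]`;
* **nursing**: load = census-weighted nursing hours `sum_i n_i M[i,t]`.

The objective maximizes revenue minus goal-programming deviation costs,

    max  sum_{i,t} r_i x[i,t]
         - sum_{r,t} cpos_r * devpos[r,t]  - sum_{r,t} cneg_r * devneg[r,t],

subject to a cycle-total admission cap `n`, the mix-share bounds
(enforced on cycle totals — the natural reading, since per-day copies of a
constraint on cycle sums would be identical), a floor `L^p` on the
admission-weighted average priority score, the hard capacity caps
`load_r[t] <= AC_r[t]`, and the deviation linkage

    load_r[t] - TC_r[t] = devpos[r,t] - devneg[r,t],   devpos, devneg >= 0.

The linkage is the standard linearization of the positive-part definitions
`devpos = [load - TC]+`, `devneg = [TC - load]+`.  The two formulations
coincide at any optimum as long as **both** unit costs are strictly
positive (otherwise the solver may inflate both deviations on some day);
the builder warns when a cost is zero or negative, and all reported
deviations are recomputed from `x` as direct positive parts regardless.

Two variants are exposed: the full model ("model I", mix bounds and
priority floor on) and a relaxation without the per-type share constraints
("model II").  Whether model II retains the priority floor is a
configuration flag — a floor of 0 is non-binding either way, and both
readings of the relaxed variant are constructible.

## Default parameters (packaged base instance)

The packaged instance describes a 290-bed respiratory department with 30%
of every capacity reserved for emergency arrivals, leaving the elective
shares: 203 beds, 201.6 exam hours/day and 561 nursing hours/day.  Targets
sit at roughly 90% of the elective availability (183 beds, 181 exam h,
512 nursing h); deviation costs are 20 per unit of overuse and 30 per idle
unit on every resource.  The three patient types have revenues
(170, 160, 150), exam hours (1.5, 1, 1.5), nursing hours (1.5, 1, 0.5),
priority scores (9, 6.5, 3), mix-share bounds upper (0.7, 0.2, 0.1) /
lower (0.5, 0.1, 0), and empirical 28-day LOS survival curves with mean
stays of 12.06, 12.5 and 12.4 days.  The admission cap defaults to the
non-binding `tau * 203 = 5684` and the priority floor to 0; neither is
active in the base case, where the binding structure is the bed capacity
plus the mix bounds.

Because the upper mix shares sum to exactly 1, *every* feasible plan with
at least one admission has its mix pinned at exactly (70%, 20%, 10%) —
this is a structural property, not an artifact of the solver.

### A note on the objective's composition

Under the default parameters, the exam and nursing targets are
unreachable: bed capacity limits admissions to roughly 20/day, so the
daily exam load is about 28.5 h against a 181 h target, and the nursing
load is at most `1.5 * 203 ≈ 305` h against a 512 h target.  Roughly
325k of idle-capacity penalty per cycle is therefore incurred by every
feasible plan, and the optimal objective is a large negative number whose
level is set by this fixed cost.  The *differences* between scenarios and
the admission plan itself are meaningful; the headline objective level is
an artifact of where the targets are placed.  Users who want an
interpretable profit figure should set exam/nursing targets near reachable
loads (or their deviation costs to small values), which the instance
schema supports per resource.

## Solving

The MILP is solved with HiGHS through `scipy.optimize.milp`.  Plans,
census, deviations and all KPIs are recomputed from the integer solution
`x` (single source of truth); the solver's own objective is kept alongside
and compared — a disagreement would indicate a modeling/solver
inconsistency (for example non-complementary deviation variables).

Numerical choices:

* **Integrality** on `x` only; deviations are continuous (the census is
  fractional).
* **Per-day bounds** `x[i,t] <= min(bed AC, exam AC / e_i, n)` are valid
  implications of the hard caps and help the search.
* **Provable deviation fixing**: when a resource's load can never exceed
  its target (e.g. nursing above), its positive-deviation variables are
  fixed at 0.  This is exactly the condition under which the fix is an
  equivalence, and it shortens the base-instance solve from minutes to
  seconds.  Wider "valid at optimum" deviation bounds were tried and
  rejected: they slowed branch-and-bound dramatically.
* **Optimality gap**: tiny instances (the oracle suite) are solved at gap
  0.  The 28-day instance has a structurally weak LP relaxation — the
  continuous optimum fills the bed capacity exactly, while integer plans
  leave O(1) residuals whose cost the bound ignores — so proving the last
  ~0.5% takes very deep branching.  The package default for full-size work
  is a 1% relative gap (tens of seconds; the incumbent admission plan is
  stable there).  Gap-based termination with no time limit is
  deterministic for fixed inputs; time limits are offered only as an
  explicit backstop and are flagged in the plan status.
* **Ties/alternate optima**: the solver returns one optimal plan;
  admission matrices may differ between runs only if solver settings
  change.  Comparisons should be made on objective, totals and mix.

Infeasibility can only come from an invalid instance (the empty plan
satisfies every constraint of a valid one); the builder therefore
validates and raises before constructing a model, and sweeps record
invalid scenarios instead of aborting.

## Scenario engine

Sweeps apply dotted-path parameter overrides to the base instance and
solve each scenario in order, recording failures per-row.  The packaged
grids cover nursing-hour sensitivity, mix-bound sensitivity (labels follow
the published grid, which skips "4"), a uniform target-capacity sweep and
the model I/model II comparison.  In the target sweep the bed target is
set directly and the exam/nursing targets are scaled to the *same
utilization fraction of their own availability* (e.g. bed 185 ⇒ fraction
185/203 ≈ 91.1%), reading the sweep as "one target-utilization level
applied to all resources".  Table emitters round revenue and percentage
shares to 2 decimals; raw values are kept in the result objects.

## Synthetic instances and oracles

`generate_instance` draws valid instances as a pure function of the seed:
geometric-like truncated survival curves (`S[s] = (1-p)^s`, discharge
probability `p ~ U(0.2, 0.8)`), positive revenues/costs, mix lower bounds
that sum below 1 with uppers above their lowers, targets at 40–100% of
availability, and an admission cap drawn small enough that it sometimes
binds (including 0, exercising the empty-plan path).  Defaults are
oracle-sized: 1–3 types, horizons up to ~6 days, capacities of a few
units.  The generator emulates the *structure* of real planning data, not
its content: no weekday patterns, no correlation between revenue and LOS,
no emergency arrivals, and survival curves from a single parametric
family.  Passing oracle tests therefore validates the optimization and
census machinery, not the realism of any particular hospital's parameters.

Two independent oracles cross-check the main code paths:

* `brute_force_optimum` enumerates every integer plan of a tiny instance
  (guarded at 10^6 candidates) and evaluates deviations as direct positive
  parts — deliberately *not* reusing the linearization, so exact agreement
  with the MILP is a meaningful test of both.
* `simulate_census` samples each patient's LOS from the pmf and counts
  occupancy day by day; pmf mass beyond the horizon is assigned to
  "still in hospital at cycle end", mirroring the survival truncation.
  The analytic census must match within Monte-Carlo error (3 standard
  errors in the test suite).

## Known limitations

* Expectation-based census only: no distributional statements about
  occupancy (overflow probabilities etc.) are available from the model.
* Patients whose stay would cross the horizon are censored at day `tau`,
  not excluded from admission; end-of-cycle admissions are therefore
  cheap in bed-days, which is visible as end-loading in optimal plans.
* Days are homogeneous — no weekend effects or calendars.
* The headline objective level is dominated by idle-capacity penalties
  whenever targets are unreachable (see above); compare scenarios by
  differences, admissions and mix.
* Proving exact optimality of full-size instances is slow with the
  bundled solver; results at the default 1% gap are deterministic but may
  differ from the true optimum by up to that gap (observed: admission
  totals can shift by ~10 patients between a 2% and a 1% gap solve).
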
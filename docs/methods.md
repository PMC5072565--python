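# Methods

This note records the modeling and numerical choices behind `cmlsched`: what
is simulated, how the optimization is made exactly linear, which defaults
were open design decisions, and what the synthetic parameter generator does
and does not emulate.

## Cell-population model

The state is a 4 × n matrix of cell counts: four differentiation layers
(stem, progenitor, differentiated, terminally differentiated) for n cell
types (normal; leukemic wild-type; leukemic kinase-domain mutants). All
rates are per day; treatment decisions are made monthly with Δt = 30 days.

Only the stem layer is nonlinear: type-i stem cells grow at
`b φ_i − d`, where the crowding factor `φ_i = 1/(1 + p_i S)` depends on the
total stem count S across all types. The coefficient `p = (b/d − 1)/K`
makes K the exact single-type equilibrium — this identity is exercised
directly by tests (the ODE right-hand side at K is zero to machine
precision). All mutant types share the leukemic-WT coefficient `p_2`.
Note that with a shared crowding factor the multi-type stationary state is
generically single-type (the fittest type's equilibrium condition is the
binding one); the equations are implemented as written and no coexistence is
enforced.

Layers 2–4 are linear: each compartment is produced proportionally to the
compartment above and dies at a first-order rate. The model deliberately
excludes acquisition of new mutations during therapy, intra-month
pharmacokinetics, and cell-cycle/quiescence substructure; each month's
regimen is one atomic mode: holiday, nilotinib, dasatinib or imatinib.

Baseline assumption: TKIs do not affect the stem compartment (layer-1 rates
are identical across modes; `DrugRateTable.check_stem_invariant` enforces
this). Consequently the stem trajectory is the same under every schedule
and can be solved once. The optional "stem effect" hypothesis
(`apply_stem_effect` / `StemEffectConfig`) multiplies leukemic stem birth
rates by 1 − a/100 during drug months; enabling it breaks
schedule-independence, so those analyses go through the full ODE path only
(fixed schedules are simulated and compared; re-optimization under the stem
effect is out of scope because the affine decomposition below no longer
exists).

## Integration and the exact affine month maps

Reference simulations use `scipy.integrate.solve_ivp` with LSODA,
rtol = 1e-9 and atol = 1e-3 cells: abundances span ~1e4–1e12, and the
sub-cell absolute floor keeps small resistant clones resolved. The
schedule-independent stem subsystem is integrated once with a dense
interpolant (rtol 1e-10) covering the whole horizon.

Because layers 2–4 are linear with the stem trajectory as known forcing, the
month-m update of the per-type (PC, DC, TC) subvector under drug j is exactly

    y(t_{m+1}) = E_j y(t_m) + f_{m,j},
    E_j = expm(A_j Δt),
    f_{m,j} = ∫₀^{Δt} expm(A_j (Δt − s)) g(t_m + s) ds,

with `A_j` the 3 × 3 lower-bidiagonal rate matrix and
`g = (b₂ x₁(t), 0, 0)` the stem forcing. The forcing integral is evaluated
by 48-node Gauss–Legendre quadrature on the dense stem interpolant; the
matrix-exponential kernels at the nodes are shared across months. The
integrand is smooth, so quadrature error is far below the integrator
tolerance; the suite verifies affine-vs-ODE agreement below 1e-6 relative
at every month boundary over random schedules and parameter sets (measured
values are ~1e-8).

## The optimization problem and its linearization

The planner minimizes the total leukemic burden (all layers, all types ≥ 2)
at the horizon, or optionally its average over the month boundaries
x¹..x^M (x⁰ is excluded from the average since no decision affects it; a
continuous, integral-based average is available for simulated
trajectories). The schedule-independent leukemic stem contribution enters
the objective as a constant.

Binary variables z^{m,j} select the mode of month m (Σ_j z^{m,j} = 1).
Products z^{m,j}·x^m are linearized with standard bounded-product
constraints using per-month, per-coordinate reachable-state upper bounds
U^m, computed by interval propagation `U^{m+1} = max_j (E_j U^m + f_{m,j})`
— valid because E (matrix exponential of a Metzler matrix) and f (integral
of a nonnegative forcing) are componentwise nonnegative. Tight per-month
bounds rather than one global big-M keep the LP relaxation as strong as
this formulation allows.

Numerics: state and product variables are expressed in units of 1e9 cells
inside the MILP, which keeps most coefficients within a few orders of
magnitude of unity at 1e12-cell burdens; bounds carry a 1e-7 relative slack
so solver round-off cannot cut off a truly reachable state; reported
objectives are recomputed from the returned schedule by affine propagation,
making the report consistent with the simulator by construction.

The backend is HiGHS via `scipy.optimize.milp`, wrapped behind a minimal
solver-agnostic model builder that can also export LP-format files for
external solvers. Solves are deterministic (single-threaded HiGHS, no
stochastic options). An exhaustive enumeration oracle evaluates all 4^M
schedules by vectorized affine propagation (capped at M ≤ 10) and is the
independent check on the MILP: objective agreement to 1e-6 relative across
horizons 3–6, with and without toxicity, on ten seeded parameter sets. Ties
are broken lexicographically (lower drug index earlier), so outputs are
reproducible.

Full 36-month instances are hard for this big-M class: proven optimality
can take on the order of an hour (matching the budget reported for
commercial solvers on the same problem shape). The solver accepts a time
limit and reports the incumbent schedule with its optimality gap; routine
validation in this package therefore runs at horizons where enumeration is
exact.

## Toxicity model

The absolute neutrophil count follows a truncated linear monthly recursion:
drug months deplete it at per-drug rates (nilotinib 350, dasatinib 300,
imatinib 250 per mm³ per month), holiday months recover 2000 capped at the
normal ceiling 3000; neutropenia is a count below 1000; the initial count is
3000. The ANC has no feedback from the cell-population state.

Two feasibility semantics are implemented because the narrative rule ("a
holiday is required at the next decision once the count dips below
threshold") and the constraint a proactive optimizer would satisfy ("never
dip below threshold") differ:

* `hard_bound` (default): y^m ≥ L for every m — the natural MILP
  constraint, strictly stronger than the trigger rule;
* `trigger`: any month that starts below L must be a holiday (big-M
  implication constraints in the MILP).

In the MILP the recursion is imposed as upper bounds on y (larger y only
relaxes feasibility, and the truncated recursion value is the maximum
feasible y, so feasibility is preserved exactly). Under `hard_bound` the
bound is enforced for m = 1..M with y⁰ given; an instance whose initial
count is already below threshold is reported infeasible outright.
Published monotherapy-with-holiday schedules show inter-holiday spacing not
exactly reproduced by either semantics with the published rates; no attempt
is made to force agreement with that spacing.

## Scenario fixtures and the synthetic parameter generator

The three printed diagnosis-time abundance tables (single mutant F317L,
single mutant M351T, and the two-mutant case) are embedded verbatim as
fixtures and covered by golden-value tests. The published per-drug rate
constants, however, live in supplementary material that is not
redistributed; analyses reproducing the published headline numbers activate
only when the user supplies that parameter file
(`params/published_rates.json`, same JSON schema as any model parameter file,
versioned so the file can be dropped in without code change).

Everything else runs on `synthetic_params(seed)`, which draws rate tables
with ~8% log-normal jitter around defaults chosen to be realistic for this
disease, constrained to the qualitative structure the study describes:

* stem rates identical across modes (TKIs spare stem cells);
* normal lineage: stem division every ~1000 days with b/d ≈ 2 and carrying
  capacity K₁ ≈ 7e4, total SC→TC amplification ≈ 4e6 — so the normal pool
  is only mildly depleted during the years of preclinical leukemic
  expansion;
* leukemic lineage off drug: b/d ≈ 6 at the stem level, K₂ ≈ 2.8e5,
  downstream amplification close to normal; a single seeded stem cell
  expands to a 1e12-cell burden in roughly a decade;
* drug inhibition multiplies leukemic birth rates of layers 2–4, with
  sorted assignment guaranteeing for every leukemic type and every seed:
  progenitor kill dasatinib > nilotinib > imatinib, differentiated-cell
  kill nilotinib > dasatinib > imatinib;
* each mutant gets one resistance exponent pulling its inhibition factors
  toward 1, which preserves those orderings;
* normal cells are mildly affected (nilotinib most, imatinib not at all).

What the generator does not emulate: calibration to clinical IC50 data,
patient-to-patient kinetic variability beyond the jitter, and the exact
detection-time composition of the printed tables — synthetic
expansion-to-detection states come out somewhat more leukemic-dominant
(~84–91% leukemic) than the printed ~77%. Tests passing on synthetic
parameters therefore establish the correctness of the machinery
(simulation, linearization, optimization, toxicity handling) and the
qualitative drug-sequencing behavior (dasatinib-then-nilotinib switch
structures arise for many seeds), not quantitative agreement with any
clinical estimate.

`derive_initial_conditions` reproduces the study's seeding convention
deterministically: one leukemic WT stem cell added to the healthy
equilibrium, untreated expansion until the leukemic burden crosses the
detection threshold (default 1e12 cells, terminal ODE event), then each
leukemic layer split between WT and mutants at the requested fractions
(default 5% per mutant, uniformly across layers, as in the printed tables).

## Known limitations

* Proven-optimal 36-month solves are slow (big-M relaxation is weak); use
  time limits and read the reported gap.
* The ANC model is deliberately parsimonious — linear rates, no feedback
  from cell counts, no nonlinear neutrophil dynamics.
* Acquired (de novo) resistance during therapy is not modeled; the tool
  optimizes against the mutant spectrum present at diagnosis.
* With the stem effect enabled, only fixed-schedule simulation is
  supported, not re-optimization.
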
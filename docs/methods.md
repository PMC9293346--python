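# Methods

This note documents the model implemented by `hbpopt`, its assumptions,
the choices made where the design was genuinely open, and what the test
fixtures do and do not establish.

## Scope and framing

The package addresses one policy decision: which of ~20 candidate health
interventions a government should include in an essential benefits package
financed free at the point of care, given a budget. Two outcomes are
modelled — deaths averted (population health) and expected cases of
catastrophic health expenditure (CHE) averted (financial risk protection,
FRP) — and the selection problem is solved exactly as a bi-objective 0/1
program. The disease model is deliberately static and illustrative: no
transmission dynamics, no herd effects, no morbidity outcomes (DALYs/QALYs
are out of scope), no supply-side constraints, and no equity
stratification. Demand is assumed constant across household income levels.

## Intervention-level model

Funding intervention *i* does two things relative to the exclusion
counterfactual: coverage rises from `C_i` by the policy increment
(`coverage_increment`, default 0.05, capped so `C'_i = min(C_i + 0.05, 1)`)
and all out-of-pocket (OOP) payments for the service are waived.

Health impact runs through one of two channels per disease target `x`:

- **incidence**: `δI = (C'−C)·E·A·I_x`, `δD = CFR_x·δI`;
- **fatality**: `δD = (C'−C)·E·A·D_x`.

`E` (effectiveness) and `A` (addressable share) are fractions in [0, 1];
`I_x`, `D_x`, `CFR_x` come from the burden table. Per-target deaths sum to
the intervention total. The treated population is `T = C'·A·POP` per
target (the intervention-level `target_population_override` wins over the
disease default), summed to `δH_i`.

### Financial risk protection

Per-capita household consumption `y` is gamma-distributed. The Gini
coefficient of a gamma depends only on the shape, through the closed form

    G(α) = Γ(α + 1/2) / (√π · Γ(α + 1)),

which is strictly decreasing with G(1) = 1/2 (the exponential case).
Calibration inverts G by bracketed bisection on α ∈ [1e−3, 1e3] to a Gini
tolerance of 1e−10 (deterministic, no seed), then sets the scale as
mean/shape. The closed form is the package's *definition* of the
calibration; it is verified against Lorenz-curve quadrature in the tests.

A payment is catastrophic when `OOP > t·y` (threshold share `t`, default
0.10, sensitivity 0.25), so the per-payer CHE probability is the gamma CDF
at `OOP/t`. **Counting is expectation-based**: expected CHE cases averted
= probability × payers. A seeded sampling helper exists purely as a
Monte-Carlo oracle for tests; the pipeline itself is fully deterministic,
because the method's outputs are single expected counts per scenario.
OOP is compared against per-capita consumption directly; no household-size
adjustment is applied (none is defined in the model).

Two FRP channels are counted:

- **primary**: every covered user (baseline and newly covered alike —
  both face the same waived-OOP threshold test) whose OOP would have been
  catastrophic: `δCHE_primary = T · F(OOP_i/t)`. For two-stage
  (screening) interventions, all screened users face the screening-cost
  test and the screen-positive fraction additionally faces the
  treatment-cost test; the two expected counts are summed.
- **secondary**: prevented incident cases no longer demand downstream
  care `j` on the same disease: `δH_ij = δI_x · C_j · A_jx` users, each
  averting `F(OOP_j/t)`. Chains are evaluated exactly one step deep
  (i → j); no transitive closure.

### Cost

The primary rule prices inclusion as the OOP subsidy for the
baseline-coverage population plus full unit cost for newly covered users:

    TC_i = Σ_x [ C·A·POP·(oop_share·u)  +  (C'−C)·A·POP·u ].

A second formulation, unit cost times the whole covered population
(`TC = u·δH`), circulates in this literature; the subsidy rule is
implemented as primary because it is the more precisely specified of the
two, and `cost_rule="simple"` reproduces the alternative for comparison.
OOP is stored as a *share* of unit cost (`oop_share`; the 34%
health-sector average is the default when a row omits it) so the absolute
OOP amount and the cost rule can never drift apart.

### Uncertainty and timing

Optimistic/pessimistic bounds take the max/min of deaths averted and CHE
cases averted over the 3×3 grid of {low, mean, high} burden × {low, mean,
high} effect (9 combinations); a field without stated bounds contributes
its central value (with a warning when a non-central scenario was
requested). Cost bounds are ±50% of unit cost, reflecting the absence of
empirical cost uncertainty ranges.

Interventions carry a delay bin — none/short/medium/long mapping to
benefit delays of 0/5/10/20 years with *immediate* costs (a vaccine
delivered today averts deaths years later; the budget is spent now). The
default steady-state mode ignores timing; `lagged` mode annotates benefit
and cost years without changing magnitudes. Whether delayed benefits
should be discounted is left open by the model as stated, so the package
annotates timing only and exposes a discount-rate hook defaulting to 0.

Expected counts stay fractional end to end; rounding (half-even) is a
reporting concern only.

Bundled interventions (e.g. labor-and-delivery signal-function packages)
are evaluated per component — each component's OOP faces its own CHE
threshold test — and summed to cumulative bundle totals. Summing the
component threshold tests (rather than testing the summed OOP) is the
documented default; the schema supports either via bundle aggregation.

## Optimization

The selection problem is

    max Σ Obj¹_i·Z_i   s.t.   Σ TC_i·Z_i ≤ B,   Σ Obj²_i·Z_i ≥ K,   Z_i ∈ {0,1},

with bundles constrained all-or-nothing. The backend collapses bundles
into units and enumerates all subsets with vectorized subset sums (up to
2²² units), so every result is a certified global optimum — appropriate
for the desk-scale instances this method targets and the property that
makes "the optimal subset" a testable claim rather than a heuristic one.
Ties are broken deterministically: higher auxiliary objective, then lower
cost, then preference for earlier-listed interventions.

**Frontier tracing.** The epsilon-constraint loop maximizes deaths averted
subject to CHE ≥ K, then jumps K to the achieved CHE plus a step. The
built-in tie-break doubles as the lexicographic second stage, so every
returned point is Pareto-optimal. Because the objectives are real-valued
expected counts, the default jump step is tolerance-scale (1e−6 — strictly
larger than the 1e−9 constraint tolerance, so the loop always advances):
this makes the traced frontier provably identical to the brute-force
non-dominated set, where a unit step could skip non-dominated points less
than one unit apart in the constrained objective. `k_step=1.0` remains
available to reproduce a coarser unit-increment sweep. Objective
coefficients are never rounded to integers, and K is treated as a real.

**Convergence ratio.** For the deaths-max endpoint `(D*, C*)`,

    λ* = max_{j ≠ *} (C_j − C*) / (D* − D_j)

over frontier points: for any valuation λ ≥ λ* (CHE cases per death
averted) the maximizer of λ·D + C over the feasible space is the
deaths-max package, and for λ just below λ* it is not. The symmetric ratio
is reported for the CHE-max endpoint. Because the weighted-sum scan is
taken over the full frontier (not only its convex hull), supportedness is
never assumed. A single-point frontier returns 0.

**Budget sweeps** report the single-objective optimum per ascending
budget, with entering/exiting interventions per step. The optimized
objective is non-decreasing (asserted; the feasible set only grows); the
auxiliary outcome is unconstrained and can fall when an expensive
high-value intervention becomes affordable and displaces several others.

Floating-point comparisons on costs and objective values use absolute
tolerance 1e−6 throughout.

## Synthetic data

No real country tables ship with the package; the generator produces
statistically realistic instances so every stage is buildable and testable
offline. Defaults emulate the shape of a national exercise in a
low-income setting: 20 interventions × 23 disease areas; coverage
U(0.05, 0.80); effects U(0.10, 0.90) with ±(10–50)% bounds; addressable
shares U(0.2, 1.0); unit costs log-uniform (~2–300 USD, yielding total
costs spanning roughly 1e5–1e7 USD) with one deliberately expensive
candidate so budget sweeps exhibit the displacement cliff; OOP shares
normal around the 34% sector average (clipped to [0.05, 0.9]); incidence
log-uniform 1e4–5e5/year with CFR U(0.01, 0.5) and deaths = incidence ×
CFR by construction; downstream links with probability 0.15 (at least one
forced); two 2-member bundles; 20% screening interventions; at least one
of each channel and one delayed intervention. The economy block (mean
consumption 1000 USD, Gini 0.40) is a round placeholder, deliberately not
any country's values. One seed drives everything; identical seeds yield
byte-identical files.

What the generator does **not** emulate: correlations between cost,
effectiveness and burden found in real data; age structure; between-
disease epidemiological dependence; measured (as opposed to synthesized)
uncertainty bounds. Passing tests therefore certify the *machinery* —
arithmetic, calibration, exact optimality, determinism — on realistic
magnitudes, not the policy conclusions for any actual country, which
require that country's parameter tables in the documented schema.

`worked_micro_example()` is a fixed 3-intervention, 2-disease instance
with Gini 0.5 (exponential consumption), chosen so every output has a
closed form; its stored expected values are derived by hand in its
docstring and serve as the pipeline regression fixture.

## Numerical and interface choices

- Gamma CDF/sampling: `scipy.stats.gamma`; log-gamma differences for the
  Gini closed form (stable at large shape).
- CSV I/O via pandas with `float_precision="round_trip"`, and writers emit
  shortest round-trip float representations, so read∘write is the byte
  identity on valid tables; result files are written at fixed 6-decimal
  precision.
- Validation errors name the offending row and field; unknown disease ids
  and dangling downstream links are reference errors, distinct from schema
  (missing column) errors. Identifiers are case-sensitive opaque strings.
- The enumeration bound (22 units) covers the intended problem scale with
  headroom; larger instances are rejected explicitly rather than solved
  approximately — approximate solvers are a non-goal.
- CLI: YAML run config with flag override (flags win); logs to stderr,
  results to files/stdout; nonzero exit with the error class named.
- Problem sizes in the test suite and acceptance script (random instances
  of 4–15 interventions against 2^N enumeration oracles, 100 instances;
  10⁶-draw Monte-Carlo checks) were chosen to keep full verification
  desk-scale — each suite runs in seconds.

## Known limitations

- Deaths are the only health outcome; high-morbidity, low-mortality
  conditions are undervalued by construction.
- Static one-step modelling: no dynamic transmission, no herd effects, no
  transitive downstream chains.
- Direct medical OOP only; indirect and transportation costs are excluded,
  understating FRP benefits for some interventions.
- Constant demand across income levels; a pro-poor package design would
  need income-stratified parameters and utilization.
- The delay machinery annotates timing but the default analysis is
  steady-state; discounting is opt-in and zero by default.
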
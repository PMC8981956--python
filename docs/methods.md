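# Methods

## Model structure

The package implements a deterministic cohort state-transition model with
four states: underweight (UW), healthy weight (HW), overweight/obese (OWB)
and death (absorbing).  Thirty starting cohorts (2 sexes × single ages
5–19) are evolved in annual cycles until age 75 or death.  The model is a
expectation (first-order) model: occupancy vectors carry fractional
persons, and all outputs are expectations over the implied individual-level
stochastic process — an equivalence the test suite checks directly against
an agent-level microsimulation.

Cycle order (default): state-specific deaths are removed first, then the
survivors are redistributed by the annual transition matrix.  This makes
death compete at the state the person occupied during that year, which is
also where the death is attributed in the output tables.  The alternative
order (transition, then death at the destination state) is available via
`ModelOptions.transition_order = "transition_first"`; mass conservation
holds under both.

Accrual conventions (defaults, each switchable in `ModelOptions`):

- persons alive at the start of a cycle accrue one full life-year (no
  half-cycle correction; `half_cycle=True` averages start- and end-of-cycle
  occupancy instead);
- discounting uses `1/(1+r)^c` with c the cycle index from the common
  start year, so the first cycle is undiscounted for every cohort
  regardless of starting age;
- deaths accumulate undiscounted — which is why the discount-rate
  scenarios leave the death count bit-identical;
- the final cycle is the year from age 74 to 75; nothing accrues at or
  beyond age 75.

## Mortality

All-cause mortality arrives as rates per sex and 5-year age group.  Single
ages are obtained from an exponential (Gompertz-type) fit: ordinary least
squares of log(rate) on the group midpoint age, one global line per sex,
evaluated at each integer age.  Group midpoints treat groups as inclusive
integer age ranges, so [5, 9] has midpoint 7.5; groups overlapping [5,
horizon) enter the fit.  Because the generating model in the synthetic data
is itself log-linear, the fit is saturated there and recovers the
generating intercept and slope to machine precision — a property test.  A
piecewise mode (log-linear interpolation between midpoints) is available
for sensitivity checks.

Hazard ratios by weight status multiply the *hazard*, not the probability,
before the actuarial conversion `q = 1 − exp(−rate)`; this is what a
hazard ratio means and guarantees q < 1.  Ratios apply only from age 20:
differential mortality in children is not supported by data, so the model
is deliberately conservative below 20.  The all-cause rate is treated as
the healthy-weight baseline by default.  The alternative reading — the
all-cause rate is a prevalence-weighted mixture across weight states, so
the baseline should be `rate / Σ_s prev(s)·hr(s)` — is implemented behind
`ModelOptions.calibrate_baseline`; since prevalence is only observed for
ages 5–19, adult ages reuse the age-19 prevalence row of the same sex as
the weight vector.

## Scenarios

A scenario multiplies the prevalence of the target state(s) and/or the
transition probabilities *into* them by (1 + relative change).  All
displaced probability mass moves to (or is taken from) the healthy-weight
cell of the same row, keeping rows exactly row-stochastic; the natural
limiting case (−100% of both states) is an entirely healthy-weight
population.  Reductions are relative, not percentage-point, so applying
−10% twice gives ×0.81, not ×0.80.  Increases that would drive the healthy
cell negative raise an error naming the row.  By default the +10%
overweight/obesity scenario scales the inbound transitions symmetrically
with the reductions; `applies_to="prevalence"` restricts any scenario to
the initial distribution only.

## Sensitivity analyses

One-way: each parameter group (prevalence, transitions, utilities) is set
wholesale to its lower or upper 95% CI bound; prevalence and transition
rows are restored to sum 1 by recomputing the healthy cell as the residual.
Utility bounds are clipped to [0, 1] and the children's structural 1.0 is
held fixed, so utility-bound runs change QALYs only — deaths and
person-years are bit-identical to the base case (a test).

PSA: per iteration every uncertain cell is redrawn independently —

- prevalence and transition cells: uniform(lo, hi) on the non-healthy
  cells, healthy takes the residual (clamped at 0 with the non-healthy
  draws rescaled in the rare case they exceed 1);
- hazard ratios: lognormal with μ = ln(hr) and σ = (ln hi − ln lo)/(2·1.959964),
  i.e. the CI bounds are the 2.5/97.5 percentiles;
- utilities: beta matched by moments, mean = point value and
  SD = (hi − lo)/(2·1.959964); degenerate cells (children's 1.0, zero-width
  CIs) stay fixed, and 18–34 rows take a single draw shared across states
  so the structural rules survive sampling.

Cells are independent — no correlation structure is imposed, a documented
limitation.  Results report the mean and the empirical 2.5/97.5 percentiles
(not a normal approximation) per outcome and sex; whether the interval
brackets the mean is checked and reported, not assumed.  The default is
10,000 iterations; the whole PSA is reproducible bit-for-bit from its seed.

## Input conventions

- Population may be given per single age or per 5-year group {5–9, 10–14,
  15–19}; grouped counts are split evenly across the five single ages by
  default (`count/5`), preserving the printed group totals, with
  user-supplied split weights as an option.
- "Age a" always means the age attained at the start of a cycle;
  transitions and mortality are indexed by that age.
- CI bounds live in optional `lo`/`hi` columns of the same CSVs; a bundle
  without them loads in point-only mode with the corresponding sensitivity
  axes disabled (warned, not fatal).
- Utilities are supplied as age bands with three structural rules enforced
  on load: ages 5–17 ≡ 1.0; 18–34 sex/age-specific, identical across
  states; 35+ sex/age/state-specific.

## Synthetic data and the Vietnam fixture

The generator emulates the structure real inputs have: smooth prevalence
age-curves with both UW and OWB present, row-stochastic transition matrices
with a dominant diagonal (default persistence 0.85, leavers routed mostly
through healthy weight), log-linear mortality, hazard ratios UW 1.50
(1.30–1.73) and OWB 1.15 (1.04–1.27) — above 1 and ordered UW > OWB in
line with the East-Asian meta-analytic pattern — and utilities declining
0.03 per decade from 0.96 (men) / 0.95 (women) at 18, with a 0.02 penalty
for non-healthy states from age 35.  Default Gompertz parameters
(intercept, slope) of (−9.6, 0.088) for males and (−10.1, 0.090) for
females give plausible south-east-Asian adult mortality (≈0.9–1.3% annual
hazard at age 70).

The Vietnam fixture uses the published 2019 census group counts
(4,354,887 / 3,737,030 / 3,352,386 boys; 3,977,832 / 3,482,807 / 3,153,831
girls) and the printed single-age prevalence exactly; because cells are
printed to one decimal percent, rows can sum to 99.9–100.1% and are
renormalised onto the healthy cell.  The remaining tables use the synthetic
defaults above and are *not* the source study's supplementary inputs;
fixture outputs therefore validate the model's structure and orderings, not
the published point estimates.  Passing real transition/mortality/HR/utility
tables into `vietnam_fixture(...)` swaps the defaults out.

What passing tests on synthetic data do not show: agreement with any real
longitudinal weight-status dynamics (the synthetic transition matrices are
age-constant up to jitter), real mortality curvature beyond log-linearity,
or correlation between parameters.

## Numerical choices and problem sizes

- Row sums are validated to 1e-9; engine mass conservation holds to ~1e-12
  relative and is asserted at 1e-6.
- The population runner evolves all 15 cohorts of a sex simultaneously
  (vectorised over cohorts per calendar cycle); the per-cohort loop is kept
  as the readable reference and the two are tested equal to 1e-12.
- Probabilities produced by hazard conversion are capped at 1 − 1e-15 so
  an occupancy never goes exactly extinct in one step.
- Test problem sizes: the microsimulation oracle uses 10 replicates of
  1e5 agents (1e6 total) on a 5-cycle instance; PSA convergence is checked
  at 500 iterations against a 3-standard-error band; generator validity is
  checked over 1,000 seeds.

## Limitations

- Transition probabilities and mortality rates are constant over calendar
  time (no secular trends).
- No costs, no DALYs, no morbidity states; outcomes are deaths, life-years
  and QALYs only.
- Parameter uncertainty is sampled independently per cell.
- The overweight and obese categories are merged, as in the data the model
  is designed around.
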
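# Methods

This note documents the model, its assumptions, the synthetic data that
stands in for real survey and demographic inputs, and the numerical and
design choices made where more than one defensible option existed.

## Model overview and assumptions

The package implements a dynamic multistate life-table analysis of smoking
and disability. The population is stratified by sex and one-year age classes
0–95, where 95 is an open-ended class; every model is estimated and
projected fully stratified by sex. Three smoking states (never, current,
former) interact with mortality through relative risks `RR_k` and with
disability through odds ratios `OR_k` (never smokers are the reference,
ratio 1). Core assumptions:

* **Stationary exposure.** Net transition probabilities are derived so that
  the age-specific smoking prevalence is constant over calendar time under
  the reference scenario. This is the model's defining property and is
  verified to 1e-8 by test.
* **Fixed state-specific hazards.** State-specific mortality and disability
  probabilities are derived once from reference inputs and held fixed across
  scenarios; policies change the composition of the population, not the
  hazards of a given state.
* **Prevalence-odds disability linkage.** Disability attaches
  cross-sectionally: given overall prevalence `π(a,s)` and odds ratios, the
  baseline log-odds `β₀(a,s)` is solved so the prevalence-weighted mixture
  of state-specific probabilities reproduces `π`. No incidence process for
  disability is modelled, and no time-since-quitting gradient exists among
  former smokers.
* **No migration, no secular mortality trend, no disease-specific module.**

## Estimation

Smoking-state prevalence is smoothed with fractional-polynomial (FP)
logistic regressions of each binary state indicator on age, per sex. Ages
are rescaled to `x = age/10`; candidate power sets are all one- and two-term
subsets of {−2, −1, −0.5, 0, 0.5, 1, 2, 3} (0 = log). Selection follows the
conventional FP function-selection procedure: the lowest-deviance model per
degree, with the two-term winner retained only if it improves on the
one-term winner by more than the 2-df chi-square critical value at the 5%
level. A pure argmin over all candidates would essentially always pick a
two-term model (an extra term buys a chance ~χ²(1) improvement), defeating
recovery of a generating one-term curve. Fits run on per-age binomial
aggregates through statsmodels GLM; record weights enter as frequency
weights, and no complex-survey variance estimation is attempted (only point
estimates flow downstream).

The three fitted state curves are renormalized per age to sum to 100%
(three independent binary fits, not one multinomial fit). The disability
curve `π(a,s)` uses the same smoother on the GALI dichotomy; odds ratios
come from a logistic regression of disability on smoking status with age
and age² adjustment — the quadratic captures curvature in the age profile
without interacting with sparse strata.

## Rate derivations

* **Mortality partition**: `q_never = q / (p_n + p_c RR_c + p_f RR_f)`,
  `q_k = RR_k q_never`, capped at 1 with a logged warning (capping breaks
  the mixture identity only at the affected cells).
* **Net transitions**: within a year, mortality acts first and transitions
  second. Survivors of the age-`a` prevalence are redistributed by a start
  probability (applied to never-smoker survivors) and then one signed
  current↔former flow — quit applied to the post-start current pool, or
  restart applied to the start-of-year former pool — so the result equals
  the age-`a+1` prevalence. With three states and two free constraints per
  step this net parameterization is exactly identified, because never-smoker
  status can only be left. Solutions outside [0, 1] are clipped with a
  warning naming the cells (smoothed curves can imply tiny negative flows at
  the oldest ages).
* **Open class**: the 95+ transitions solve the self-map fixed point — the
  flow that keeps the 95+ prevalence stationary under age-95 mortality.
  Copying the age-94 solution instead (the obvious alternative) leaves a
  slow drift in the open class, because the 94→95 balance uses age-94
  mortality and a different source distribution; the fixed point is what the
  stationarity property requires on the full grid.
* **Disability solver**: vectorized bisection for `β₀` on [−50, 50]
  (80 iterations, resolution far below 1e-12; the mixture is strictly
  increasing in `β₀` so the root is unique). `π` exactly 0 or 1 maps to all
  `d_k` 0 or 1 with `β₀ = ∓∞`.

## Scenarios

Nine registry scenarios: reference; smoking-free population; zero (re)start;
all smokers quit; both combined; an alternative low-smoking prevalence
table; zero smoking prevalence below 18; quit chances ×1.3; quit chances
×2.0. Conventions:

* Quit-chance edits act every projection year, not as one-off shocks.
* "All smokers quit" sets the quit probability to 1 wherever the net flow is
  not a restart; net restart cells keep their baseline flow, so a small
  residual current-smoker prevalence can persist. The combined scenario
  zeroes restarts and sets quit to 1 everywhere.
* "No initiation under 18" empties the smoking states below age 18 at
  baseline and zeroes the start rate below 18, leaving 18+ untouched
  (initiation is delayed, not re-allocated).
* The low-prevalence scenario swaps the baseline prevalence table and
  re-derives net transitions from it, so the alternative prevalence is
  itself stationary — the same treatment the reference gives its own table.
* Transition transforms recompute from the untransformed baseline schedule
  (each schedule keeps a reference to its root), which makes applying a
  scenario twice equal to applying it once, including for the
  multiplicative quit scenarios.

## Projection engines

The partial microsimulation gives each individual a stochastic smoking
history but a deterministic fractional alive-weight (no random death
events), which removes the mortality component of Monte Carlo variance. The
default design is 2500 individuals per age class 0–95 per sex (480,000
simulants), each representing cell population / 2500 persons; newborn
cohorts of the same size enter each year at age 0 as never-smokers, weighted
by the newborn series.

Within a year: survival update first, then one transition draw, then ageing
(95+ absorbs). The transition kernel is the exact stochastic counterpart of
the net-flow balance: in a net-quit cell a never-smoker starts and then
faces the same year's quit flow (never→current with probability
`s(1−quit)`, never→former with `s·quit`), current smokers quit with
probability `quit`; in a net-restart cell starters are unaffected and the
start-of-year former pool restarts. One uniform per person-year drives the
draw; a naive one-move-per-individual kernel is *not* expectation-equivalent
to the balance equations and biases the current-smoker share upward over
long horizons.

The deterministic engine propagates the identical bookkeeping as a matrix
recursion on state counts — the exact expectation of the microsimulation —
and serves as oracle and fast path. Seeding: one root seed spawns per-sex
substreams; all scenarios reuse the same individuals and the same uniforms
(common random numbers), so scenario differences are free of between-run
noise, and with null effects (RR = OR = 1) all scenarios produce
bit-identical totals. Total counts are accumulated directly rather than
summed from the state split so they do not inherit summation-order noise.

One extra calendar year beyond the configured horizon is projected
internally, so period life tables at the final reported year have the
year+1 survival they need; the synthetic newborn series carries matching
spare years.

## Summary measures

Sullivan expectancies at year *t* use period death probabilities
`q(a) = 1 − N(a+1, t+1)/N(a, t)`; that ratio is a cohort identity only
while the receiving cell is a closed one-year class, so age 94 takes its
death flow `D/N` instead, and the open class closes with a constant hazard
`e₉₅ = 1/m₉₅`, `m₉₅ = D₉₅/(N₉₅ − D₉₅/2)`, with the open-class disability
prevalence applied to that remaining expectation. Deaths are mid-interval
(`L = l − d/2`). ULY is the prevalence-weighted person-year sum; HLY = LE −
ULY identically.

Cohort expectancies follow the baseline cohort down the aggregate diagonal;
a 30-year horizon cannot observe extinction of a 15-year-old cohort, so
beyond the horizon the cohort is continued with the final projected year's
age-specific rates (under the stationary reference this continuation is
exact, and Sullivan and cohort measures coincide to machine precision — a
numerical check of the stationarity equivalence theorem). The truncation
survival share is logged.

## Synthetic data

The generator emulates a cross-sectional health interview survey (ages 15+,
default 20,000 records; weights default to 1), baseline population and
mortality schedules, and a newborn projection:

* **Smoking truth**: the probability of ever having smoked is a quadratic-
  logistic curve in `age/10`, constrained non-decreasing over ages 15–95 —
  a cross-section with a rising never-smoker share would admit no
  non-negative net start flow, contradicting the stationarity construction.
  Current smokers are a declining logistic share of ever-smokers, so current
  smoking peaks in mid-adulthood (~24% for men, ~16% for women at 40) and
  former smoking accumulates with age.
* **Disability truth**: never-smoker log-odds linear in age; ORs 1.8/1.3
  (men, current/former) and 2.0/1.4 (women); disability prevalence rises
  from ~3% at 30 to ~40–45% at 80.
* **Mortality**: Gompertz `q(a) = 1 − exp(−level·e^{slope·a})` with level
  and slope chosen to put male period life expectancy at birth at ~77 years
  and female at ~81 under the deterministic life table — the order of a
  Western European population, deliberately not calibrated to any published
  table. Relative risks of death: 2.1/1.35 (men), 1.9/1.3 (women).
* **Demography**: newborns decline geometrically at 0.2%/year; the baseline
  age pyramid is cohort-consistent with that series and the mortality
  schedule (the 95+ class holds its accumulated stationary count), so the
  reference projection is a stationary population and the stationarity and
  Sullivan-cohort equivalence checks are exact rather than approximate.
* **GALI severity**: disabled records split 70/30 into not-severe/severe;
  only the dichotomy matters downstream. Ages below 15 are never-smokers
  with no disability linkage.

What the generator does **not** emulate: household clustering, nonresponse,
missingness, design weights beyond a per-record scalar, cohort effects in
smoking uptake, or calibration to any real country's margins. Passing tests
therefore demonstrate internal correctness and recoverability under the
stated generating model, not agreement with any published national estimate.

## Problem sizes and tolerances

Parameter-recovery checks use 200,000 survey records (prevalence curves
recovered within 0.02 absolute on ages 20–80, odds ratios within 15%,
observed margins are several times tighter). Engine convergence is checked
at 100/400/1600 simulants per class against the deterministic oracle
(root-n error decay) and at the full 2500 design with a 3-standard-error
band estimated from replicate seeds. Exact identities (mixture
conservation, transition round-trips, disability inversion) are asserted at
1e-10 to 1e-12; stationarity at 1e-8 over the full 30-year horizon. The
routine test suite keeps microsimulations at reduced sizes (60–400 per
class, 10–12-year horizons) — the package's own choice of problem sizes for
its checks — while the full design is exercised in the oracle-equivalence
and population-count tests.

## Known limitations

* Net (not gross) transitions: a net quit flow of zero does not mean nobody
  quits, only that quitting and restarting balance; panel data would be
  needed to separate them.
* The disability linkage is cross-sectional attribution, not an incidence
  hazard; the two coincide only under stationarity of the disability
  process.
* No uncertainty quantification is produced (point estimates throughout).
* Cohort expectancies beyond the horizon assume the final year's rates
  persist; for strongly non-stationary scenarios this understates late
  dynamics.
* The plug-in period life table from a finite microsimulation carries an
  O(1/n) ratio bias per cell; at the default design it is an order of
  magnitude below the Monte Carlo standard error and far below the
  deterministic engine's exactness, which is why the deterministic engine
  is the recommended path for headline numbers.
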
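# Methods

## Projection model

The core is a female-and-male, single-year-of-age, multi-birthplace
cohort-component model on a mid-year Lexis framework. State is a grid of
counts by birthplace × sex × completed age, ages 0 to an open top
interval (default 100+). One projection step applies, per period-cohort
a→a+1, the accounting identity P(t+1) = P(t) − D + I − E, with deaths and
emigration as rates times person-years at risk. Person-years are
approximated by the mean of the start- and end-of-year cohort
populations; since the end population appears on both sides, each cohort
is solved implicitly:

    P_end = (P_start·(1 − (d+e)/2) + I) / (1 + (d+e)/2).

The solution is exact for the linear balance, requires d+e < 2 (enforced
with an explicit error — beyond that the linear exposure approximation
is meaningless for one-year steps), and guarantees P_end ≥ 0 for
non-negative inputs; a clip-to-zero guard with a logged warning remains
for numerical edge cases.

Conventions and choices:

- **Open interval.** The top age is advanced as its own period-cohort:
  survivors remain in it and the cohort ageing from top−1 flows in, both
  through the same implicit balance within a simultaneous step. Whether
  an implementation ages the open interval before or after merging the
  incoming cohort is immaterial here because both cohorts are advanced
  independently and summed.
- **Births.** B = Σ_i Σ_a b[i,a]·½(Pf[i,a](t)+Pf[i,a](t+1)), using
  age-specific (not cohort) female populations at both endpoints. All
  births are credited to birthplace 0 (the native-born): children born
  in-country to overseas-born mothers are native-born by definition.
  Newborns then pass through a birth→age-0 cohort with its own death and
  emigration rates and immigrant newborns, mirroring the half-interval
  exposure logic of the other cohorts. Sex split at birth: 105 males per
  100 females, configurable.
- **Immigration.** Treated as flows, not rates — inflows respond to
  policy, not to the resident population at risk. Each projection year
  the base age-sex-birthplace flow pattern is rescaled uniformly so its
  sum equals the national total for that year (a linear trajectory by
  default, extrapolated from the scenario's totals if the horizon runs
  past them). Arrivals are assumed to carry no within-year exposure to
  the resident rates beyond what the implicit balance assigns to the
  receiving cohort.
- **Emigration** uses the same person-years formulation as deaths, and
  its base rates stay constant over the horizon, as do fertility rates.

## Mortality assumptions

Mortality enters as life expectancy at birth. A period life table is
built from single-year death rates with qx = mx/(1+(1−ax)mx), ax = 0.5
except a0 = 0.1 (infant deaths cluster early in the first year), and
open-interval person-years L = l/m. Target e0 values are hit by uniform
proportional scaling of the whole schedule, solved by bisection on the
log scaling factor over [1e-6, 1e6] to 1e-6 years (max 200 iterations);
e0 is strictly monotone in the factor, so the bracket is verified up
front and unreachable targets report the achievable range. Proportional
scaling is this package's choice of relational model; it keeps the age
pattern fixed while shifting the level.

Projected targets follow a national trend plus fixed birthplace-sex
differentials: e0[i,s](t) = e0[i,s](0) + g(t), evaluated mid-period
(t+½) for the rates applied during year t. The trend g is pluggable —
linear (default 0.15 years/year, a continuation of long-run national
improvement) or damped-linear with a geometric damping factor. An
optional sex-convergence setting shrinks each birthplace's female–male
e0 gap linearly to a chosen fraction of its initial size by horizon end,
leaving the birthplace mean on trend. The fixed-mortality variant simply
freezes the jump-off schedules; under proportional scaling this is
equivalent to freezing e0 and re-deriving rates.

## Age disaggregation (IPF)

Grouped-age tables are split to single years by iterative proportional
fitting of a detailed single-year seed to the grouped totals. The IPF
core is general n-dimensional: marginals are swept in listed order,
convergence is the maximum relative marginal discrepancy (default tol
1e-8, max 1000 iterations), structural zeros are never revived, and
infeasible positive targets over all-zero seed slices are detected
before iterating. Age splitting routes each birthplace-sex age vector
through the same core by scattering ages into a (group × offset) matrix,
making group totals an ordinary axis marginal. With only group marginals
binding, the result is exactly proportional scaling within each group,
so a noiseless seed is recovered identically.

## Base-period migration calibration

Projecting the start-of-base-period population forward n years with
base-period rates should land on the end-of-period population. The
calibration adjusts immigration only — one scale factor per (birthplace,
sex), solved by an element-wise secant iteration (max 50 rounds, tol
1e-6 relative on birthplace-sex totals). The projection response to the
factors is almost exactly linear (the only coupling is the fertility
feedback of overseas-born mothers into the native-born), so convergence
takes a handful of rounds. Factors driven below zero mean the target is
unreachable by scaling inflows and raise an error suggesting emigration
adjustment instead. During calibration the inflows act as base-period
volumes: the national-total constraint applies to future projection
years, not to the historical reconciliation window. An optional second
pass tilts the inflow age profile by the target/projected ratio at each
age (clipped to [0.2, 5]) and re-normalises per birthplace-sex through a
one-marginal IPF before re-solving the scalars; diagnostics expose the
remaining age-level discrepancy rather than forcing it to zero, since
the inverse problem at age level is underdetermined.

## Growth decomposition

Growth G of the population aged ≥65 (configurable) between jump-off and
horizon end is attributed by variant projections sharing all other
assumptions: the life-expectancy contribution is G_main − G_fixed-e0,
the migration contribution is G_main − G_no-migration, and cohort flow
is the residual closing the identity exactly. The no-migration variant
zeroes **both** immigration and emigration — emigration is part of
international migration, and without it net-loss groups could not show
negative migration contributions. The scheme ignores the
mortality–migration interaction; an optional fourth variant (both
switched off) reports that interaction separately as
(G_main − G_both) − (ΔLE + Δmigration). Decomposition is linear over
birthplaces, so aggregates equal sums of members. Shares are reported as
percent of total growth, rounded half-away-from-zero to whole percent by
default.

## Synthetic scenarios

The generator emulates the structure of real migration-wave inputs
without reproducing any actual population:

- **Overseas-born jump-off stocks** accumulate a wave of constant annual
  arrivals between a start and end year, each arrival cohort depleted by
  the group's Gompertz hazard μ(x) = α·exp(βx) to the jump-off date;
  ages past the top fold into the open interval. A wave that ceased
  decades ago therefore yields an old-skewed stock with nobody below
  (jump-off − wave-end) years of age; a still-running wave yields a
  young-adult-skewed stock.
- **Native-born stock** is a stationary-population approximation:
  constant annual births survived to jump-off. Only the cohort-size
  contrast with the wave populations matters for exercising cohort flow,
  so no baby-boom structure is imposed.
- **Age-at-arrival distribution** is unimodal with mode in the 20s:
  a discretised gamma (shape 7, scale 4.5) by default, a triangular
  alternative configurable — migration above age 45 is small.
- **Mortality schedules** are Gompertz hazards at interval midpoints,
  rescaled so each group's e0 equals the national value (birthplace 0's
  schedule) plus its configured differential, with a fixed 4.0-year
  female–male gap split symmetrically.
- **Emigration rates** are a small base level with a young-adult
  Gaussian peak (≈2.5%/year at 25 before group scaling); **fertility**
  is a Gaussian-shaped schedule over ages 15–49 scaled to the group TFR
  (defaults below replacement, 1.6–2.0).
- **Base inflows** equal the wave scale for still-open waves, a 5%
  residual trickle for ceased waves, and an 8%-of-births return flow for
  the native-born; 0.5% of each inflow arrives as newborns. The national
  total trajectory rises linearly (default 200,000 + 2,500/year for the
  5-birthplace default scenario).
- **Census-seed noise** is multiplicative lognormal (default σ = 0.05),
  chosen to preserve positivity for IPF; σ = 0 reproduces the truth
  bit-for-bit. It is a stand-in for seed/total mismatch, not a model of
  any agency's error structure.

All randomness (inflow sex shares, seed noise) derives from a single
root seed through spawned substreams, so identical configurations give
bit-identical bundles. What the generator does **not** emulate: real
category sizes, intercensal error, second-generation (parents'
birthplace) structure, non-constant wave intensities, or baby-boom
fertility history. Passing tests therefore demonstrate the machinery's
correctness and its qualitative behaviour on wave-structured
populations, not agreement with any country's published projections;
in particular the default scenario's driver shares need not match those
of any real population.

## Problem sizes and numerics

The test suite and the acceptance script run compact configurations
chosen to exercise every code path: 3-birthplace bundles with top age 85
for unit tests, 20 five-birthplace scenarios with top age 100 projected
40 years for the accounting-identity sweep, and horizons of 3–8 years
where only correctness of the arithmetic is at stake. The accounting
identity holds to ~1e-15 relative (pure floating-point error); the
acceptance threshold of 1e-9 leaves ample headroom. Exact-equality
oracles (cohort shift) round jump-off counts to whole persons first so
that partial sums are exact in double precision.

## Known limitations

- Deterministic only: no stochastic projection intervals.
- Proportional mortality scaling cannot change the age pattern of
  mortality, so very large e0 targets distort qx at old ages before the
  bracket error triggers.
- The migration effect in the decomposition bundles immigration and
  emigration; separating them would need a third variant.
- Calibration reconciles levels by birthplace and sex; age-level
  residuals are reported, not eliminated.
- No subnational geography and no second-generation tracking.
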
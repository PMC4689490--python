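# Methods

## The model

`epiburden` estimates the burden of a chronic condition — developed around
convulsive epilepsy in a rural health and demographic surveillance system
(HDSS) cohort — as disability-adjusted life years (DALYs):

    DALY = YLL + YLD

with years of life lost

    YLL = Σ deaths(a) · ex(a)

(`ex` the remaining expectancy of a standard life table at the age of death),
and years lived with disability computed under either convention:

    YLD_p = prevalent cases · DW          (prevalence-based, GBD 2010)
    YLD_i = incident cases · D · DW       (incidence-based, earlier GBD rounds)

where DW is a disability weight in (0, 1) and D the expected duration of
disease. No age weighting and no time discounting are applied anywhere; the
package deliberately has no discount parameter at all, so the undiscounted
convention cannot be switched off silently.

The two YLD conventions agree only when prevalence equals incidence times
duration — true in a stationary population with age-constant rates. The
pipeline computes both and reports the percent gap, which is the
substantively interesting output when the age structure is in transition.

### Illness-death consistency engine

Surveillance systems measure prevalence, incidence and mortality with
sampling noise and on different denominators; the quantities are rarely
mutually consistent. Consistency is restored through the generic three-state
illness-death model. Along age `a` the fractions alive without disease `W(a)`
and with disease `C(a)` obey

    dW/da = −(i+m) W + r C
    dC/da =  i W − (r+m+f) C

with band-constant hazards: incidence `i`, remission `r`, excess mortality of
cases `f`, background mortality `m` (all per person-year). Derived outputs:
prevalence `p = C/(W+C)`, the standardized mortality ratio `SMR = (m+f)/m`,
and duration `D(a)`, the expected remaining sojourn in the disease state
under exit hazard `q = r+m+f`.

`fit_consistent` minimises, by bounded trust-region least squares, the
weighted discrepancy between the forward solution's band-level summaries
(mean prevalence; population incidence rate `i(1−p̄)`; cause-specific death
rate `f·p̄`; remission) and the observations, with inverse-variance weights
when standard errors are supplied and proportional weights otherwise. At
least three observed quantities per sex are required; with fewer the system
is underdetermined and rejected. A cohort with no observed disease returns
zero hazards flagged `unidentified` rather than pretending `r` and `f` were
estimated.

`m` is taken directly from the observed all-cause mortality rate. Strictly
it is background (non-cause) mortality, but for a condition with prevalence
of a few per 1,000 the cause-attributable share of all-cause deaths (`f·p̄`,
about 0.5% here) is far below the sampling error of `m`, the same
approximation consistency tools conventionally make for rare conditions.

## Numerical choices

* **Integration.** Fixed-step classical RK4 on a 0.1-year grid from the
  first band's lower bound to an age cap of 100 years (the open 50+ band is
  truncated there). For a linear autonomous system RK4's update is the
  4th-order Taylor polynomial of `expm(hA)`; because hazards are constant
  within bands the step matrix is constant per band, and the trajectory is
  evaluated through closed-form matrix powers (eigen decomposition, with the
  exact Jordan form for a repeated eigenvalue). This is bit-identical to the
  stepwise RK4 recursion, reproducible, and fast enough for simulation
  studies. Local truncation error at these hazard magnitudes (≤ 0.1/yr) is
  far below the 1e-4 relative tolerance asserted against the closed forms
  `p(a) = 1 − exp(−i a)` (r = f = 0) and `D = 1/q`.
* **Duration tail.** `D(a)` is computed by exact backward recursion over the
  piecewise-constant exit hazard, with an analytic exponential tail beyond
  the age cap using the terminal band's hazard, so constant-hazard durations
  equal `1/q` regardless of the cap. With `q = 0` the tail is truncated at
  the cap and an all-zero incidence cohort reports duration 0 ("undefined as
  zero").
* **Degenerate inputs.** `m = 0` with `f = 0` reports SMR 1; `m = 0` with
  `f > 0` reports SMR ∞ rather than failing. Prevalence is clamped to [0, 1]
  against rounding at the 1e-15 level.
* **Smoothing.** Band-level quantities can be carried to continuous age by
  piecewise-linear interpolation of band midpoints, a window-3 moving
  average over bands (shrunk at the edges, so constants are preserved), or a
  natural cubic spline through midpoints clamped outside the outermost
  midpoints. Smoothing is presentational; the solver itself uses
  band-constant hazards, matching how band-level inputs are reported.
* **Fit warm start.** `i ≈ inc/(1−p̄)`, `f ≈ cmort/p̄`, and `r` from the
  local steady state; with consistent inputs the optimiser converges to
  machine precision, and under 5% observation noise the median relative
  error of recovered incidence is a few percent.

## Uncertainty

Two stages are exposed and deliberately not nested by default:

* **Monte-Carlo consistency stage** (`propagate_uncertainty`): inputs are
  redrawn per iteration from independent normals truncated at zero (rates
  cannot be negative), the fit re-run, and 2.5/97.5 percentiles reported.
  Default 1,000 iterations, seed 20151223 (seeding is a required,
  recorded configuration field).
* **Bootstrap burden stage** (`bootstrap_interval`): stratum event counts
  are redrawn from Poisson distributions centred on the observed counts
  (rare events on person-time denominators; a configurable alternative
  draws rates from parametric truncated normals instead), the burden
  statistic recomputed, and percentile intervals formed. Percentile rather
  than BCa: the simplest method consistent with mildly asymmetric intervals.
  Replicates on which the statistic fails are dropped and counted; more than
  5% failures aborts.

On synthetic cohorts with known truth the 95% bootstrap intervals for
prevalence-based YLD cover the true value in ≈95% of replicates (asserted at
93–97% over 500 replicates, binomial tolerance).

## Synthetic cohorts

`generate_cohort` emulates a 2-sex × 6-band HDSS follow-up study: expected
stratum counts (person-years; all-cause, cause-specific deaths; prevalent
cases at baseline; incident cases over follow-up) come from the forward
solution with a uniform within-band age distribution, and realised counts
are Poisson. Default study conditions mirror the packaged surveillance
fixtures: band populations equal to the observed person-years divided by the
4-year follow-up (≈75,000 people), fixture-level incidence (13–30 per
100,000 py), remission, all-cause mortality (0.9–44 per 1,000 py) and excess
mortality backed out of the band SMRs as `f = (SMR−1)·m`. Loss to follow-up
is available as a uniform person-time thinning and defaults to off (no rate
is published for the source cohort).

What the generator does **not** emulate: in-migration and ageing across
bands during follow-up, village-level clustering, screening sensitivity of
the three-stage case-finding, and within-band age gradients. Passing tests
therefore demonstrate correctness of the estimators under idealised
sampling, not robustness to those field realities.

Problem sizes used in the shipped simulation studies — 100 replicates for
noisy parameter recovery, 500 replicates × 1,000 bootstrap iterations for
coverage — were chosen to make the binomial/Monte-Carlo tolerances in the
assertions meaningful while keeping a default test run interactive.

## Fixtures and reporting conventions

The packaged Agincourt tables (demography/all-cause mortality; consistency-
model outputs with 95% UIs; the prevalence-method burden table; the all-ages
method-comparison inputs) are fixtures: the consistency outputs came from
DisMod II, whose proprietary smoothing and fit internals this package does
not attempt to replicate, and the per-band ages of the epilepsy deaths
behind the published YLLs are not public. Consequently the fixture burden
cells feed downstream stages but are not recomputation targets. Two source
quirks are preserved deliberately: the female 0–5 duration interval is
stored as missing (unparseable in the source), and the "standardized
mortality rate" column is interpreted as a ratio.

All arithmetic is in full precision; tables round to 1 d.p. and headline
percentages to integers only at presentation. Deaths reported per band are
assigned the band midpoint age by default (configurable to the lower or
upper bound). The packaged standard life table is the GBD 2010 reference
table (86.02 years at birth, identical for both sexes) and is swappable via
configuration for any `age,ex` CSV.

## Known limitations

* Band-level (ecological) fitting only; no individual event histories.
* The WLS consistency fit reports a discrepancy but no goodness-of-fit test;
  structurally inconsistent inputs (as the fixture tables are, having been
  produced by a different engine) yield a best compromise, not a diagnosis.
* Remission is weakly identified when it is not directly observed and
  prevalence is nearly flat in age.
* The DW sensitivity scan rescales uncertainty bounds linearly rather than
  re-bootstrapping per weight — exact for points, an approximation for
  interval endpoints.
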
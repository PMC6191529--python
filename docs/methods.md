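# Methods

## Model

`flsim` is a patient-level discrete event simulation (DES) of the
remitting–relapsing follicular lymphoma (FL) treatment pathway. Each
simulated patient receives baseline attributes (age at diagnosis, sex,
disease stage, FLIPI category, initial management) and is then advanced
event by event: in every health phase, a time is sampled for each event
that could happen next and the earliest one wins (a competing-risks race).
There are no fixed model cycles; time is continuous, measured internally in
days (1 year = 365.25 days).

Phases and legal transitions:

```
pretreatment ──► watch & wait (W&W) ──► first-line treatment ──► ...
      │                │ │                    │ │
      │                │ └─ transformation    │ └─ death / transformation
      │                └─── death             └─── remission
      └─► end-of-life (untreated) ──► death

treatment line L ──► remission L (response) | treatment L+1 (refractory)
remission L     ──► treatment L+1 (relapse) | transformation | death
```

Transformation to diffuse large B-cell lymphoma (DLBCL) is an absorbing
exit: the FL model stops and a configurable economic add-on (expected cost,
life-years and QALYs of the post-transformation course) is booked at the
transformation date. Treatment lines beyond the third reuse line-3
parameters, reflecting the sparsity of observed post-third-line treatment.
A stem cell transplant (autologous or allogeneic) can occur once, on entry
to any line ≥ 2. Simulation stops at death, transformation, age 100, or a
configured horizon; horizon truncation is recorded as censoring, so
finite-horizon life-years are restricted means.

## Time-to-event machinery

Six parametric families are supported: normal (left-truncated at zero and
renormalized when used as a time distribution), exponential, Weibull
(S(t) = exp(−(t/σ)^k)), gamma (shape/scale), log-normal, and log-logistic
(S(t) = 1/(1 + (t/σ)^k)). Sampling is by inverse transform, t = S⁻¹(u^{1/h}),
which is exact proportional hazards for any baseline: a hazard ratio h acts
as S(t)^h. For the exponential and Weibull families the transform folds into
the parameters (rate·h; scale·h^{−1/k}); other families carry h symbolically.
An accelerated-failure-time hook lets covariates rescale time through
exp(Σβx); the default parameterization does not use it, since no
covariate-specific coefficients are publicly available. Tail quantiles use
the complementary normal inverse (−ndtri(p)) to stay accurate when hazard
ratios push probabilities deep into the tails.

Censored maximum likelihood uses log f for events plus log S for
right-censored rows, optimized on log-transformed positive parameters
(Nelder–Mead from method-of-moments starts, polished by BFGS, tolerance
1e-8; the exponential rate has the closed form events/exposure). The
coefficient covariance is the inverse finite-difference observed information
on the fitting scale, so multivariate-normal uncertainty draws map back to
valid (positive) parameters. Families are ranked by AIC = 2k − 2logL, with
BIC = k·ln(n) − 2logL reported alongside; ties break toward fewer
parameters, then a fixed family order. Kaplan–Meier estimation is delegated
to `lifelines`.

## Parameterization

The default configuration (`flsim/data/default_fl.yaml`) carries the
published FL values: the Weibull(5.57, 69.33) age-at-diagnosis distribution
(mean 64.0 years, truncated by rejection to [18, 100]); per-age-band Beta
counts for sex and W&W induction-rituximab decisions and Dirichlet counts
for the five-way initial-management split; Beta-distributed phase utilities;
and 2016 GBP unit costs (per-cycle chemotherapy regimens, radiotherapy
planning and fractions, transplants, outpatient tariffs; £1 = US$1.2505).
Where printed category proportions disagree with their own count weights,
the counts are authoritative for sampling. The age-band lookup places the
boundary age 30 in the youngest ("≤30") band and treats interior bands as
[lo, hi).

Quantities that are not publicly printed are shipped as documented fixtures,
flagged `fixture: true` in the configuration and logged at run time:

* every transition time-to-event specification (the fitted parameters are
  not public). Fixtures were chosen once for qualitative plausibility — e.g.
  W&W→treatment log-normal with median 2.5 years and a heavy tail,
  end-of-life survival exponential with mean 75 days (matching the ~0.21
  life-years reported for untreated patients), remission and mortality
  Weibulls with means of roughly a decade — and produce a cohort whose
  subgroup mix, life expectancy (~8–9 LY) and cost ordering are of the
  published order without reproducing its magnitudes;
* the diagnostic work-up bundle (£1,200), end-of-life daily cost (£80),
  monitoring frequency (4 follow-up visits/year), radiotherapy fraction
  counts (15 localized / 5 palliative), cycles per regimen (6), per-line
  regimen mixes, stage-IA prevalence (10%), and the rituximab monotherapy
  administration cost (£1,260 = the R-CVP minus CVP per-cycle difference;
  the analogous differences for other regimens disagree, so this is a
  default, not a claim);
* the DLBCL add-on (£22,000, 11.5 LY, 8.0 QALY per transformation), sized so
  the cohort-level gap between FL-only and FL+DLBCL outcomes is of the
  published order given a ~20–25% lifetime transformation fraction.

Tests that touch fixture-driven magnitudes are property-based (orderings,
partitions, conservation laws), never value-matching.

## Economics

Continuous accrual over [t0, t1] years is discounted with the closed form
((1+r)^{−t0} − (1+r)^{−t1})/ln(1+r) (default r = 3.5%/year); point costs at
t are weighted (1+r)^{−t}. Continuous discounting is used rather than
annual-step discounting because DES event times are continuous and step
weights would create artifacts at phase boundaries. Chemotherapy cycle costs
are booked as a lump at treatment start (the within-phase timing is not
specified in the source data); radiotherapy books planning plus per-fraction
costs; monitoring accrues during W&W and remission; end-of-life care accrues
per day. Resource decisions (regimen, fractions, transplant type, rituximab
administrations) are made by the pathway engine and carried on the event
records; the economics layer only prices and discounts them, so a trajectory
can be re-costed under different unit costs, rates or horizons.

## Cohort analyses and uncertainty

The incidence analysis simulates a closed cohort (default 1860 patients, the
expected UK annual case load) over horizons of 5–30 years and lifetime,
reporting per-subgroup means (W&W only / first line only / second line plus
with and without SCT / not treated, plus "treated" and "total" aggregates)
with 95% percentile intervals across Monte Carlo iterations. The prevalence
analysis is an open cohort: arrivals at the annual incidence (Poisson by
default; deterministic spacing available for validation oracles) over a
burn-in (default 30 years) plus a 1-year observation window; the annual
burden is the undiscounted cost accrued inside the window by anyone alive in
it, the literal reading of "treating new and existing patients in a year".

Probabilistic sensitivity analysis redraws, once per iteration before the
first-order patient draws: Beta proportions, Dirichlet management mixes,
Beta utilities, and — where a fitted covariance is attached by calibration —
multivariate-normal survival coefficients on the fitting scale. Fixture
transitions without a covariance fall back to point values with a logged
warning. Intervals are 2.5–97.5 percentiles across iterations. All
randomness descends from one master seed through `SeedSequence` spawning:
one stream per iteration, two per patient (pathway and scenario decisions),
which makes runs bit-reproducible and guarantees that policy scenarios leave
the event streams of unaffected patients untouched.

## Policy scenarios

Scenario "induction_ww": newly diagnosed W&W patients (excluding the ~2%
already receiving induction rituximab in the base case) take up with the
configured probability; taking up applies HR 0.35 (95% CI 0.22–0.56) to the
W&W→treatment time and books 4 weekly rituximab administrations. Scenario
"maintenance": treatment responders take up with the configured probability;
each remission applies HR 0.55 (95% CI 0.44–0.68) to the relapse time and
books one administration every 2 months for at most 24 months (doses at
months 2, 4, …, 24; min(⌊m/2⌋, 12) doses for an m-month remission). In PSA
the log hazard ratio is drawn normal with sd (ln U − ln L)/3.92. The HR is
applied to time-to-next-treatment only, not to survival. Scenario deltas are
reported per uptake level against a base run sharing configuration and
seeds; whether a scenario saves money net of its dosing costs depends on the
fixture cost/TTE magnitudes, so only the mechanism (delay of treatment
starts) is asserted, not the sign or size of the published savings.

## Synthetic registry and calibration

Because the underlying population registry is confidential, `generate_registry`
emulates its observational structure from a known parameter set: uniform
accrual over 7 years (default 740 patients), 4 further years of follow-up,
administrative right-censoring at the calendar end of follow-up, and flat
per-transition rows in which competing events censor each other (the losing
candidates of each phase visit contribute right-censored rows at the
winner's sojourn time). `calibrate` replays the estimation workflow — all
six families fitted per transition with AIC selection, attribute Betas and
Dirichlets re-estimated as raw observed counts — and `recovery_report`
compares generating and recovered specifications (families, parameters,
survival-curve sup distances, KM overlays).

The round trip (simulate registry → calibrate → re-simulate) is evaluated
under common random numbers on the truth and recalibrated arms: per-patient
lifetime cost is extremely dispersed (its standard deviation exceeds its
mean, driven by allogeneic transplants and long multi-line tails), so
without CRN two independent comparison cohorts differ by several percent
from first-order noise alone. At the study's size (740 patients, ~69% of
transition rows censored) the recovered mean cost varies around truth with a
standard deviation of roughly 6% across registry replicates; a single
replicate can therefore miss 10% (≈1 in 10 does), while the error averaged
over replicates is well inside it. Life-years are recovered within a few
percent throughout. Transitions with fewer than 2 observed events retain
their prior specification with a warning.

## Problem sizes and numerical choices

Default API sizes match the study (1860 patients/year, 1000 PSA iterations,
30-year burn-in); the test suite and the acceptance script run scaled-down
versions chosen for statistical resolution at interactive run times (e.g.
5 incidence iterations of 1860 patients; 2 prevalence iterations; oracle
checks at 20,000–100,000 draws). Oracle tolerances follow the statistics
involved: 3 standard errors for frequency checks, 0.015 absolute for
occupancy against the matrix-exponential Markov solution, 5% for Little's
law on a short-sojourn configuration where a 5-year burn-in genuinely
reaches steady state (the realistic parameterization has sojourns up to ~80
years, so no practical burn-in is fully stationary — a property of the
disease model, not of the implementation). Exact ties in the event race are
broken death > transformation > response > relapse; they occur with
probability zero under continuous sampling and matter only for degenerate
configurations.

## Known limitations

* All fixture time-to-event magnitudes are placeholders: absolute costs,
  life expectancy and scenario savings are of the right order but are not
  reproductions of the published tables.
* Mortality is not age-modulated in the default fixtures (the AFT hook
  exists but no coefficients are shipped); very old patients are therefore
  handled by the age-100 cap rather than by rising hazards.
* The DLBCL add-on books expected post-transformation totals at the
  transformation date (discounted by the point weight at that date), which
  overstates early-horizon totals slightly compared with simulating the
  post-transformation course event by event.
* No left truncation or interval censoring in the fitting machinery; no
  spline/flexible parametric families.
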
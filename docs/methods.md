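# Methods

## The model

Time use is compositional: a worker's day is budgeted across behaviors, so
only relative information is meaningful. The package represents a worker's
average workday by two compositions — work = (MVPA, sedentary, standing,
LIPA) and leisure = (MVPA, sedentary, standing, LIPA, time in bed) — each
closed to its own mean daily duration. Work and leisure are deliberately
*not* treated as sub-compositions of the 1440-minute day: their totals are
externally fixed (contracted hours), and minutes cannot realistically be
moved between domains. A whole-day sensitivity mode (all nine parts as one
composition, eight pivot coordinates) is available through
`composition_mode="whole_day"`.

Each D-part composition enters the regression through pivot isometric
log-ratio (ilr) coordinates built from the sequential binary partition
that splits off one part at a time in the listed order, MVPA first:

    z_k = sqrt((D-k)/(D-k+1)) * ln( x_k / geomean(x_{k+1}, ..., x_D) )

The first coordinate is therefore "MVPA relative to everything else in the
same domain", which is the coefficient of scientific interest; the later
coordinates complete an orthonormal basis so that the remaining relative
information is fully adjusted for. The contrast matrix rows are orthonormal
and sum to zero (property-tested for D = 2..8).

The outcome is first-event long-term sickness absence (LTSA): the first
run of at least `min_run = 6` consecutive sickness weeks in a weekly
benefit register, with the whole qualifying run required to fit inside the
`horizon = 212` weeks of follow-up. The register's shortest representable
spell is 5 weeks, so 5-week runs are exactly the hardest negative case and
the synthetic register plants them deliberately. Event time is the run's
start week (risk ends when the spell begins); dating the event at the
qualifying run's end is available via `event_timing="end"` since either
convention is defensible. Censoring reasons are emigration, death, early
or ordinary retirement at the week their code appears, and pregnancy,
back-dated 35 weeks (eight months: 8 x 30.44 / 7, rounded) from the
maternity-leave code, floored at week 1 and applied to women only. The
earliest censoring time binds; a tie between an event and a censoring code
in the same week goes to the event, which is observed within that risk
week.

Hazards are modelled as Cox proportional hazards on the 3 + 4 ilr
coordinates plus confounders (age in years, sex, BMI, smoking status,
occupational lifting/carrying duration 1-6 entered as a single numeric
covariate; optionally two socioeconomic-status indicator columns against a
white-collar reference). Weekly event times produce heavy ties, so the
Efron correction is the default (Breslow available for comparison).

## Estimation and inference

The partial likelihood is maximized by Newton-Raphson from beta = 0 with
step-halving on any likelihood decrease; convergence requires a gradient
max-norm below 1e-9 (at most 50 iterations). The covariance is the inverse
observed information at the optimum. A rank check with column-pivoted QR
rejects collinear model matrices naming the offending columns, and runaway
coefficients (|beta| > 50) are flagged as suspected monotone likelihood
rather than reported as converged. Per-coefficient inference is Wald
(z = beta/se, two-sided normal p).

Proportionality is tested with the Grambsch-Therneau score test: Efron-
weighted Schoenfeld residuals s_k at each event, scaled as
s*_k = d * s_k * V (d = number of events, V = estimated covariance, i.e.
the classical average-information approximation V_bar ~ I/d), regressed on
a transform g(t) of event time. Per covariate the statistic is
[sum (g - gbar) s*_j]^2 / (d V_jj sum (g - gbar)^2) on 1 df; the global
statistic is d u' V u / sum (g - gbar)^2 with u = sum (g - gbar) s_k on
p df. The default transform is the Kaplan-Meier transform g = 1 - KM(t)
(also `rank` and `identity`), chosen because it is constant within tied
weeks — under weekly ties this makes the statistic invariant to the
arbitrary ordering of tied events, which exact cross-library comparison
requires. This is the pre-2019 approximation used by the established zph
implementations; the test suite verifies agreement with an independent
implementation to 1e-6.

Null calibration is verified by simulation: with all planted coefficients
zero, the Wald test on the first work coordinate and the global
proportionality test both reject at 5.0% +/- Monte-Carlo error across
1000 replicates of 200-worker cohorts.

## Substitution effect sizes

Effects are translated to the time scale by compositional isotemporal
substitution around the sample compositional mean (part-wise geometric
means closed to the cohort's mean domain duration). A reallocation of
`delta` minutes into the focal behavior removes them from the remaining
parts proportionally to their base minutes, preserving the non-focal
subcomposition and the domain total exactly. Proportional removal (rather
than equal minutes per remaining part) was chosen because it keeps the
remaining behaviors' relative structure fixed, so "MVPA versus everything
else" is the only contrast that moves: under the pivot basis only the
first ilr coordinate changes, making the planted-coefficient inversion
(below) exact. The predicted hazard ratio is exp(Dz' beta) with Dz the ilr
difference padded with zeros over non-domain columns; its 95% CI is the
delta method on the linear predictor, exp(Dz' beta -+ 1.96 sqrt(Dz' V Dz)).
The default grid is -30..+30 minutes in 5-minute steps. Note that
HR(+d) * HR(-d) = 1 holds only to first order for the proportional-removal
path; the tests assert reciprocity within 1% for |d| <= 5 minutes only.

## The synthetic cohort

The generator emulates the structure of a blue-collar accelerometer cohort
linked to a weekly benefit register; its defaults are the study
conditions and are not tuned per run.

* **Compositions.** Worker-level work and leisure compositions are
  Dirichlet with precision 100. The published descriptive means are
  *compositional* means, so the Dirichlet parameters are solved (inverse
  digamma, Newton) such that the cohort's compositional mean converges to
  the configured means — work (64, 176, 137, 74) of 451 min, leisure
  (33, 311, 77, 41, 429) of 892 min — rather than placing them at the
  arithmetic mean. Domain totals are truncated normals: work N(451, 80)
  >= 223 min, leisure N(892, 109) >= 536 min. Precision 100 is a free
  choice (no dispersion is published for the behavior minutes); it gives a
  between-worker SD of roughly 0.25 on the first work pivot coordinate.
* **Days.** Each worker contributes 4 days. Day-level behavior minutes are
  the worker's composition times independent lognormal noise
  (sigma = 0.05 per part), split into raw accelerometer classes with fixed
  fractions (e.g. work MVPA = 75% fast walking, 20% stair climbing, 5%
  running; leisure MVPA additionally 25% cycling; work cycling is not
  generated, matching its exclusion from work MVPA). 5% of days are
  non-workdays and 8% are invalidated by one of three mechanisms (work
  wear < 4 h, leisure wear < 75% of the worker's average, time in bed
  < 4 h) to exercise the validity screening. The 0.05 day-level sigma
  deliberately understates real day-to-day behavioral variation: the
  generator's purpose is to verify the pipeline's correctness (merging,
  validity, aggregation, estimation), not to model accelerometer
  reliability, and recovery results should be read accordingly.
* **Events.** The weekly hazard is lambda0 * exp(eta) with eta linear in
  the worker's true pivot coordinates. Interpretable targets — HR 1.15
  per +20 min work MVPA, HR 0.80 per +20 min leisure MVPA — are inverted
  into first-pivot coefficients via beta1 = ln(HR)/Dz1 at the configured
  mean composition (exact by construction, since proportional reallocation
  moves only the first coordinate). lambda0 is calibrated by root-finding
  so that the mean probability of an event run *starting early enough to
  qualify* (start week <= 207) equals the 21% target incidence. Event
  workers receive a sickness run of 6 + geometric extra weeks.
* **Censoring and decoys.** Censoring codes are assigned to workers
  without a planted event with total probability 5% (uniform week 1..212;
  reasons emigration 1.5%, pregnancy 1.5% — women only, emitted as a
  maternity code 35 weeks later so the register module does the
  back-dating — ordinary retirement 0.9%, early retirement 0.8%, death
  0.3%). Attaching censoring to the non-event stratum makes the planted
  rate directly identifiable as "censored fraction among workers without
  an event"; the cost is that generated censoring never truncates a
  planted event, a rule exercised instead by constructed register
  fixtures. 10% of non-event workers receive a decoy 5-week spell.
* **Confounders** (age N(44.9, 9.7), 45% women, BMI N(27.1, 4.8), 30%
  smokers, lifting 1-6 with mean 3.9, SES 19/39/42% with 12.7% missing)
  are generated independent of the compositions, so SES-adjusted and
  unadjusted estimates agree up to noise — a testable null; dependence can
  be introduced through the planted-coefficient hooks.

## Numerical choices and degenerate inputs

* Closure and ilr round-trips are exact to 1e-9 relative tolerance
  (double precision, D <= 5).
* Zero part durations are repaired by multiplicative replacement with
  delta = 0.5 min — half the 1-minute resolution of the day-level
  summaries — before any log-ratio; delta must stay below the smallest
  non-zero part, and all-zero compositions are rejected as degenerate.
* Aggregation requires at least one day that is simultaneously work-,
  leisure- and bed-valid; workers failing this are excluded with a reason
  code and exclusion counts are conserved across the pipeline.
* The wear-time validity reading maps ">= 4 h" to the work period and
  ">= 75% of average wear" to the leisure period; both thresholds are
  configuration fields should the opposite mapping be wanted.
* Infeasible substitution grid points (delta exhausting a part) are
  dropped with a warning, never silently.

## Problem sizes used in the checks

Parameter recovery averages 50 cohorts of n = 929 workers (about 190
events each); the null-calibration simulation uses 1000 replicates of
n = 200; oracle-equivalence checks run on datasets of n <= 200 against an
independent survival library and on 1000 random register series against a
brute-force window scan. These sizes give Monte-Carlo standard errors
comfortably below the effects being verified while keeping the default
test run to a few minutes.

## Known limitations

* The generator does not model within-worker autocorrelation across days,
  seasonal patterns, wear-time diaries, or realistic accelerometer
  misclassification; passing recovery demonstrates pipeline correctness,
  not robustness to those features of real data.
* Day-level inputs are assumed to be already non-wear-cleaned summaries;
  raw signal classification is out of scope.
* The Cox implementation covers time-fixed covariates only (no frailty,
  no time-varying effects); the baseline hazard is left unestimated except
  for a Breslow estimator used in simulation checks.
* Pregnancy back-dating uses a fixed 35-week lead; calendar effects are
  ignored (the register is indexed by follow-up week, not date).
* With ~190 events the partial-likelihood estimate of the leisure
  first-pivot coefficient carries a small finite-sample magnitude
  inflation (order 4%), visible only when averaging many replicates; it is
  well inside the recovery tolerances.
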
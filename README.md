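# codaltsa

Compositional accelerometer time-use analysis of long-term sickness absence
(LTSA). The package is aimed at occupational and time-use epidemiologists
who want to test "physical activity paradox"-style questions — does
moderate-to-vigorous physical activity (MVPA) at work carry a different
prognosis than MVPA in leisure? — with device-measured behaviors, a
register-based outcome, and statistics that respect the compositional
nature of time use.

## What it computes

A worker's day is summarized as two compositions of behavior minutes:

* **work**: (MVPA, sedentary, standing, LIPA), closed to the work duration;
* **leisure**: (MVPA, sedentary, standing, LIPA, time in bed), closed to
  the leisure duration.

Each composition **x** with D parts enters the hazard model through its
pivot isometric log-ratio (ilr) coordinates

```
z_k = sqrt((D-k)/(D-k+1)) * ln( x_k / ( x_{k+1} * ... * x_D )^(1/(D-k)) ),   k = 1..D-1
```

so z_1 contrasts MVPA against the geometric mean of the remaining
behaviors. The outcome is the first run of >= 6 consecutive sickness-
absence weeks in a weekly benefit register within a 212-week follow-up,
with censoring for emigration, death, retirement and (back-dated)
maternity leave. The association is estimated with a Cox proportional-
hazards model (Efron ties, Newton–Raphson on the partial likelihood)

```
h_i(t) = h_0(t) * exp( z_i(work)' b_w + z_i(leisure)' b_l + c_i' g )
```

adjusted for age, sex, BMI, smoking, occupational lifting/carrying and,
optionally, socioeconomic-status indicators; proportionality is checked
with the Grambsch–Therneau test on scaled Schoenfeld residuals. Effect
sizes are reported as compositional isotemporal substitutions: reallocate
`d` minutes into MVPA from the remaining behaviors (proportionally, so
their mutual ratios are kept), and report `HR = exp(Dz' b)` relative to
the sample compositional mean, with a delta-method 95% CI.

A calibrated synthetic-cohort generator (`codaltsa.synthetic`) emulates the
whole data structure — Dirichlet compositions around published
compositional means, day-level accelerometer class tables with wear-time
validity traps, weekly register series with decoy 5-week spells — and
plants interpretable effects (the hazard ratio of a +20-minute MVPA
reallocation per domain), so the full pipeline is testable end to end
without any restricted data.

## Worked example

```python
from codaltsa import GeneratorConfig, generate_cohort, analyze_frames
from codaltsa.substitution import predict_hr, reallocate
from codaltsa.pipeline import sample_compositional_mean

cohort = generate_cohort(GeneratorConfig(), seed=1)     # 929 workers
res = analyze_frames(cohort.days, cohort.bed, cohort.covariates, cohort.register)

fit = res["fit"]
print(round(res["outcomes"]["event"].mean(), 4))        # 0.2063 (~21% LTSA incidence)
base = res["means"]["work"]                             # sample compositional mean
print([round(v, 1) for v in base.minutes])              # [63.0, 174.7, 137.6, 73.2]
new = reallocate(base, "mvpa", 20).new_comp
print(predict_hr(fit, base, new))                       # (1.017, 0.868, 1.191)
```

The last line reads: in this particular generated cohort, moving 20
minutes into work MVPA from the other work behaviors is associated with a
1.7% higher hazard of LTSA (95% CI −13.2% to +19.1%) — a single cohort is
noisy; the planted population value is a 15% increase, and averaging the
recovered hazard ratios over many seeds returns it. `res["curves"]` holds the
full substitution curves (default grid −30…+30 min by 5), and
`res["ph_test"]` the proportionality diagnostics.

The same analysis is available as a CLI over CSV files:

```bash
codaltsa --outdir run --seed 1 all --simulate --plot
```

which writes `workers.csv`, `outcomes.csv`, `fit.csv`, `ph_test.csv`,
`substitution.csv`, a two-panel substitution plot and a `report.json`
with the cohort flow accounting.

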
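# affectinertia

Tools for separating **within-day** and **overnight affective inertia** in
experience-sampling (EMA) data.

Affective inertia — how strongly momentary affect persists from one
assessment to the next — is usually modelled as a single AR(1)
autoregression. But burst designs with several daily beeps also contain
one long overnight interval per day, and sleep is unlikely to carry
affect forward the way waking life does. This package models the two
interval types separately and asks which of four candidate overnight
regimes the data support: the within-day process **continues** through
the night, **pauses** during sleep, **stops** entirely, or is
**different** overnight.

## Model

For beep *t* of person *i* on day *d* in wave *w*:

```
affect_dwti = β0_dwi + β1_i·overnight_ti
            + β2_i·affect_(t−1,i)·withinday_ti
            + β3_i·affect_(t−1,i)·overnight_ti + ε_dwti

β0_dwi = γ00 + u0_i + ξ0_wi + ζ0_dwi      (person, wave, day intercepts)
β1_i   = γ10 + u1_i                        (morning main effect)
β2_i   = γ20 + u2_i                        (within-day inertia)
β3_i   = γ30 + u3_i                        (overnight inertia)
```

`withinday`/`overnight` are dummies for the interval type: a lag is
formed only between directly adjacent scheduled beeps with a gap of
1–4 h (within-day) or 10–17 h (overnight, the first beep of a day); a
missed beep makes the lag missing. The person effects (u0…u3) are
jointly correlated; estimation is Bayesian MCMC (a blocked Gibbs sampler
with weakly-informative priors — half-t scale priors, marginally uniform
random-effect correlations; split-R-hat < 1.05 as the convergence
criterion; posterior medians with 95% highest-density intervals).

Because an AR(1) coefficient for an interval *k* times longer is the
base coefficient to the *k*-th power, the posterior of
`γ30 − γ20^(Δt_night/Δt_day)` tests "continue" (with the default
intervals, exponent 13.7/2.6 ≈ 5.3) and
`γ30 − γ20^(Δt_awake/Δt_day)` tests "pause" (awake share of the night:
(13.7 − 7.7)/2.6 ≈ 2.3), while the HDI of `γ30` itself tests "stop".

The package also includes a synthetic EMA generator with this exact
model as ground truth (wake-time-anchored semi-random beep schedules,
0–100 slider items scored into 0–10 composites, configurable compliance
and overnight regime), per-covariate moderation models (within/between
decomposition with cross-level interactions), multilevel McDonald's ω
composite reliability, marginal/conditional R², and individual-slope
reports.

## Worked example

```python
from affectinertia import (StudyDesign, negative_affect_truth, EmaSimulator,
                           LagTransformer, InertiaModel)

design = StudyDesign(n_persons=100, n_waves=1, n_days_per_wave=14, compliance=0.8)
data = EmaSimulator(design, negative_affect_truth()).simulate(seed=3)
lagged = LagTransformer().transform(data.beeps)
model = InertiaModel(chains=4, iterations=1500, warmup=500, random_state=1).fit(lagged)
```

prints (via `model.summary_`, `model.classification_`, `model.r2_`):

```
eligible observations: 4469
gamma20             0.329  95% HDI [ 0.276,  0.380]
gamma30             0.166  95% HDI [ 0.097,  0.232]
contrast_continue   0.163  95% HDI [ 0.094,  0.228]
contrast_pause      0.087  95% HDI [ 0.015,  0.158]
overnight process: different
marginal/conditional R2: 0.137 / 0.708
```

Read: within-day inertia is ~0.33 per 2.6 h step; overnight inertia is
~0.17 — far above the ~0.001 implied by letting the within-day process
decay over 13.7 h (`contrast_continue` excludes 0, ruling out
"continue") and above the ~0.07 implied by decay over the ~6 awake
hours (`contrast_pause` excludes 0, ruling out "pause"); since `gamma30`
also excludes 0 ("stop" ruled out), the overnight process is classified
as **different**.

The same pipeline is available from the shell:

```
affectinertia simulate --seed 3 --out data/
affectinertia preprocess --in data/ --out lagged.csv
affectinertia derive --data lagged.csv --out derived.json
affectinertia report --data lagged.csv --out report/
```

## Data layout

The simulator writes three CSVs: `beeps.csv` (one row per answered
beep: `person_id, wave, day, beep, timestamp` in hours, four negative-
and four positive-affect items plus three perseverative-thought items on
0–100, their 0–10 composites `na`, `pa`, `urt`, and a binary
`stressor`), `mornings.csv` (daily sleep items, `sleep_quality`,
`bed_time`/`rise_time` as 12-h clock strings, `time_in_bed` in hours),
and `persons.csv` (wake time and six baseline questionnaire scores).
User data in the same layout can enter the pipeline at any stage.
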
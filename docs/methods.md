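# Methods

This note documents the generative model, the estimator, the numerical
choices and the known limitations of `affectinertia`.

## The model

Momentary affect (a 0–10 composite of 0–100 slider items) follows a
multilevel AR(1) process in which the lag-1 term is split by interval
type. Two dummies code whether the interval from the previous to the
current beep lies within a day (1–4 h between adjacent scheduled beeps)
or across a night (10–17 h, the last beep of one day to the first beep
of the next). The fixed effects are the intercept γ00, a morning main
effect γ10 (how the first beep of a day differs in level), the
within-day autoregression γ20 and the overnight autoregression γ30.
All four carry jointly correlated person-level random effects; the
intercept additionally varies by wave (burst) and by day. Residuals are
normal.

Only rows with an observed, in-bounds lag enter the likelihood; the lag
variable is left uncentered for the inertia analysis (person-mean
centering the lag biases the within-person autoregressive slope) and is
person-mean centered in the moderation models, where the goal shifts to
cross-level interaction estimates.

### Decay contrasts and regime classification

Under AR(1), the coefficient for an interval *k* times the base
interval is the base coefficient to the *k*-th power. With a mean
within-day gap of 2.6 h, a mean overnight gap of 13.7 h and a mean time
in bed of 7.7 h, the exponents are 13.7/2.6 = 5.2692… (reported as 5.3)
and (13.7 − 7.7)/2.6 = 2.3077… (reported as 2.3). Both exponent modes
are supported; the reported-precision mode (5.3/2.3) is the default
because summary tables round the exponent before differencing, and the
worked-example checks reproduce published values only in that mode.
The contrasts γ30 − γ20^5.3 ("continue") and γ30 − γ20^2.3 ("pause")
are computed on every posterior draw and summarised by the median and
the 95% highest-density interval; point-estimate versions (contrast of
the medians) are reported alongside. For negative posterior draws of
γ20 the power transform uses the sign-preserving continuous extension
−|γ20|^k, which keeps the per-draw transform total on the reals; this
only affects posterior tails.

A regime is *ruled out* when the relevant 95% HDI excludes zero (the
γ30 HDI for "stop", the contrast HDIs for "continue" and "pause").
Exactly one survivor gives that label; no survivor gives "different";
several survivors give "indeterminate" — a label added because HDI
exclusion logic can genuinely leave more than one candidate standing
(see the power analysis below).

## Priors and sampler

"Weakly-informative" is made explicit as:

* fixed effects: independent N(0, 10²) (an improper flat prior is
  available and is used for the least-squares equivalence check);
* scalar SDs (residual, wave, day): half-Cauchy with scale 5;
* the 4×4 person random-effect covariance: the Huang–Wand (2013)
  prior with ν = 2 and scale 5, whose implied marginals are half-t(2)
  SDs and uniform correlations.

All of these admit conjugate conditionals — the half-Cauchy and
Huang–Wand priors through inverse-gamma mixture representations — so
the posterior is explored by a blocked Gibbs sampler rather than
gradient-based MCMC. Two structural choices matter for mixing:

* the sampler runs in the *centered* parametrization (person effects
  b_i = γ + u_i), which mixes well here because every person
  contributes dozens of beeps;
* the base fixed effects are drawn jointly with the person effects:
  γ is sampled from its conditional with u integrated out (a Woodbury
  identity on per-person 4×4 sufficient statistics), then u | γ. This
  removes the γ ↔ mean(u) random-walk coupling that otherwise
  dominates the autocorrelation time.

Defaults are 4 chains × 1,500 iterations with 500 warm-up — desk-scale
settings at which the experiments in the test suite converge
(split-R-hat < 1.05 for the fixed effects); longer runs are a config
change away. Convergence is diagnosed with classic split-R-hat and
bulk/tail effective sample sizes; a failed threshold warns rather than
errors. Wave-level intercepts are dropped automatically when the data
contain a single wave, where they are not identified separately from
the person intercept. The log joint density (`log_posterior`) is the
backend contract: it is tested against an independent row-by-row
implementation at 1e-10 relative tolerance, the prior-predictive
distribution of the sampler is tested against the closed-form priors,
and flat-prior fixed effects are tested against ordinary least squares.

`sigma_eps` for the reference parameterisations is not part of the
published fixed-effect tables; it is backed out from the reported
marginal/conditional R² and variance components (≈0.97 for negative
affect, ≈1.26 for positive affect).

## The synthetic-data generator

The generator emulates a measurement-burst design: up to 3 waves ×
14 days × 5 beeps, seven beep schedules anchored to whole-hour wake
times between 5 and 11 AM, first beep at least 55 min after waking
plus up to 30 min jitter, subsequent gaps uniform on [2.2, 3.0] h
(mean 2.6 h), and a latest-beep cap 12 h 55 min after waking enforced
by redrawing a day's gaps. With five beeps per day the overnight gap is
24 h minus the within-day span, giving a mean of ≈13.6 h inside the
10–17 h analysis window; an exactly 2.6 h within-day mean and an
exactly 13.7 h overnight mean are arithmetically incompatible at five
beeps per 24 h, and the generator keeps the within-day target.

Affect dynamics follow the model equation exactly on a continuous
scale; each person's first beep of a burst is initialised at the
stationary mean of their within-day process (avoiding burn-in
artifacts; bursts months apart carry no AR information across the gap).
Under a generating *regime*, the overnight coefficient is pinned to the
implied value (continue: γ20^(13.7/2.6); pause: γ20^(6.0/2.6); stop: 0)
and applied once per night regardless of the exact gap, matching the
fitted model's single overnight coefficient. Item scores are
loading-scaled composite values plus normal noise clipped to [0, 100],
which reproduces the mild floor skew of real negative-affect sliders.
The stored composite is *not* clipped by default: floor-censoring ~10%
of negative-affect values at 0 creates runs of zeros that mimic
persistence and measurably bias recovery of γ20 upward (+0.05 with
coverage collapse in our experiments); `TruthParams.clip_composites`
turns bounded composites on for realism studies. Missingness is
completely at random at the beep level; morning reports are thinned by
the same mechanism. Answer latency is not simulated (it is small
relative to 2.6 h gaps). Person-level stressor probabilities are
Beta-distributed so the marginal stressor rate matches its target.

What the generator does **not** emulate: circadian mean trends, weekday
effects, wave-to-wave change in inertia, skew beyond item clipping,
informative (non-random) missingness, and real measurement reactivity.
Passing recovery tests therefore show that the estimator recovers the
stated process under the stated design — not that real EMA data follow
that process.

## Estimator properties discovered by simulation

Two properties of the *analysis rule* (not of the sampler) surfaced in
the package's own recovery experiments and are worth knowing:

1. **Exclusion-rule endogeneity under beep-level missingness.** The
   analysis keeps a row only if its scheduled-adjacent predecessor was
   answered; the predecessor's *value* still serves as the regressor.
   When a skipped beep breaks the chain, that anchor value's own row is
   excluded from the likelihood, yet the value contains the shared
   day-level intercept ζ. The lag regressor is then correlated with the
   row's own random day intercept, and the within-day coefficient
   absorbs day-level variance: at 80% compliance with a day-intercept
   SD of 0.337, recovered within-day inertia is asymptotically ≈0.34
   for a generating 0.28 while the day SD is underestimated. At full
   compliance recovery is unbiased (a small residue remains from the
   burst-start anchor of day 1). The overnight coefficient is largely
   unaffected because its anchor carries the *previous* day's
   intercept. This bias is inherent to listwise deletion of
   missing-lag rows — the standard practice this package implements —
   and is why the recovery acceptance checks on the within-day
   coefficient fail at 80% compliance by design of the experiment.

2. **Regime discrimination is power-limited.** "Stop" (γ30 = 0) and
   "continue" (γ30 = γ20^5.3) differ by γ20^5.3 ≈ 0.001 at γ20 = 0.28 —
   far inside any realistic HDI around zero, so no design of practical
   size can separate them at that inertia level (the classifier
   correctly returns "indeterminate"). The regime-recovery study
   therefore generates continue/pause/stop with γ20 = 0.7, whose
   extrapolations (0.15 and 0.44) are separated by more than posterior
   uncertainty, and generates "different" at the published 0.28/0.19
   values; it runs at full compliance to keep regime recovery distinct
   from the missingness effect above.

## Problem sizes used by the tests

Unit fits use 25–100 persons, 5–14 days, 2 chains × 400–1,500
iterations. The recovery study replicates 20 seeded datasets per
outcome at 100 persons × 14 days × 5 beeps, 80% compliance, 4 chains ×
1,500 iterations; the regime study replicates 20 datasets per regime at
100 persons × 10 days, full compliance, 2 chains × 800 iterations. The
acceptance script averages three replicate recovery experiments per
outcome to damp dataset-level Monte-Carlo spread of the reported
medians (~0.02–0.04 per run).

## Other numerical and design choices

* **Time-in-bed recoding.** Durations are computed from 12-h clock
  strings, adding 24 h when rise precedes bed. Values outside a
  [2, 16] h plausibility window are recoded deterministically:
  durations *above* the window are treated as the classic AM/PM entry
  slip and fixed by toggling AM/PM on the bed time, then the rise time,
  keeping the first plausible result; durations *below* the window
  (e.g. a five-minute "night") are unrecoverable entry errors and
  become missing. Window-only ladders were rejected because any sub-2 h
  duration toggles to ~12 h and would always be "rescued".
* **Composite scoring.** Reverse-coded items are mapped x → (max − x)
  on the input range before averaging; the mean is taken over answered
  items; all-missing yields missing; division by 10 rescales to 0–10.
* **Overnight row definition.** An overnight lag connects the first
  beep of a calendar day to the previous day's last scheduled beep,
  both answered; any missed beep in between severs the pair. Morning
  survey linkage is not used.
* **Moderation models.** One covariate per model. Time-varying
  covariates are split into within-person (person-mean-centered) and
  between-person (person mean, grand-mean-centered) components; each
  component enters as a main effect plus interactions with the
  overnight dummy and both inertia terms (8 new fixed effects;
  between-only covariates contribute 4). Alignment rules: a momentary
  report moderates the interval ending at that beep; an interval event
  (stressor) covers (t−1, t]; a morning report moderates that day's
  overnight arrival and all of that day's within-day intervals.
  Moderation coefficients are fixed effects; random slopes stay on the
  base terms. Traits enter as person-level values.
* **Multilevel ω.** The item covariance matrix is decomposed by the
  method of moments into pooled within-cluster and between-cluster
  components; a one-factor model is fit to each by ML (L-BFGS on the
  discrepancy log|Σ| + tr(Σ⁻¹S), valid for singular sample
  covariances), and ω = (Σλ)²/((Σλ)² + Σθ). A non-PSD between
  component flags ω_between undefined. The estimator is deliberately
  model-fitting-free at the multilevel stage and swappable.
* **R² partition.** Marginal R² = var(fixed-effect predictions) over
  the model-implied total (fixed + person/wave/day random-effect
  variances + residual); conditional R² adds the random-effect
  variances to the numerator. Computed per posterior draw; medians
  reported; conditional ≥ marginal holds draw-wise by construction.
* **Individual slopes.** Posterior means of the conditional effects
  (γ + u), i.e. shrunken estimates; per-person least squares is
  available as a diagnostic alternative through the lagged dataset.
* **Interfaces.** The pipeline is exposed both as sklearn-style
  estimators (`LagTransformer`, `InertiaModel`, `ModerationModel`) and
  as a thin `click` CLI (`simulate`, `preprocess`, `fit`, `derive`,
  `moderate`, `report`).

## Limitations

The model ignores interval-length variation within each interval class
(a single coefficient covers 1–4 h and another 10–17 h); residuals are
normal while real affect data are bounded and skewed; missingness is
assumed ignorable; inertia is assumed constant across waves; and the
continue/pause/stop/different logic inherits the power limits described
above. Continuous-time or dynamic structural equation approaches would
lift the first limitation and are out of scope here.
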
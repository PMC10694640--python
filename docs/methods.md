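# Methods

`stepfall` implements an ambulatory fall-risk analysis that starts from
*step-event timestamps* — the output of a placement-agnostic step detector —
rather than from raw inertial signals. This note documents the models,
conventions and numerical choices, and what the synthetic-data experiments
do and do not demonstrate.

## Walking-bout segmentation

Steps belong to the same walking bout while consecutive events are
separated by strictly less than `gap_s` (default 2.0 s); a gap of exactly
2.0 s splits. Only bouts with raw step count strictly greater than
`min_steps` (default 200, about two minutes of continuous walking at
typical older-adult cadence) are analysed. The threshold is applied to the
raw count: a 200-step raw bout would retain only 190 steps after trimming
and could never supply the constant 200-step complexity window, so "longer
than 200 steps" is read as `raw > 200`. Each kept bout is trimmed by 5
steps at each end to discard gait initiation and termination, leaving
`raw − 10` retained steps. Participants whose week contains no kept bout
are excluded from the cohort and tallied — the analysis by construction
selects people who sustain long continuous walks.

Step intervals are successive differences of retained steps. Because an
unlabeled step detector cannot assign feet, stride intervals are
reconstructed as non-overlapping two-step spans `t[2k+2] − t[2k]` starting
at the first retained step, dropping a trailing unpaired interval; an
overlapping variant (`t[k+2] − t[k]`) is available behind a flag. The
non-overlapping default keeps stride intervals statistically independent
of each other at lag 0 in the same way labeled left/right strides would be.

## The 12 gait parameters

* **Quantity** — number of kept bouts, total steps, average steps per
  bout. Totals count retained steps of kept bouts, consistent with every
  other parameter being computed on retained steps.
* **Intensity** — mean step time, mean stride time (seconds), and cadence
  defined as `60 / mean step time` (steps/min). Defining cadence from the
  mean interval rather than total steps over total duration differs only
  at bout edges.
* **Variability** — coefficient of variation (sample SD / mean, `n−1`
  denominator) of the step- and stride-interval series, reported as a
  fraction, not percent.
* **Complexity** — DFA scaling exponent and sample entropy of the step-
  and stride-interval series. Both estimators are strongly
  length-dependent, so they are computed on a constant-length window: the
  central 200 retained steps (left-biased for odd remainders), giving 199
  step intervals and 99 stride intervals per eligible bout. Eligibility
  therefore requires ≥ 200 retained steps (raw ≥ 210); ineligible bouts
  contribute the other domains but missing complexity.

Per participant, bout-level parameters are collapsed by the median over
bouts where they are defined; quantity parameters are weekly totals (a
median "total number of steps" over bouts would be meaningless).

### DFA

First-order DFA: the interval series is mean-centered and cumulatively
summed; the profile is cut into non-overlapping boxes of size `n`
(trailing remainder dropped), each box linearly detrended, and the RMS
fluctuation `F(n)` pooled over boxes. Box sizes are log-spaced integers
from 4 to `N/4` (10 sizes requested, ≥ 6 distinct required); the exponent
is the least-squares slope of `log10 F(n)` on `log10 n`. For stationary
fGn the exponent estimates the Hurst exponent: 0.5 for white noise, → 1.5
for an integrated random walk. A constant series has `F(n) = 0` and the
exponent is undefined (error).

### Sample entropy

`SampEn(m, r) = −ln(A/B)` with `m = 2` and `r = 0.2 ×` the sample SD of
the analysed series, Chebyshev distance, self-matches excluded, and both
template counts taken over the `N − m` templates so every length-`m`
template can extend to length `m+1`. `A = 0` or `B = 0` yields an
undefined value that propagates as missing for that bout; participant
medians are taken over defined bouts only, because dropping a bout is far
less damaging than dropping a participant. A constant series gives 0
(every match extends).

## Cohort statistics and the fall model

Spearman rank correlations (average ranks for ties) screen the 12
parameters; |ρ| bands are weak `[0, 0.4)`, moderate `[0.4, 0.7)`, strong
`[0.7, 1]` (boundaries closed upward). Candidate models contain at most
one parameter from any strongly correlated pair.

Twelve-month fall counts are modelled by NB2 negative-binomial regression
(log link, variance `μ + αμ²`, maximum-likelihood dispersion, Wald
inference) on z-transformed parameters (cohort mean 0, SD 1, sample SD),
always adjusting for intervention-group membership. The NB model is a
*count* model; discrimination of fallers (≥ 1 fall) from nonfallers is
measured by ranking participants on the predicted expected count, which is
a monotone function of the linear predictor, so the AUC is well defined.

**Stability-based backward elimination.** The candidate model is refit on
10 independent random subsets, each 70 % of the cohort drawn without
replacement (70 % subsets cannot partition the data, so draws are
independent by design). A gait term is *stable* when the mean and the SD
of its Wald P value across the 10 fits are both below 0.20. If any term is
unstable, the least stable one (largest mean P; ties by larger SD, then
name) is removed and the procedure repeats — one term at a time with
refitting, since simultaneous removal of correlated terms can discard a
genuine effect (simultaneous removal is available behind a flag). The
group covariate and intercept are never eliminated. Group × parameter
interaction terms are added *after* elimination and are not themselves
eliminable. Within each subset fit the standardization is re-estimated on
that subset. A subset drawing a singular design is redrawn; a
non-converged subset fit contributes P = 1 for every term (conservative)
and is counted in the stability report.

**Evaluation.** (a) Train = test: fit and score on the full cohort.
(b) Repeated shuffle-split: 10 seeded random 80/20 splits; for each,
standardization and the NB fit use the training 80 % only and the held-out
20 % is scored — no leakage. A split whose test part lacks one of the two
classes is redrawn (at most 100 attempts). AUC uses the exact Mann–Whitney
formulation with ties counted 0.5.

Numerical details: the NB likelihood is optimized by L-BFGS, falling back
to BFGS and Nelder–Mead; a fit is accepted when the optimizer converges
*and* the Wald covariance is finite, otherwise the fit is flagged
non-converged — never silently accepted. Rank-deficient designs raise an
error naming the collinear columns (pivoted QR).

## The synthetic cohort generator

The generator emulates the statistical structure of week-long ambulatory
monitoring in community-dwelling older adults:

* **Bout structure** — per waking day (07:00–22:00, ≥ 60 s between bouts)
  a Poisson number of bouts with a per-participant rate (gamma-distributed,
  mean 2/day); bout lengths mix short walks (≈ 80 steps) and long walks
  (≈ 320 steps, floored at 210) with a per-participant long-bout
  propensity, so lengths straddle the 200-step threshold and a small
  fraction of participants is excluded, as in real cohorts.
* **Stride process** — exact fractional Gaussian noise (circulant
  embedding / Davies–Harte; eigenvalues are provably non-negative for fGn,
  only round-off is clipped) scaled to a per-participant mean stride time
  (population 1.10 ± 0.08 s) and CoV (0.035 ± 0.012), with Hurst exponent
  0.75 ± 0.08 — values typical of healthy-to-older gait. A per-participant
  fraction of the variance (uniform on [0, 0.4]) is replaced by white
  noise, lowering the effective long-range correlation. Intervals are
  floored at 0.2 × mean to preserve positivity.
* **Steps from strides** — each stride splits into two step intervals with
  a fixed 0.5 ± 0.02 asymmetry ratio plus zero-sum timing jitter
  (≈ 10 ms SD) on the split point. The jitter cancels exactly within each
  stride pair, so it perturbs step-level but not stride-level parameters —
  giving the step- and stride-level complexity measures partially
  independent generative dials (Hurst, white fraction, jitter).
* **Outcomes** — 12-month fall counts from the NB2 model (gamma–Poisson
  mixture) with log rate `β₀ + Σ β·z(true parameter) + β_group·group`,
  standardized over the cohort's true values. Defaults: `β₀ = ln 0.8`,
  dispersion 1.0, and the published sign pattern with magnitudes
  (0.4, 0.6, 0.5, −0.8, −0.6, −0.6) for (steps, cadence, CoV stride,
  DFA step, SampEn step, SampEn stride). Magnitudes were chosen so the
  linear predictor has a realistic spread (annual fall rates mostly
  between ~0.1 and ~10, faller fraction ≈ 0.4) while every effect is
  detectable at cohort scale; copying published coefficient magnitudes
  verbatim onto independently standardized synthetic columns would imply
  hundreds of falls per year for extreme participants.

"True" values of derived parameters are defined as the estimator values on
a long seeded reference realization of the participant's interval process
(1200 strides, complexity averaged over consecutive 199-step / 99-stride
windows mirroring the middle-200 convention). This is the population
quantity the bout medians estimate, so pipeline recovery can be tested
against it.

### What the generator does not emulate

Real accelerometry artifacts (nonwear, device noise), foot-laterality,
turning, surface and context effects, diurnal and day-to-day
non-stationarity, and any systematic relation between walking *speed* and
interval statistics. Sample entropy in particular has no direct generative
dial: between-participant SampEn variation arises only indirectly through
the Hurst, white-fraction and jitter dials and is weak at stride level,
where 99-interval windows make the estimator noisy. Consequently, passing
recovery tests demonstrates estimator correctness and pipeline integrity
under the modelled structure, not that SampEn is a sensitive biomarker in
real data; SampEn correctness is certified separately against an exact
brute-force template-counting oracle.

## Simulation scales used by the tests and acceptance script

The test suite runs the full stream pipeline once at 300 participants ×
7 days and the model-stage simulations (sign recovery, optimism, selection
consistency) at 50 replicates of parameter-level cohorts (n = 300–400),
where the statistical properties under test live; large-sample coefficient
recovery uses n = 2000. Parameter-level cohorts draw the 12-parameter
vectors directly (multivariate normal with a plausible correlation
structure and observation noise emulating bout-median estimation error),
which makes 50-replicate experiments affordable while exercising exactly
the same model-stage code paths.

## Known limitations

* Stride intervals from unlabeled steps are a convention, not a
  measurement; both conventions shipped here differ from labeled stride
  times when gait is strongly asymmetric.
* The NB model is linear on the log scale; threshold or interaction
  effects beyond quantity × parameter and group × parameter are out of
  scope.
* DFA on 99-interval stride windows is noisy (SD ≈ 0.1–0.15 per bout);
  participant medians inherit part of that noise.
* The stability-elimination path depends on the subset RNG; all
  randomness is seeded and reports carry their seeds.
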
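# Methods

## Outcomes as compositions

A night's sleep macroarchitecture is summarised as the proportions of the
sleep–wake cycle spent awake, in light (N1+N2), deep (N3) and REM sleep; the
nocturnal stress profile as the proportions of asleep minutes whose 0–100
HRV-based stress level falls in four equidistant bands — low [0, 25], medium
[26, 50], high [51, 75], highest [76, 100], on integer stress values with
real-valued inputs floored first. Both are points on a simplex, so components
cannot be modelled independently: an increase in one is necessarily a decrease
in others. All modelling therefore happens in additive log-ratio (ALR)
coordinates, `alr(p)_i = ln(p_i / p_baseline)`, which are unconstrained and
close to Gaussian for the data at hand. The baseline is configurable; the
defaults are the dominant components (light sleep; the low-stress band), which
keeps the log-ratios well scaled. Because the highest stress band is rarely
occupied and its proportion is zero-inflated, the two upper bands are merged
before transformation (low/medium/high, with high = [51, 100]), giving two ALR
outcomes; the 4-part sleep composition gives three.

Exact zeros are handled by additive (Laplace) smoothing,
`p -> (p + λ) / (1 + Dλ)` with λ = 0.01 by default, applied to both outcome
families before the transform. The smoothing strategy is a plain function and
can be swapped (e.g. for count-based replacement) without touching the rest of
the pipeline. Note that smoothing is a *data-cleaning* device, not part of the
probability model: it perturbs every composition slightly, most visibly
components near λ in magnitude. This matters for validation — see
"Parameter recovery" below.

## Marker derivation

The sleep–wake cycle is the half-open interval from the first minute labeled
light/deep/REM to the minute after the last such label; awake minutes outside
it (before sleep onset, after final wake-up) are excluded, so the awake
component of the sleep composition measures intra-night fragmentation only.
"Asleep" stress minutes are the sleep-stage minutes inside the cycle; every
other valid minute of the day counts as "awake", and each summary statistic
(mean, sample SD, min, max, median) drops missing stress minutes rather than
imputing them. The average daily stress covariate is defined as the
awake-period mean (the 24-hour mean is the obvious alternative; the awake mean
was chosen because nocturnal stress is itself an outcome). Active hours are
`0.25 × (active + highly-active 15-minute epochs)`.

## Preprocessing

Subjects with fewer than a configurable number of valid sleep nights are
excluded entirely. Missing questionnaire answers are mean-imputed conditioning
on subject and weekend indicator (Saturday/Sunday), with a deterministic
fallback chain — same-subject any-day mean, global same-flag mean, global
mean — so imputation is total whenever a field is observed at least once; the
operation is idempotent. Numeric predictors with pairwise |Pearson r| at or
above 0.75 are pruned greedily, keeping the higher-priority member (the
default priority keeps age over career seniority and activity time over step
counts, the two collisions that arise in practice with wearable data; the
cutoff sits below the r = 0.79–0.82 range at which those pairs collide).
The design matrix has nine columns in fixed reporting order: intercept, age
centered at 30, indicators for low and moderate alcohol intake (rare "high"
answers are recoded to moderate; "none" is the reference), hours worked,
subjective evening stress and energy (1–10 scales), active hours, and average
daily stress centered at 30. Centering at 30 makes the intercept the expected
ALR outcome for a 30-year-old at stress level 30.

## The model and its sampler

For ALR dimension d, observation j of subject i:

    y_{ijd} = x_{ij}' β_d + u_{id} + ε_{ijd},
    u_{id} ~ N(0, σ_ud²),   ε_{ijd} ~ N(0, σ_ed²).

Random intercepts and residuals are independent across ALR dimensions — the
model is a set of parallel univariate mixed models sharing one frame, which is
the simplest structure consistent with reporting per-dimension intercept SDs.
A correlated-error extension would share information across dimensions; the
flag is reserved but not implemented.

Priors are conjugate: β_d ~ N(0, 10² I) (weakly informative on standardised
ALR-scale coefficients), and inverse-gamma(2, 1) on each variance (prior mean
1, infinite variance at shape 2 — permissive for SDs anywhere between ~0.2 and
~3, the plausible ALR range). All are overridable via `PriorSpec`.

The reference sampler is Gibbs, exact because of conjugacy. The β-update uses
the *collapsed* full conditional with u marginalised out (via the Woodbury
identity on V = σ_e² I + σ_u² ZZ'), followed by u | β, the inverse-gamma draw
for σ_u² | u, and σ_e² | rest. Collapsing matters: the plain β | u update
leaves the strong anticorrelation between the intercept (and any
between-subject covariate such as age) and the mean of u, and mixes an order
of magnitude slower; the collapsed kernel reaches split-R̂ ≈ 1.00 within a few
hundred iterations on study-sized frames. Multivariate normal draws are
Cholesky-based (one factorisation per dimension per sweep); variance draws are
σ² = scale / Gamma(shape). Defaults follow the study protocol: 5 chains of
5,000 iterations, first half discarded as warm-up, random N(0,1) initialisation
of β per chain. Split-R̂ and autocorrelation-truncated ESS (Geyer
initial-positive-sequence) are computed for every scalar parameter after each
fit; any split-R̂ above 1.05 raises a prominent `ConvergenceWarning` and is
recorded in the draws' metadata. Degenerate conventions: constant chains give
R̂ = 1 and ESS = 0.

A second backend (`sampler="ensemble"`) runs emcee's affine-invariant ensemble
sampler over the identical log posterior, with the SDs log-transformed
(Jacobian included) and walkers grouped into pseudo-chains for diagnostics. It
is algorithmically independent of the Gibbs kernel and serves as a cross-check
that both routes land on the same posterior; it is considerably slower and not
the default. A Hamiltonian/No-U-Turn backend would serve the same purpose and
could be slotted in behind the same `sampler` switch.

## Reporting

Summaries pool draws across chains (diagnostics stay per-chain). The effect
estimate is the pooled posterior median; the PoD is the share of pooled draws
with the same sign as that median, with zero draws counted in neither sign and
the larger signed share used in the measure-zero event of an exactly-zero
median. PoD maps to posterior odds by p/(1−p), so the 0.75 reporting threshold
equals odds of 3. Text reports round EE and PoD to two decimals and flag
PoD > 0.75 (never the intercept); the CSV keeps full precision. Both 89% and
95% equal-tailed intervals are computed (linear-interpolation quantiles).
Residuals are evaluated at the posterior-median parameters and summarised by
mean, SD, skewness and excess kurtosis per dimension, with an optional
residual-vs-fitted plot.

## Synthetic study and what it shows

The generator emulates the study design: 16 subjects × 7 nights by default
(configurable), age uniform on 24–44 years and constant within subject,
alcohol categorical with probabilities (0.50, 0.25, 0.20, 0.05) for
none/low/moderate/high, hours worked truncated-normal(8, 2.5) on [0, 14],
subjective scales uniform on 1–10, active hours truncated-normal(1.5, 1) on
[0, 6], average daily stress truncated-normal(35, 15) on [0, 100], and up to 3
missing questionnaire cells per subject (numeric fields only — a
mean-imputation target needs a mean). Outcomes are drawn from the model in
the generative direction and mapped onto the simplex by the inverse ALR. The
default generating coefficients and random-intercept SDs (0.88/0.68/0.65 for
sleep; 2.64/2.29 for stress) mirror the effect landscape reported for the
motivating study, so the simulated posteriors look like the real ones in
location and spread; the residual SD is not reported there and is fixed at 0.5
per sleep ALR dimension (1.0 for the noisier stress outcome) — large enough
that single-night compositions vary visibly, small enough that week-level
effects are detectable. Minute streams are built to match each night's target
composition within rounding (largest-remainder allocation), with stages as
contiguous blocks, one mid-night awakening, awake lead-in/out periods, plus
stress and activity series; they are sufficient for proportion-based markers,
not for transition or spectral analyses. Nocturnal stress compositions are
zero-inflated (default 15% of rows) by zeroing the smallest non-baseline
component, exercising the smoothing path.

Every generator is a pure function of (config, seed).

**Parameter recovery.** The calibration study refits 30-subject × 14-day
replicates (2 chains × 2,000 iterations each — posterior summaries stabilise
well before that at this data size; the test suite uses 200 replicates, the
acceptance script 60) and checks that 95% intervals cover each generating
coefficient at nominal rate and that effect directions flagged at PoD > 0.95
agree with the true sign (entries with an exactly-zero generating coefficient
have no sign and are excluded from the sign check). The recovery frames are
built with λ = 0: the generator emits strictly positive compositions, so
smoothing is unnecessary there, and applying it would bias components of
magnitude comparable to λ (the ~1% awake share roughly doubles), attenuating
precisely the coefficients with the smallest posterior SEs. That is a real
property of Laplace smoothing on real data too — a known limitation, not an
artifact of the simulation.

What passing these tests shows: the transforms are exact, the sampler targets
the correct posterior, and interval/PoD calibration holds *when the model is
correctly specified*. What they do not show: robustness to staging error in
the wearable, informative missingness, circadian or day-of-week structure,
cross-dimension residual correlation, or any causal claim about lifestyle
effects.

## Numerical choices and edge cases

- Inverse ALR is computed via log-sum-exp (max subtraction), so coordinates of
  magnitude 50+ do not overflow.
- Compositions validate to a sum of 1 within 1e-8 on input and are emitted
  summing to 1 within 1e-12.
- Stress-band boundaries are closed on the left band: 25 is low, 26 is medium.
- Sample SD of a single stress minute is defined as 0.
- A singular β full-conditional precision raises an error naming the block;
  non-positive SDs make the log posterior −∞ (a rejected state, not an
  exception).
- Subject codes are contiguous integers in first-appearance order; permuting
  input rows or chain order leaves all summaries unchanged (up to MC error for
  rows).
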
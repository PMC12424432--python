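# somnalr

Bayesian mixed-effects analysis of **compositional sleep-stage and nocturnal-stress
outcomes** derived from consumer wearables.

Consumer smartwatches produce minute-resolution hypnograms (awake / light / deep /
REM), HRV-based stress levels on a 0–100 scale, and activity epochs. Aggregated to
daily features, these support small longitudinal studies of how lifestyle factors
(alcohol intake, working hours, subjective evening stress and energy, physical
activity, daytime stress) relate to sleep macroarchitecture and nocturnal autonomic
stress — questions relevant to recovery, resilience and burnout prevention. This
package implements the full analysis pipeline for such studies, together with a
synthetic-study generator with known ground truth, so every stage is testable
without access to any private participant data.

## The model

Both outcomes are **compositions**: vectors of proportions on the simplex (time in
each sleep stage; time in each nocturnal stress band). After additive (Laplace)
zero-replacement with λ = 0.01, each D-part composition *p* is mapped to D−1
unconstrained coordinates by the additive log-ratio (ALR) transform against a
designated baseline component,

```
alr(p) = [ ln(p₁/p_D), …, ln(p_{D−1}/p_D) ],
```

using light sleep as the baseline for the sleep profile (3 ALR outcomes) and the
low-stress band for the merged 3-part nocturnal-stress profile (2 ALR outcomes).
The ALR outcomes are modelled by a multivariate linear mixed model with
subject-specific random intercepts,

```
Y = Xβ + Zu + ε,    u_i ~ N(0, σ_u²),    ε ~ N(0, σ_e²),
```

with independent errors and intercepts per ALR dimension. Estimation is Bayesian
with conjugate priors (normal on β, inverse-gamma on the variances): the reference
backend is a self-implemented blocked **Gibbs sampler** whose β-update marginalises
the random intercepts (all full conditionals are exact), and an optional
ensemble-MCMC backend (emcee) samples the identical posterior through an
independent route as a cross-check. Effects are reported as posterior medians (EE)
with equal-tailed 89%/95% credible intervals and the **probability of direction**
(PoD) — the share of posterior draws sharing the sign of the median — highlighting
PoD > 0.75, which corresponds to posterior odds greater than 3.

## Worked example

```python
import somnalr as sa
from somnalr import preprocess, synthetic

cfg = synthetic.sleep_config(seed=42)          # 16 subjects x 7 nights
records, truth = synthetic.generate_dataset(cfg)
records = preprocess.impute_missing(records)
frame = preprocess.build_model_frame(records, outcome="sleep", lam=0.01)

model = sa.CompositionalMixedLM.from_frame(frame)
res = model.fit(config=sa.McmcConfig(seed=0))  # 5 chains x 5,000 iterations
print(res.summary())
```

```
Estimated median fixed effects (posterior medians and PoD)
====================================================================================================
Coefficient                    Deep/Light EE     PoD    REM/Light EE     PoD  Awake/Light EE     PoD
----------------------------------------------------------------------------------------------------
(Intercept)                           -1.99   1.00           -1.11   1.00           -3.45   1.00
Age-30                                -0.02   0.73            0.03   0.89*          -0.00   0.59
Low alcohol intake                     0.08   0.77*          -0.24   0.98*          -0.04   0.73
Moderate alcohol intake                0.36   1.00*          -0.45   1.00*          -0.09   0.89*
Hours worked                           0.01   0.66            0.04   0.95*           0.01   0.66
Subjective evening stress             -0.00   0.62            0.03   0.95*           0.00   0.69
Subjective evening energy             -0.01   0.82*           0.01   0.68            0.01   0.86*
Active hours                           0.10   0.97*          -0.04   0.74           -0.04   0.87*
Average daily stress-30               -0.03   1.00*           0.01   1.00*           0.00   0.55
----------------------------------------------------------------------------------------------------
* PoD > 0.75 (posterior odds > 3), intercept never flagged
sampler: gibbs  chains: 5  draws/chain: 2500  max split-Rhat: 1.001
```

Each cell is the posterior median effect of one daily covariate on one log-ratio of
sleep-stage proportions (e.g. `Moderate alcohol intake, REM/Light = -0.45, PoD
1.00`: moderate drinking reduces the REM-to-light-sleep ratio, with essentially all
posterior mass on the negative side). Because the data were simulated, the
generating coefficients are known; `res.recovery(truth)` scores bias, interval
coverage and sign agreement per coefficient. `res.random_intercept_sd` gives the
posterior median between-subject SD per ALR dimension, and `res.residuals()`
returns residuals with normality/homoscedasticity diagnostics.

The same stages are available as a shell pipeline:

```sh
somnalr generate --seed 3 --out-dir data
somnalr derive  --streams-dir data/streams --out daily_markers.csv
somnalr prepare --markers daily_markers.csv --covariates data/covariates.csv --out-dir prepared
somnalr fit     --frame prepared/model_frame_sleep.csv --out draws.csv --seed 4
somnalr report  --draws draws.csv --frame prepared/model_frame_sleep.csv --out-dir report
```

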
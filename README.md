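# socialvalue

Hierarchical Bayesian estimation of how much a rhesus macaque values
looking at a social image, measured in milliseconds of forgone juice.

## The problem

In "pay-per-view" style experiments a monkey repeatedly chooses between a
juice-only option and a juice-plus-image option while the juice
differential `dv = juice_image − juice_blank` is varied in blocks and the
images are drawn from four categories (gray-square control, female
perinea, dominant-male faces, subordinate-male faces).  The point of
subjective equality — the `dv` at which both options are chosen equally
often — measures the image's value `v` through `dv* = −v`.

Choice behavior is noisy and drifts from day to day, and subjects
contribute very unequal numbers of sessions, so per-session fits are
fragile and fully pooled fits erase real individual differences.  This
package mediates between the two extremes with a partial-pooling
hierarchy over an aggregated choice table (one row per subject, session,
category, and `dv`, with counts `n` of `N` image choices):

```
v_msc ~ Normal(V_mc + α_mc·t_s, σ_m²)        session values per subject m,
η_msc = (dv + v_msc) / τ_s                    category c, session s
logit p_msc ~ Normal(η_msc, ω_m²)             overdispersed logit choice
n_msc ~ Binomial(N_msc, p_msc)
```

`V_mc` is the mean image value (seconds of juice access), `σ_m` the
session-to-session value s.d., `τ_s` a session-specific utility scale
(the choice-curve width), `ω_m` extra-binomial choice variability, and
`α_mc` an optional linear drift per standardized session rank `t_s`.
Weakly informative priors complete the model: `V_mc ~ N(0, 0.01 s²)`
(s.d. 100 ms), `σ_m ~ U(10⁻⁶, 1)`, `log ω_m ~ U(−6, 2)`, and a
positively truncated Student-t prior on `τ_s` whose location, scale, and
degrees of freedom carry uniform hyperpriors.

Eight pooling variants (`model0` … `model7`) vary how sessions,
categories, and subjects are pooled — from one independent fit per
session to a single model per subject — and are ranked by the Deviance
Information Criterion.  Posterior predictive checks simulate fictitious
sessions from a fitted posterior and refit them with a standard logistic
choice curve `logit p ~ β0 + β1·dv` so observed and predicted value/width
distributions can be compared like-for-like.

Because the original colony data are not bundled, a first-class synthetic
study generator simulates complete experiments (including the archived
study's shape: 8 subjects with 60/32/51/23/14/10/8/8 sessions) with known
ground truth, so every stage — recovery, shrinkage, pooling metrics, DIC
direction, predictive checks — is exercisable end to end.

## Worked example

```python
import numpy as np
import socialvalue as sv

# simulate the canonical study: 4 monkeys x 10 sessions x 4 image
# categories x 5 juice differentials x 30 choices per block
design = sv.small_study_design()
truth = sv.small_study_truth(design)
dataset, _ = sv.simulate_dataset(truth, design, np.random.default_rng(0))

# fit the partial-pooling hierarchy (Model 6) with two chains
config = sv.ChainConfig(n_chains=2, n_adapt=300, n_burn=600,
                        n_iter=1600, thin=4, seed=1)
samples = sv.run_mcmc(sv.ModelSpec.from_model_number(6), dataset, config)

for s in sv.value_summaries(samples)[:4]:  # subject A
    print(f"{s.subject} {s.category:16s} "
          f"{s.posterior_median:6.1f} ms  95% CI ({s.ci95[0]:6.1f}, {s.ci95[1]:6.1f})")

report = sv.dic(samples, samples.spec, dataset)
print(f"DIC = {report.DIC:.0f}  (Dbar = {report.Dbar:.0f}, pD = {report.pD:.0f})")
```

prints

```
A control            -5.2 ms  95% CI ( -17.3,    7.2)
A female             27.1 ms  95% CI (  14.4,   40.6)
A dominant_male      10.0 ms  95% CI (  -2.1,   22.9)
A subordinate_male   -4.0 ms  95% CI ( -17.4,    8.5)
DIC = 4071  (Dbar = 3592, pD = 479)
```

Subject A's generating values were (0, +30, +15, −10) ms for the four
categories: the posterior medians land near the truth, the credible
intervals reflect ten sessions of data per cell, and the positive value
for female images means the animal gave up about 27 ms of juice access
per trial to view them.  The DIC decomposition shows the effective
parameter count (pD ≈ 479) is far below the nominal latent dimension —
the signature of partial pooling.

The same pipeline is scriptable from the shell:

```sh
socialvalue simulate --design small --seed 0 --out runs/sim
socialvalue fit --data runs/sim/choices.csv --model 6 --seed 1 --out runs/fit
socialvalue compare --data runs/sim/choices.csv --models 0,2,6 --out runs/cmp
socialvalue report --data runs/sim/choices.csv --samples runs/fit/samples --out runs/rep
```

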
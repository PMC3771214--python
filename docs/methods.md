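# Methods

## Model

The unit of observation is a block: all trials of one session in which a
fixed juice differential `dv` (seconds of solenoid-open time, image
option minus blank option) was paired with one of four image categories.
The generative model is a four-level hierarchy:

1. **Session values.** `v_msc ~ N(V_mc + α_mc t_s, σ_m²)`.  Each
   subject×category pair has a mean value `V_mc`; each subject has a
   session-to-session s.d. `σ_m`; `α_mc` is a linear drift in value per
   unit of the session-time covariate and is present only in the
   time-trend variant.
2. **Utility.** `η = (dv + v) / τ_s`.  The session-specific scale `τ_s`
   is the width of the session's choice curve; its distribution is shared
   by all subjects (no subject index).
3. **Overdispersed choice probability.**
   `logit p ~ N(η, ω_m²)` adds subject-specific variability beyond
   binomial noise.
4. **Counts.** `n ~ Binomial(N, p)`.

Units: all value-like parameters are held in seconds of juice access
internally; file I/O and reports use milliseconds.  The indifference
point (PSE) is `dv* = −v`.

**Priors** (all on the seconds scale): `V_mc ~ N(0, 0.01)`,
`σ_m ~ U(10⁻⁶, 1)`, `log ω_m ~ U(−6, 2)`,
`τ_s ~ t₊(ℓ, ς, ν)` — a Student-t truncated to the positive reals and
renormalized — with `ℓ ~ U(0, 0.5)`, `ς ~ U(10⁻⁴, 0.1)`,
`ν ~ U(0.1, 50)`, and `α_mc ~ N(0, 0.01)`.  These are weakly
informative: the value prior s.d. (100 ms) is far larger than any
plausible image value.  The same prior family is used by every pooling
variant, including the non-hierarchical ones.

**Session-time covariate.** Within each subject, session dates are rank
ordered (ties get midranks, so the transform is deterministic and
order-independent) and z-scored with the population (divide-by-n)
standard deviation, making "mean 0, unit variance" exact for the
realized covariate vector.  Per-subject z-scoring is used because the
drift enters a per-subject regression; a subject with a single session
gets covariate 0 with a warning.  Trend summaries are reported in ms per
standardized rank unit, with a per-session rescaling (one session step =
`sqrt(12/(k²−1))` standardized units for k evenly ranked sessions)
emitted alongside.

## Pooling variants

Eight variants arise from pooling each factor: sessions
(none / partial / complete), categories (none / complete), subjects
(none / complete).  "Complete" collapses the factor's index to one
group; "none" keeps independent parameters per level with shared priors;
"partial" (sessions only) is the Gaussian hierarchy above.  Model 0
(all sessions independent) keeps a per-(session, category) value with
the `V` prior applied directly and no hierarchy — a regularized
Bayesian analogue of per-session fitting.  The time-trend variant
(model 7) extends model 6 and requires partial session pooling.

## Sampling

The joint density is handled in latent-augmented form: the block logits
and session values are explicit parameters, matching the hierarchical
statement of the model (a quadrature-based marginal likelihood exists in
the test suite as an independent oracle, never in the sampling path).

The kernel is a deterministic-scan hybrid Gibbs sampler:

* `v`, `V`, and `α` have linear-Gaussian full conditionals (the block
  logit is linear in the value at fixed `τ`) and are drawn **exactly**.
* The block logits and all positivity-constrained scales (`σ`, `ω`,
  `τ`, and the three `τ` hyperparameters) use adaptive random-walk
  Metropolis — on the log scale with the Jacobian where positive —
  vectorized across their conditionally independent components.
  Proposal scales adapt toward 44% acceptance during the adaptation and
  burn-in phases with a decaying Robbins–Monro gain, and are frozen
  afterwards so retained draws come from a fixed kernel.  Metropolis
  updates are repeated three times per sweep; the conjugate draws make
  these the mixing bottleneck, and the repetitions cut their
  autocorrelation at modest cost.
* Numerical floors: `τ ≥ 10⁻⁶ s` (the utility divides by τ), and the
  simulator floors `ω` at `10⁻⁸` logit units so the no-overdispersion
  limit can be exercised.

Chains run sequentially; per-chain generators are spawned from the
master seed via `numpy.random.SeedSequence.spawn`, so runs are
bit-reproducible.  Initialization is dispersed: `V`, `σ`, `ω`, and the
`τ` hyperparameters from their priors, `τ` at 0.05 s jittered, session
values at no-pooling inversions of the empirical block logits jittered,
and block logits at continuity-corrected empirical logits.  A start with
non-finite joint density is re-drawn (up to ten attempts).

The default protocol retains 1000 draws per chain from five chains
(1000 adaptation + 10,000 burn-in + 20,000 kept iterations thinned by
20).  Desk-scale work in the tests and the acceptance script uses two
chains with 200–300 adaptation, 400–600 burn-in, and 800–1600 kept
iterations thinned by 4 — sizes chosen so a full-model fit of the
canonical study takes a few seconds while all monitored parameters reach
split-R̂ < 1.1.

**Diagnostics.** Split-R̂ (chains halved, between/within variance
ratio) and an autocorrelation-based effective sample size (per-chain FFT
autocovariance, multi-chain variance correction, Geyer
initial-monotone-positive-pair truncation, capped at the draw count).
Both are cross-checked against arviz in the tests.  Monitored set: `V`,
`σ`, `ω`, `α`, `τ` and its hyperparameters, and `v`; the per-block
logits are retained by default (they are required for DIC and the
counts-level pooling metrics) but can be dropped to save memory.

## Model comparison and fit metrics

**DIC.** The deviance focus is the observed counts given each block's
latent choice probability: `D = −2 Σ log Binomial(n | N, p)`.  The
penalty is the Spiegelhalter plug-in `pD = D̄ − D(θ̄)` with the latent
means taken on the logit scale, and `DIC = D̄ + pD`.  This focus is
well defined under latent augmentation and invariant to the priors by
construction; a different focus convention (e.g. marginalizing the
latent level) would shift pD for all variants, so DIC values are
comparable within a run, not across conventions.  The comparison table
reports D̄'s Monte-Carlo s.e. from the autocorrelation-adjusted draw
count, the worst R̂ per fit, and a convergence flag; rows are sorted by
DIC with ties left in place.

**Level-wise R² and pooling fractions.** For each level carrying
variance, `R² = 1 − var(ε)/var(x)` and `λ = 1 − var(E_u[ε])/var(ε)`
with plug-in residuals at posterior means:

* counts — `ε = n/N − p̂`, units = (session, category) trial sets;
* utility — `ε = empirical logit (½-count corrected) − η̂`, units =
  sessions (the level of `τ_s`);
* session — `ε = v̂ − (V̂ + α̂ t)`, units = subject×category cells.

Variances are population variances over all entries; the between-unit
variance is the size-weighted variance of unit means (each residual
replaced by its unit mean), so the law of total variance pins
`λ ∈ [0, 1]` even for unbalanced units.  The level grouping ("units")
is a design choice — the level names alone do not determine it — so
these metrics are comparable across runs of this package, not across
differently grouped implementations.  Zero-variance levels are flagged
undefined (NaN) rather than invented.

**Shrinkage.** Partial pooling should interpolate: the posterior mean
session value should lie between a data-only estimate and the fitted
subject×category mean.  The data-only ("no pooling") endpoint is the ML
value in the plain logistic model `p = expit((dv + v)/τ̂_s)` with the
utility scale fixed at the session's posterior mean — the unique
no-pooling estimator on the model's own scale, computed from raw counts
only.  A per-category refit that estimates its own width is *not* a
valid endpoint here, because the hierarchy shares one `τ` per session
across categories; with per-category widths, strict between-ness fails
even for an exact sampler.  Separated cells (all choices one way) have
infinite data-only estimates and count as interpolating when the
posterior mean sits on the pooled side.  A 0.5 ms tolerance absorbs
Monte-Carlo error of the posterior means.

**Posterior predictive checking.** Fictitious sessions are simulated by
picking a whole joint posterior draw uniformly, drawing a fresh `τ` from
that draw's truncated-t hyperparameters, fresh session values from
`N(V, σ²)`, then block logits and counts — the full cascade below the
population level, with the dv grid and block size taken from the
observed data.  Fictitious and observed sessions are refit by the same
ML logistic choice-curve code (`logit p ~ β0 + β1 dv`; width `1/β1`,
PSE `−β0/β1`), and the value and width distributions are compared by
two-sample KS.  Refits under (near-)complete separation — all observed
fractions extreme, or |β1| implying a width below 1 ms — are flagged
divergent and excluded from distribution comparisons rather than given
fabricated values.

**Correlation scatter sampling.** Cross-category value correlations are
explored, not estimated: for a subject, whole `(session, draw)` vectors
`(v_1 … v_4)` are sampled uniformly with replacement from the pooled
posterior, preserving within-draw correlation structure.  Categories are
never mixed across draws — an independently shuffled version is the
negative control in the tests.

## Synthetic studies

The generator emulates the structure of the real colony data: subjects
with strongly unequal session counts (the archived shape is 8 subjects
with 60/32/51/23/14/10/8/8 sessions, 206 total), four categories per
session, a small dv grid (down to 3 levels), tens of choices per block,
and values from near zero to tens of ms including all-negative subjects.
It does **not** emulate within-session trial order, satiety, block
transitions, or any neural data, so passing tests speak to the
statistical machinery, not to those aspects of real experiments.

The canonical desk-scale fixture is 4 subjects × 10 sessions × 4
categories × 5 dv levels (±60, ±30, 0 ms) × N = 30, with fixed
realistic truth: `V_mc` within ±45 ms (one all-negative subject),
`σ_m` = 10–25 ms, `ω_m` = 0.3–0.6, `τ_s ~ t₊(0.05, 0.015, 6)`
(seeded draw).  Fixed realistic truth was chosen over prior-drawn truth
because the priors are deliberately far wider than observed behavior;
consequently the recovery experiment measures frequentist coverage at
fixed truth over 20 replicated studies (≈95% by asymptotic posterior
normality) rather than exact Bayesian calibration.

`draw_parameters` draws complete parameter sets from the stated priors
(truncated-t sampling by rejection of non-positive draws — exact at
these scales) and accepts fixed overrides for any parameter, validated
for shape and support.

## Problem sizes

Chosen as the package's own desk-scale defaults: recovery coverage uses
20 replications of the canonical study (320 subject×category cells);
the DIC-direction experiments use 4 subjects × 8 sessions with strong
(±60 ms spread) or zero between-subject heterogeneity; predictive
checks refit 160 fictitious sessions; conjugate kernel checks use two
chains of 5000 draws.  The counts 5000 (retained draws of the default
protocol), 32 (trend parameters of the archived design), 206 (archived
sessions), and 100 ms (value-prior s.d.) are recomputed, not assumed, by
the acceptance script.

## Known limitations

* DIC's pD depends on the deviance focus convention; comparisons to
  values computed with a different focus (or a different sampler's
  plug-in point) are approximate.
* The pooling-fraction λ depends on the chosen unit grouping per level.
* The no-pooling shrinkage endpoint conditions on the posterior-mean
  utility scale; it is data-only in its counts but not a fully joint
  per-session refit.
* Adaptive-Metropolis components mix more slowly than the conjugate
  draws; very short chains can under-disperse the scale parameters
  (the convergence table flags this via R̂/ESS).
* The sampler is specialized to this model family; it is validated
  against closed forms at the kernel level and against quadrature
  oracles at the density level, not against an external MCMC engine.
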
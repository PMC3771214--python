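"""Posterior sampling for the hierarchical choice model.

The kernel is a deterministic-scan hybrid Gibbs sampler tailored to the
latent-variable formulation of the model:

* every Gaussian full conditional is drawn exactly (session values ``v``,
  mean values ``V``, and drift rates ``alpha`` are conditionally
  linear-Gaussian given the block logits, because
  ``logit p ~ N((dv + v)/tau, omega^2)`` is linear in the value);
* the block logits and all positivity-constrained scale parameters
  (``sigma``, ``omega``, ``tau``, and the tau hyperparameters) are updated
  by adaptive random-walk Metropolis, on the log scale with the Jacobian
  where the parameter is positive.  Proposal scales adapt toward an
  acceptance rate of 0.44 during the adaptation and burn-in phases only,
  and are frozen afterwards, so the retained draws come from a fixed
  Markov kernel.

The sampled stationary distribution is the posterior defined by
:mod:`socialvalue.hier_model` for any of the pooling variants.  Chains are
run sequentially with per-chain generators spawned from the master seed
(``numpy.random.SeedSequence(seed).spawn``), so a run is bit-reproducible
given its configuration.

Convergence is monitored with the split-:math:`\\hat R` statistic
(between/within-chain variance ratio, halved chains) and an
autocorrelation-based effective sample size (Geyer initial-positive-pair
truncation with the multi-chain variance correction).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import stdtr

from .choice_data import Dataset
from .hier_model import (
    TAU_FLOOR,
    ModelIndex,
    ModelSpec,
    ParameterSet,
    _t_logpdf,
    log_likelihood,
    log_prior,
)

__all__ = [
    "ChainConfig",
    "PosteriorSamples",
    "run_mcmc",
    "rhat",
    "effective_sample_size",
    "convergence_table",
    "sample_scalar_posterior",
]

_TARGET_ACCEPT = 0.44  # optimal scalar random-walk acceptance rate


@dataclass(frozen=True)
class ChainConfig:
    """Multi-chain sampling protocol.

    Defaults are the full-scale protocol: five chains, 1000 adaptation
    iterations, 10,000 burn-in iterations, 20,000 post-burn iterations
    thinned by 20 — i.e. 1000 retained draws per chain, 5000 in total.
    Desk-scale fits use far smaller settings.
    """

    n_chains: int = 5
    n_adapt: int = 1000
    n_burn: int = 10000
    n_iter: int = 20000
    thin: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chains", "n_adapt", "n_burn", "n_iter", "thin"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_iter % self.thin != 0:
            raise ValueError("thin must divide n_iter evenly")

    @property
    def retained_per_chain(self) -> int:
        return self.n_iter // self.thin

    @property
    def retained_total(self) -> int:
        return self.n_chains * self.retained_per_chain

    def to_mapping(self) -> dict:
        return {k: getattr(self, k)
                for k in ("n_chains", "n_adapt", "n_burn", "n_iter", "thin", "seed")}


def dataset_fingerprint(dataset: Dataset) -> str:
    """SHA-256 of the canonical CSV serialization of a dataset."""
    text = dataset.to_frame().to_csv(index=False)
    return hashlib.sha256(text.encode()).hexdigest()


@dataclass
class PosteriorSamples:
    """Named posterior draws indexed by (chain, retained iteration, ...)."""

    draws: dict[str, np.ndarray]
    meta: dict

    def __post_init__(self) -> None:
        shapes = {k: v.shape[:2] for k, v in self.draws.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"inconsistent (chain, iteration) shapes: {shapes}")

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws_per_chain(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    @property
    def spec(self) -> ModelSpec:
        return ModelSpec.from_mapping(self.meta["spec"])

    def stacked(self, param: str) -> np.ndarray:
        """Draws with chains concatenated: shape (chains * draws, ...)."""
        x = self.draws[param]
        return x.reshape(-1, *x.shape[2:])

    # -- persistence: columnar .npy files plus a JSON manifest -------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "parameters": {k: list(v.shape) for k, v in self.draws.items()},
            "meta": self.meta,
        }
        with open(directory / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        for k, v in self.draws.items():
            np.save(directory / f"{k}.npy", v)

    @classmethod
    def load(cls, directory) -> "PosteriorSamples":
        directory = Path(directory)
        with open(directory / "manifest.json") as fh:
            manifest = json.load(fh)
        draws = {k: np.load(directory / f"{k}.npy")
                 for k in manifest["parameters"]}
        return cls(draws=draws, meta=manifest["meta"])


# ---------------------------------------------------------------------------
# the Gibbs/Metropolis chain


class _Chain:
    """State and update steps of one chain for one (spec, dataset) pair."""

    def __init__(self, index: ModelIndex, rng: np.random.Generator):
        self.ix = index
        self.spec = index.spec
        self.priors = index.spec.priors
        self.rng = rng
        ix = index
        # per-subject-group block counts and per-group cell counts
        self.blocks_per_subj = np.bincount(ix.block_subj, minlength=ix.n_subj_groups)
        self.cells_per_subj = (
            np.bincount(ix.session_subj, minlength=ix.n_subj_groups) * ix.n_cat_groups
        )
        self.cell_group = (  # (S, C) -> (subject group, cat group) flat id
            ix.session_subj[:, None] * ix.n_cat_groups
            + np.arange(ix.n_cat_groups)[None, :]
        )
        self.block_group = ix.block_subj * ix.n_cat_groups + ix.block_cat
        self.n_groups = ix.n_subj_groups * ix.n_cat_groups
        self.emp_logit = np.log((ix.n + 0.5) / (ix.N - ix.n + 0.5))
        self._init_state()
        # proposal log-steps
        self.ls_x = np.full(ix.n_blocks, np.log(0.5))
        self.ls_sigma = np.full(ix.n_subj_groups, np.log(0.3))
        self.ls_omega = np.full(ix.n_subj_groups, np.log(0.3))
        self.ls_tau = np.full(ix.n_sessions, np.log(0.3))
        self.ls_hyp = np.full(3, np.log(0.3))

    # -- initialization ----------------------------------------------------
    def _init_state(self) -> None:
        ix, p, rng = self.ix, self.priors, self.rng
        for _ in range(10):
            self.tau = 0.05 * np.exp(0.3 * rng.standard_normal(ix.n_sessions))
            self.x = self.emp_logit + 0.1 * rng.standard_normal(ix.n_blocks)
            self.omega = np.exp(rng.uniform(*p.log_omega_bounds, ix.n_subj_groups))
            self.tau_loc = rng.uniform(*p.tau_location_bounds)
            self.tau_scale = rng.uniform(*p.tau_scale_bounds)
            self.tau_df = rng.uniform(*p.tau_df_bounds)
            self.sigma = (rng.uniform(1e-3, 0.9, ix.n_subj_groups)
                          if ix.has_sigma else None)
            self.V = (rng.normal(0.0, np.sqrt(p.V_variance),
                                 (ix.n_subj_groups, ix.n_cat_groups))
                      if ix.has_V else None)
            self.alpha = (rng.normal(0.0, np.sqrt(p.alpha_variance),
                                     (ix.n_subj_groups, ix.n_cat_groups))
                          if ix.has_alpha else None)
            if ix.has_v:
                # no-pooling-style starts: invert the utility at the
                # empirical logit, averaged within each (session, category)
                y = self.tau[ix.block_session] * self.emp_logit - ix.dv
                num = np.bincount(ix.block_cell, weights=y, minlength=ix.n_cells)
                cnt = np.maximum(np.bincount(ix.block_cell, minlength=ix.n_cells), 1)
                self.v = (num / cnt).reshape(ix.n_sessions, ix.n_cat_groups)
                self.v += 0.01 * rng.standard_normal(self.v.shape)
            else:
                self.v = None
            if np.isfinite(self._joint_logpost()):
                return
        raise RuntimeError("could not find a finite starting point in 10 tries")

    def params(self) -> ParameterSet:
        return ParameterSet(
            V=self.V, sigma=self.sigma, omega=self.omega, tau=self.tau,
            tau_loc=self.tau_loc, tau_scale=self.tau_scale, tau_df=self.tau_df,
            alpha=self.alpha, v=self.v, logit_p=self.x)

    def _joint_logpost(self) -> float:
        try:
            prm = self.params()
            return (log_prior(prm, self.spec, None, self.ix)
                    + log_likelihood(prm, self.spec, None, self.ix))
        except (ValueError, FloatingPointError):
            return -np.inf

    # -- pieces ------------------------------------------------------------
    def _value_per_block(self) -> np.ndarray:
        ix = self.ix
        if ix.has_v:
            return self.v[ix.block_session, ix.block_cat]
        return self.V[ix.block_subj, ix.block_cat]

    def _eta(self) -> np.ndarray:
        ix = self.ix
        return (ix.dv + self._value_per_block()) / self.tau[ix.block_session]

    def _v_prior_mean_sd(self):
        """Latent-value prior mean (S, C) and per-session sd."""
        ix, p = self.ix, self.priors
        if self.spec.session_pooling == "partial":
            mean = self.V[ix.session_subj, :]
            if ix.has_alpha:
                mean = mean + self.alpha[ix.session_subj, :] * ix.session_t[:, None]
            sd = self.sigma[ix.session_subj][:, None]
            prec = 1.0 / (self.sigma[ix.session_subj] ** 2)[:, None]
            return mean, prec
        return np.zeros((ix.n_sessions, ix.n_cat_groups)), \
            np.full((ix.n_sessions, ix.n_cat_groups), 1.0 / p.V_variance)

    # -- updates -----------------------------------------------------------
    def update_x(self, adapt: bool, gamma: float) -> None:
        """Vectorized RWM over block logits (independent full conditionals)."""
        ix, rng = self.ix, self.rng
        eta = self._eta()
        om = self.omega[ix.block_subj]

        def logf(x):
            z = (x - eta) / om
            return -0.5 * z * z + ix.n * x - ix.N * np.logaddexp(0.0, x)

        prop = self.x + np.exp(self.ls_x) * rng.standard_normal(ix.n_blocks)
        delta = logf(prop) - logf(self.x)
        acc = np.log(rng.random(ix.n_blocks)) < delta
        self.x = np.where(acc, prop, self.x)
        if adapt:
            self.ls_x += gamma * (acc.astype(float) - _TARGET_ACCEPT)

    def update_v(self) -> None:
        """Exact Gaussian draw of each (session, category) value."""
        ix, rng = self.ix, self.rng
        tau_b = self.tau[ix.block_session]
        om_b = self.omega[ix.block_subj]
        var_b = (tau_b * om_b) ** 2
        y = tau_b * self.x - ix.dv
        prec_like = np.bincount(ix.block_cell, weights=1.0 / var_b,
                                minlength=ix.n_cells).reshape(ix.n_sessions, -1)
        num_like = np.bincount(ix.block_cell, weights=y / var_b,
                               minlength=ix.n_cells).reshape(ix.n_sessions, -1)
        mean0, prec0 = self._v_prior_mean_sd()
        prec = prec0 + prec_like
        mean = (prec0 * mean0 + num_like) / prec
        self.v = mean + rng.standard_normal(mean.shape) / np.sqrt(prec)

    def update_V(self) -> None:
        """Exact Gaussian draw of the mean values V per group."""
        ix, p, rng = self.ix, self.priors, self.rng
        if self.spec.session_pooling == "partial":
            z = self.v.copy()
            if ix.has_alpha:
                z -= self.alpha[ix.session_subj, :] * ix.session_t[:, None]
            w = 1.0 / (self.sigma[ix.session_subj] ** 2)[:, None]
            w = np.broadcast_to(w, z.shape)
            gid = self.cell_group.ravel()
            prec_like = np.bincount(gid, weights=w.ravel(), minlength=self.n_groups)
            num_like = np.bincount(gid, weights=(w * z).ravel(),
                                   minlength=self.n_groups)
        else:  # complete session pooling: V enters the block level directly
            tau_b = self.tau[ix.block_session]
            var_b = (tau_b * self.omega[ix.block_subj]) ** 2
            y = tau_b * self.x - ix.dv
            prec_like = np.bincount(self.block_group, weights=1.0 / var_b,
                                    minlength=self.n_groups)
            num_like = np.bincount(self.block_group, weights=y / var_b,
                                   minlength=self.n_groups)
        prec = 1.0 / p.V_variance + prec_like
        mean = num_like / prec
        draw = mean + rng.standard_normal(self.n_groups) / np.sqrt(prec)
        self.V = draw.reshape(ix.n_subj_groups, ix.n_cat_groups)

    def update_alpha(self) -> None:
        """Exact Gaussian draw of the drift rates (time-trend model)."""
        ix, p, rng = self.ix, self.priors, self.rng
        z = self.v - self.V[ix.session_subj, :]
        t = ix.session_t[:, None]
        w = 1.0 / (self.sigma[ix.session_subj] ** 2)[:, None]
        gid = self.cell_group.ravel()
        prec_like = np.bincount(gid, weights=np.broadcast_to(w * t * t, z.shape).ravel(),
                                minlength=self.n_groups)
        num_like = np.bincount(gid, weights=(w * t * z).ravel(),
                               minlength=self.n_groups)
        prec = 1.0 / p.alpha_variance + prec_like
        mean = num_like / prec
        draw = mean + rng.standard_normal(self.n_groups) / np.sqrt(prec)
        self.alpha = draw.reshape(ix.n_subj_groups, ix.n_cat_groups)

    def update_sigma(self, adapt: bool, gamma: float) -> None:
        """RWM on log sigma; uniform prior on sigma itself."""
        ix, p, rng = self.ix, self.priors, self.rng
        mean = self.V[ix.session_subj, :]
        if ix.has_alpha:
            mean = mean + self.alpha[ix.session_subj, :] * ix.session_t[:, None]
        ss = np.bincount(ix.session_subj,
                         weights=((self.v - mean) ** 2).sum(axis=1),
                         minlength=ix.n_subj_groups)
        cnt = self.cells_per_subj
        lo, hi = p.sigma_bounds

        def logf(log_sig):
            sig = np.exp(log_sig)
            out = -(cnt - 1.0) * log_sig - ss / (2.0 * sig**2)
            return np.where((sig > lo) & (sig < hi), out, -np.inf)

        cur = np.log(self.sigma)
        prop = cur + np.exp(self.ls_sigma) * rng.standard_normal(cur.shape)
        acc = np.log(rng.random(cur.shape)) < logf(prop) - logf(cur)
        self.sigma = np.exp(np.where(acc, prop, cur))
        if adapt:
            self.ls_sigma += gamma * (acc.astype(float) - _TARGET_ACCEPT)

    def update_omega(self, adapt: bool, gamma: float) -> None:
        """RWM on log omega; flat prior on log omega within bounds."""
        ix, p, rng = self.ix, self.priors, self.rng
        r = self.x - self._eta()
        ss = np.bincount(ix.block_subj, weights=r * r, minlength=ix.n_subj_groups)
        cnt = self.blocks_per_subj
        lo, hi = p.log_omega_bounds

        def logf(log_om):
            om2 = np.exp(2.0 * log_om)
            out = -cnt * log_om - ss / (2.0 * om2)
            return np.where((log_om > lo) & (log_om < hi), out, -np.inf)

        cur = np.log(self.omega)
        prop = cur + np.exp(self.ls_omega) * rng.standard_normal(cur.shape)
        acc = np.log(rng.random(cur.shape)) < logf(prop) - logf(cur)
        self.omega = np.exp(np.where(acc, prop, cur))
        if adapt:
            self.ls_omega += gamma * (acc.astype(float) - _TARGET_ACCEPT)

    def update_tau(self, adapt: bool, gamma: float) -> None:
        """Vectorized RWM on log tau per session.

        The per-session log likelihood is quadratic in 1/tau, so the three
        sufficient statistics (A, B, C) are accumulated once per sweep.
        """
        ix, rng = self.ix, self.rng
        w = 1.0 / self.omega[ix.block_subj] ** 2
        b = ix.dv + self._value_per_block()
        A = np.bincount(ix.block_session, weights=w * self.x * self.x,
                        minlength=ix.n_sessions)
        B = np.bincount(ix.block_session, weights=w * self.x * b,
                        minlength=ix.n_sessions)
        Cs = np.bincount(ix.block_session, weights=w * b * b,
                         minlength=ix.n_sessions)

        def logf(log_tau):
            tau = np.exp(log_tau)
            loglik = -0.5 * (A - 2.0 * B / tau + Cs / tau**2)
            lp = (_t_logpdf(tau, self.tau_df, self.tau_loc, self.tau_scale)
                  + log_tau)  # Jacobian of the log transform
            out = loglik + lp
            return np.where(tau >= TAU_FLOOR, out, -np.inf)

        cur = np.log(self.tau)
        prop = cur + np.exp(self.ls_tau) * rng.standard_normal(cur.shape)
        acc = np.log(rng.random(cur.shape)) < logf(prop) - logf(cur)
        self.tau = np.exp(np.where(acc, prop, cur))
        if adapt:
            self.ls_tau += gamma * (acc.astype(float) - _TARGET_ACCEPT)

    def _tau_hyper_loglik(self, loc: float, scale: float, df: float) -> float:
        # truncated-t log density of all tau draws under (loc, scale, df)
        mass = stdtr(df, loc / scale)
        if mass <= 0.0:
            return -np.inf
        return float(np.sum(_t_logpdf(self.tau, df, loc, scale))
                     - self.tau.size * np.log(mass))

    def update_tau_hypers(self, adapt: bool, gamma: float) -> None:
        """Sequential scalar RWM on the tau-prior hyperparameters."""
        p, rng = self.priors, self.rng
        bounds = (p.tau_location_bounds, p.tau_scale_bounds, p.tau_df_bounds)
        vals = [self.tau_loc, self.tau_scale, self.tau_df]
        cur_ll = self._tau_hyper_loglik(*vals)
        for i in range(3):
            lo, hi = bounds[i]
            prop = vals[i] + np.exp(self.ls_hyp[i]) * (hi - lo) \
                * rng.standard_normal()
            acc = False
            if lo < prop < hi:
                cand = list(vals)
                cand[i] = prop
                ll = self._tau_hyper_loglik(*cand)
                if np.log(rng.random()) < ll - cur_ll:
                    vals, cur_ll, acc = cand, ll, True
            if adapt:
                self.ls_hyp[i] += gamma * (float(acc) - _TARGET_ACCEPT)
        self.tau_loc, self.tau_scale, self.tau_df = vals

    # Metropolis steps are repeated within a sweep: the conjugate draws are
    # exact, so overall mixing is limited by the random-walk components
    # (block logits and the scale parameters).  A few cheap repetitions per
    # sweep cut their autocorrelation substantially.
    N_REP_X = 3
    N_REP_SCALE = 3

    def sweep(self, adapt: bool, gamma: float) -> None:
        for _ in range(self.N_REP_X):
            self.update_x(adapt, gamma)
        if self.ix.has_v:
            self.update_v()
        if self.ix.has_V:
            self.update_V()
        if self.ix.has_alpha:
            self.update_alpha()
        for _ in range(self.N_REP_SCALE):
            if self.ix.has_sigma:
                self.update_sigma(adapt, gamma)
            self.update_omega(adapt, gamma)
            self.update_tau(adapt, gamma)
            self.update_tau_hypers(adapt, gamma)


def _monitored(chain: _Chain, keep_latent_p: bool) -> dict[str, np.ndarray | float]:
    out: dict[str, np.ndarray | float] = {
        "omega": chain.omega.copy(),
        "tau": chain.tau.copy(),
        "tau_loc": chain.tau_loc,
        "tau_scale": chain.tau_scale,
        "tau_df": chain.tau_df,
    }
    if chain.ix.has_V:
        out["V"] = chain.V.copy()
    if chain.ix.has_sigma:
        out["sigma"] = chain.sigma.copy()
    if chain.ix.has_alpha:
        out["alpha"] = chain.alpha.copy()
    if chain.ix.has_v:
        out["v"] = chain.v.copy()
    if keep_latent_p:
        out["logit_p"] = chain.x.copy()
    return out


def run_mcmc(spec: ModelSpec, dataset: Dataset, config: ChainConfig,
             keep_latent_p: bool = True) -> PosteriorSamples:
    """Sample the posterior of ``spec`` on ``dataset``.

    Returns ``config.n_iter // config.thin`` retained draws per chain.
    Deterministic given ``config.seed``.  ``keep_latent_p`` retains the
    per-block latent logits (needed for DIC and the count-level pooling
    metrics; switch off only to save memory).
    """
    index = ModelIndex(dataset, spec)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    n_pre = config.n_adapt + config.n_burn
    retained_per_chain = config.retained_per_chain

    storage: dict[str, list] = {}
    for c_ix in range(config.n_chains):
        rng = np.random.default_rng(seeds[c_ix])
        chain = _Chain(index, rng)
        kept: list[dict] = []
        for it in range(n_pre + config.n_iter):
            adapt = it < n_pre
            gamma = min(0.25, (it + 1.0) ** -0.6) if adapt else 0.0
            chain.sweep(adapt, gamma)
            if it >= n_pre and (it - n_pre + 1) % config.thin == 0:
                kept.append(_monitored(chain, keep_latent_p))
        assert len(kept) == retained_per_chain
        for name in kept[0]:
            storage.setdefault(name, []).append(
                np.stack([np.asarray(d[name]) for d in kept]))

    draws = {name: np.stack(chain_list) for name, chain_list in storage.items()}
    meta = {
        "config": config.to_mapping(),
        "spec": spec.to_mapping(),
        "sessions": index.sessions,
        "subjects": index.subjects,
        "session_subjects": [dataset.subject_of[s] for s in index.sessions],
        "n_cat_groups": index.n_cat_groups,
        "n_subj_groups": index.n_subj_groups,
        "fingerprint": dataset_fingerprint(dataset),
    }
    return PosteriorSamples(draws=draws, meta=meta)


# ---------------------------------------------------------------------------
# convergence diagnostics


def _split_chains(x: np.ndarray) -> np.ndarray:
    """Split each chain in half: (m, n, ...) -> (2m, n//2, ...)."""
    m, n = x.shape[:2]
    half = n // 2
    x = x[:, : 2 * half]
    return x.reshape(m, 2, half, *x.shape[2:]).reshape(2 * m, half, *x.shape[2:])


def _rhat_1d(x: np.ndarray) -> float:
    x = _split_chains(x)
    m, n = x.shape
    means = x.mean(axis=1)
    w = float(np.mean(x.var(axis=1, ddof=1)))
    b = n * float(np.var(means, ddof=1))
    if w == 0.0:
        warnings.warn("zero within-chain variance; Rhat undefined", stacklevel=3)
        return np.nan
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _ess_1d(x: np.ndarray) -> float:
    x = _split_chains(x)
    m, n = x.shape
    means = x.mean(axis=1, keepdims=True)
    w = float(np.mean(x.var(axis=1, ddof=1)))
    if w == 0.0:
        warnings.warn("zero within-chain variance; ESS undefined", stacklevel=3)
        return np.nan
    b = n * float(np.var(means.ravel(), ddof=1))
    var_plus = (n - 1) / n * w + b / n
    # per-chain autocovariance via FFT (biased, divisor n)
    centered = x - means
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(centered, nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), nfft, axis=1)[:, :n].real / n
    mean_acov = acov.mean(axis=0)
    rho = 1.0 - (w - mean_acov) / var_plus
    # Geyer initial monotone positive sequence over lag pairs
    max_pairs = (n - 1) // 2
    tau = rho[0]  # lag-0 term (~1)
    prev = np.inf
    for k in range(1, max_pairs + 1):
        pair = rho[2 * k - 1] + rho[2 * k]
        if pair < 0:
            break
        pair = min(pair, prev)
        tau += 2.0 * pair
        prev = pair
    ess = m * n / max(tau, 1e-12)
    return float(min(ess, m * n))


def _per_component(samples: PosteriorSamples, param: str, fn):
    if param not in samples.draws:
        raise KeyError(f"parameter {param!r} not in samples "
                       f"({sorted(samples.draws)})")
    x = samples.draws[param]
    if x.shape[0] < 2:
        raise ValueError("need >= 2 chains; with one chain use ESS per chain only")
    if x.shape[1] < 10:
        raise ValueError("need >= 10 retained draws per chain")
    if x.ndim == 2:
        return fn(x)
    flat = x.reshape(x.shape[0], x.shape[1], -1)
    out = np.array([fn(flat[:, :, j]) for j in range(flat.shape[2])])
    return out.reshape(x.shape[2:])


def rhat(samples: PosteriorSamples, param: str):
    """Split-:math:`\\hat R` for ``param``; scalar or array matching its shape.

    Values near 1 indicate the chains have mixed; the conventional
    convergence criterion is :math:`\\hat R < 1.1`.  NaN (with a warning)
    marks a degenerate
    zero-variance parameter.
    """
    return _per_component(samples, param, _rhat_1d)


def effective_sample_size(samples: PosteriorSamples, param: str):
    """Autocorrelation-based effective sample size, capped at the draw count."""
    return _per_component(samples, param, _ess_1d)


def convergence_table(samples: PosteriorSamples,
                      params: list[str] | None = None):
    """Per-scalar-component Rhat/ESS table (pandas DataFrame).

    By default covers the monitored structural parameters (everything
    except the per-block latent logits).
    """
    import pandas as pd

    if params is None:
        params = [k for k in samples.draws if k != "logit_p"]
    rows = []
    for name in params:
        r = np.atleast_1d(rhat(samples, name))
        e = np.atleast_1d(effective_sample_size(samples, name))
        shape = samples.draws[name].shape[2:]
        for j, (rv, ev) in enumerate(zip(r.ravel(), e.ravel())):
            ix = np.unravel_index(j, shape) if shape else ()
            label = name + ("[" + ",".join(map(str, ix)) + "]" if ix else "")
            rows.append({"parameter": label, "rhat": rv, "ess": ev})
    return pd.DataFrame(rows, columns=["parameter", "rhat", "ess"])


# ---------------------------------------------------------------------------
# elementary kernel, exposed for validation against conjugate models


def sample_scalar_posterior(logpdf, x0: float, n_draws: int, n_burn: int,
                            rng: np.random.Generator,
                            step: float = 1.0) -> np.ndarray:
    """Adaptive random-walk Metropolis on a scalar log density.

    This is the same update rule the Gibbs sweep applies to its scale
    parameters (Gaussian proposal, adaptation toward 44% acceptance during
    burn-in, frozen step afterwards).  Exposed so the elementary kernel can
    be validated against closed-form conjugate posteriors.
    """
    x = float(x0)
    ls = np.log(step)
    cur = logpdf(x)
    if not np.isfinite(cur):
        raise ValueError("logpdf(x0) must be finite")
    out = np.empty(n_draws)
    for it in range(n_burn + n_draws):
        prop = x + np.exp(ls) * rng.standard_normal()
        lp = logpdf(prop)
        acc = np.log(rng.random()) < lp - cur
        if acc:
            x, cur = prop, lp
        if it < n_burn:
            ls += min(0.25, (it + 1.0) ** -0.6) * (float(acc) - _TARGET_ACCEPT)
        else:
            out[it - n_burn] = x
    return out
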
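"""Model criticism: pooling metrics, DIC comparison, and predictive checks.

Three complementary views of a fitted hierarchy:

* **Level-wise fit and pooling** — for each level that carries variance
  (choice counts, scaled utilities, session values) a variance-explained
  fraction ``R^2 = 1 - var(eps)/var(x)`` and a pooling fraction
  ``lambda = 1 - var(E_u[eps])/var(eps)``, where ``eps`` are plug-in
  residuals at posterior means and ``E_u`` averages residuals within
  units.  ``lambda = 1`` means residuals carry no between-unit structure
  (complete pooling); ``lambda = 0`` means they are all between-unit
  (no pooling).
* **DIC** — the deviance information criterion with the plug-in
  (Spiegelhalter) penalty: ``Dbar`` is the posterior-mean deviance of the
  counts given each block's latent choice probability,
  ``pD = Dbar - D(posterior mean)`` with the latent means taken on the
  logit scale, and ``DIC = Dbar + pD``.  Lower is better.
* **Posterior predictive sessions** — fictitious sessions simulated from
  the fitted posterior (hyperparameter draws propagated through the
  generative model), refit with the same standard logistic choice curve
  ``logit p ~ b0 + b1 dv`` as the observed data, so value and width
  distributions can be compared like-for-like.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .choice_data import CATEGORIES, ChoiceBlock, Dataset
from .hier_model import ModelIndex, ModelSpec
from .sampler import ChainConfig, PosteriorSamples, _ess_1d, rhat, run_mcmc
from .synthetic_data import _truncated_t_positive

__all__ = [
    "PoolingReport",
    "DicReport",
    "ChoiceCurveFit",
    "variance_explained",
    "pooling_fraction",
    "pooling_metrics",
    "dic",
    "compare_models",
    "posterior_predictive_sessions",
    "fit_choice_curve",
    "refit_choice_curves",
]


# ---------------------------------------------------------------------------
# pooling metrics (R^2 and lambda per level)


def variance_explained(x: np.ndarray, residuals: np.ndarray) -> float:
    """``R^2 = 1 - var(eps)/var(x)`` with population variances.

    Returns NaN (flagged undefined) when ``x`` has zero variance.
    """
    vx = float(np.var(x))
    if vx == 0.0:
        warnings.warn("zero total variance; R^2 undefined", stacklevel=2)
        return np.nan
    return 1.0 - float(np.var(residuals)) / vx


def pooling_fraction(residuals: np.ndarray, unit_ids: np.ndarray) -> float:
    """``lambda = 1 - var(E_u[eps]) / var(eps)`` over the given units.

    The between-unit variance is the size-weighted population variance of
    the unit means (each residual replaced by its unit's mean), so by the
    law of total variance lambda always lands in [0, 1], also for
    unbalanced units.
    """
    residuals = np.asarray(residuals, dtype=float)
    unit_ids = np.asarray(unit_ids)
    ve = float(np.var(residuals))
    if ve == 0.0:
        warnings.warn("zero residual variance; lambda undefined", stacklevel=2)
        return np.nan
    _, inverse = np.unique(unit_ids, return_inverse=True)
    sums = np.bincount(inverse, weights=residuals)
    cnts = np.bincount(inverse)
    unit_means = sums / cnts
    return 1.0 - float(np.var(unit_means[inverse])) / ve


@dataclass
class PoolingReport:
    """R^2 / lambda per level, with residuals retained for audit.

    ``levels`` maps each level name (``session``, ``utility``, ``counts``)
    to a dict with keys ``R2``, ``lambda``, ``x``, ``residuals``,
    ``unit_ids``.
    """

    levels: dict[str, dict]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"level": name, "R2": d["R2"], "lambda": d["lambda"]}
                for name, d in self.levels.items()]
        return pd.DataFrame(rows, columns=["level", "R2", "lambda"])


def _posterior_mean(samples: PosteriorSamples, name: str) -> np.ndarray:
    return samples.stacked(name).mean(axis=0)


def pooling_metrics(samples: PosteriorSamples, spec: ModelSpec,
                    dataset: Dataset) -> PoolingReport:
    """Level-wise R^2 and pooling fraction at plug-in posterior means.

    Levels and their residuals:

    * ``counts`` — observed choice fraction ``n/N`` minus the posterior
      mean choice probability (latent logits averaged on the logit
      scale); units are (session, category) trial sets.
    * ``utility`` — empirical block logit (1/2-count continuity
      correction) minus the posterior-mean utility
      ``(dv + v)/tau``; units are sessions.
    * ``session`` — posterior-mean session values minus their fitted
      level means ``V + alpha t``; units are subject x category cells.
    """
    if spec.session_pooling != "partial":
        raise ValueError("pooling metrics require a partial-pooling model")
    index = ModelIndex(dataset, spec)
    if "logit_p" not in samples.draws:
        raise ValueError("samples must retain logit_p for pooling metrics")

    xbar = _posterior_mean(samples, "logit_p")
    vbar = _posterior_mean(samples, "v")
    Vbar = _posterior_mean(samples, "V")
    taubar = _posterior_mean(samples, "tau")
    abar = _posterior_mean(samples, "alpha") if "alpha" in samples.draws else None

    levels: dict[str, dict] = {}

    # counts level: probability scale, units = (session, category) cells
    frac = index.n / index.N
    p_hat = 1.0 / (1.0 + np.exp(-xbar))
    eps_n = frac - p_hat
    levels["counts"] = {
        "R2": variance_explained(frac, eps_n),
        "lambda": pooling_fraction(eps_n, index.block_cell),
        "x": frac, "residuals": eps_n, "unit_ids": index.block_cell,
    }

    # utility level: logit scale, units = sessions
    emp_logit = np.log((index.n + 0.5) / (index.N - index.n + 0.5))
    eta_hat = (index.dv + vbar[index.block_session, index.block_cat]) \
        / taubar[index.block_session]
    eps_eta = emp_logit - eta_hat
    levels["utility"] = {
        "R2": variance_explained(emp_logit, eps_eta),
        "lambda": pooling_fraction(eps_eta, index.block_session),
        "x": emp_logit, "residuals": eps_eta, "unit_ids": index.block_session,
    }

    # session level: value scale, units = subject x category cells
    mean_v = Vbar[index.session_subj, :]
    if abar is not None:
        mean_v = mean_v + abar[index.session_subj, :] * index.session_t[:, None]
    eps_v = (vbar - mean_v).ravel()
    unit_mc = (index.session_subj[:, None] * index.n_cat_groups
               + np.arange(index.n_cat_groups)[None, :]).ravel()
    levels["session"] = {
        "R2": variance_explained(vbar.ravel(), eps_v),
        "lambda": pooling_fraction(eps_v, unit_mc),
        "x": vbar.ravel(), "residuals": eps_v, "unit_ids": unit_mc,
    }
    return PoolingReport(levels=levels)


# ---------------------------------------------------------------------------
# DIC


@dataclass(frozen=True)
class DicReport:
    """Posterior-mean deviance, effective parameter count, and their sum."""

    Dbar: float
    pD: float
    DIC: float
    n_draws: int
    n_excluded: int
    Dbar_se: float

    @classmethod
    def from_parts(cls, Dbar: float, pD: float, n_draws: int,
                   n_excluded: int, Dbar_se: float) -> "DicReport":
        return cls(Dbar=Dbar, pD=pD, DIC=Dbar + pD, n_draws=n_draws,
                   n_excluded=n_excluded, Dbar_se=Dbar_se)


def _deviance_draws(samples: PosteriorSamples, index: ModelIndex) -> np.ndarray:
    """Deviance of the counts per retained draw, shape (chains, draws)."""
    x = samples.draws["logit_p"]  # (chains, draws, blocks)
    const = float(np.sum(index.log_binom_coef))
    ll = const + x @ index.n - np.logaddexp(0.0, x) @ index.N
    return -2.0 * ll


def dic(samples: PosteriorSamples, spec: ModelSpec, dataset: Dataset) -> DicReport:
    """DIC with the plug-in penalty ``pD = Dbar - D(posterior-mean logits)``.

    Non-finite deviance draws are excluded (their count is reported);
    more than 1% non-finite draws raises.
    """
    if "logit_p" not in samples.draws:
        raise ValueError("samples must retain logit_p to compute DIC")
    index = ModelIndex(dataset, spec)
    dev = _deviance_draws(samples, index)
    finite = np.isfinite(dev)
    n_total = dev.size
    n_bad = int(n_total - finite.sum())
    if n_bad > 0.01 * n_total:
        raise ValueError(f"{n_bad}/{n_total} non-finite deviance draws")
    x = samples.draws["logit_p"]
    flat = x.reshape(-1, x.shape[-1])[finite.ravel()]
    dbar = float(dev[finite].mean())
    xbar = flat.mean(axis=0)
    const = float(np.sum(index.log_binom_coef))
    d_at_mean = -2.0 * (const + xbar @ index.n - np.logaddexp(0.0, xbar) @ index.N)
    # MC standard error of Dbar from the autocorrelation-adjusted draw count
    if dev.shape[0] >= 2 and dev.shape[1] >= 10 and np.var(dev) > 0:
        ess = _ess_1d(np.where(finite, dev, dbar))
        se = float(np.std(dev[finite]) / np.sqrt(max(ess, 1.0)))
    else:
        se = float("nan")
    return DicReport.from_parts(Dbar=dbar, pD=dbar - float(d_at_mean),
                                n_draws=int(finite.sum()), n_excluded=n_bad,
                                Dbar_se=se)


def compare_models(dataset: Dataset, specs: list[ModelSpec],
                   config: ChainConfig) -> pd.DataFrame:
    """Fit each spec, compute DIC, and return a table sorted by DIC.

    Columns mirror the standard comparison layout: model number (when the
    spec is a canonical variant), description, the pooling triple, Dbar,
    pD, DIC, the Dbar Monte-Carlo s.e., the worst Rhat over monitored
    structural parameters, and a convergence flag (Rhat < 1.1).  Ties are
    left in place (stable sort), not broken.
    """
    rows = []
    for spec in specs:
        samples = run_mcmc(spec, dataset, config, keep_latent_p=True)
        report = dic(samples, spec, dataset)
        worst = 0.0
        for name in samples.draws:
            if name == "logit_p":
                continue
            r = np.atleast_1d(rhat(samples, name))
            r = r[np.isfinite(r)]
            if r.size:
                worst = max(worst, float(r.max()))
        rows.append({
            "model": spec.model_number,
            "description": spec.description,
            "session": spec.session_pooling,
            "category": spec.category_pooling,
            "subject": spec.subject_pooling,
            "Dbar": report.Dbar,
            "pD": report.pD,
            "DIC": report.DIC,
            "Dbar_se": report.Dbar_se,
            "max_rhat": worst,
            "converged": bool(worst < 1.1),
        })
    frame = pd.DataFrame(rows)
    return frame.sort_values("DIC", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# shrinkage: no-pooling session estimates vs posterior session values


def no_pooling_values(dataset: Dataset, spec: ModelSpec,
                      tau_by_session: np.ndarray) -> np.ndarray:
    """Data-only (no-pooling) session value estimates, shape (S, C).

    For each (session, category) trial set, the ML estimate of the value
    ``v`` in the plain logistic model ``p = expit((dv + v)/tau_s)`` with
    the utility scale fixed at the supplied per-session value — the
    estimate a per-session fit would produce on the model's own scale,
    using no information from other sessions.  Separated cells (all
    choices one way) give ``+/-inf``.
    """
    from scipy.optimize import brentq
    from scipy.special import expit

    index = ModelIndex(dataset, spec)
    out = np.empty((index.n_sessions, index.n_cat_groups))
    for s in range(index.n_sessions):
        tau = float(tau_by_session[s])
        for c in range(index.n_cat_groups):
            m = (index.block_session == s) & (index.block_cat == c)
            dv, n, N = index.dv[m], index.n[m], index.N[m]

            def score(v):
                return float(np.sum(n - N * expit((dv + v) / tau)))

            lo, hi = -1.0, 1.0  # +/- 1 s bracket, far beyond any real value
            if score(lo) <= 0:
                out[s, c] = -np.inf
            elif score(hi) >= 0:
                out[s, c] = np.inf
            else:
                out[s, c] = brentq(score, lo, hi, xtol=1e-10)
    return out


def shrinkage_fraction(samples: PosteriorSamples, spec: ModelSpec,
                       dataset: Dataset, tol: float = 0.0005) -> float:
    """Fraction of (session, category) cells where partial pooling
    interpolates: the posterior mean session value lies between the
    no-pooling estimate (:func:`no_pooling_values` at the posterior-mean
    scale) and the fitted subject x category mean.

    ``tol`` (seconds) absorbs Monte-Carlo error of the posterior means.
    Separated cells count as interpolating when the posterior mean sits on
    the pooled-mean side of the (infinite) no-pooling estimate.
    """
    index = ModelIndex(dataset, spec)
    vbar = _posterior_mean(samples, "v")
    Vbar = _posterior_mean(samples, "V")
    taubar = _posterior_mean(samples, "tau")
    abar = _posterior_mean(samples, "alpha") if "alpha" in samples.draws else None
    pooled = Vbar[index.session_subj, :]
    if abar is not None:
        pooled = pooled + abar[index.session_subj, :] * index.session_t[:, None]
    v_np = no_pooling_values(dataset, spec, taubar)
    lo = np.minimum(v_np, pooled) - tol
    hi = np.maximum(v_np, pooled) + tol
    inside = (vbar >= lo) & (vbar <= hi)
    return float(inside.mean())


# ---------------------------------------------------------------------------
# posterior predictive sessions


def _common_dv_grid(dataset: Dataset) -> np.ndarray:
    dvs = sorted({b.dv for b in dataset.blocks})
    if len(dvs) > 12:  # irregular grids: keep the most frequent levels
        counts: dict[float, int] = {}
        for b in dataset.blocks:
            counts[b.dv] = counts.get(b.dv, 0) + 1
        dvs = sorted(sorted(counts, key=counts.get, reverse=True)[:12])
    return np.asarray(dvs)


def posterior_predictive_sessions(samples: PosteriorSamples, dataset: Dataset,
                                  n_sessions: int,
                                  rng: np.random.Generator) -> Dataset:
    """Simulate fictitious sessions from the fitted posterior.

    Each fictitious session takes one joint posterior draw (chain,
    iteration picked uniformly), assigns a subject by cycling through the
    fitted subjects, draws a fresh utility scale from the draw's
    truncated-t hyperparameters, fresh session values from
    ``N(V_mc, sigma_m^2)``, then block logits and binomial counts — the
    full generative cascade below the population level.  The dv grid and
    block size are taken from the observed dataset.
    """
    spec = samples.spec
    if spec.session_pooling != "partial":
        raise ValueError("posterior predictive sessions require a hierarchical fit")
    subjects = (["pooled"] if spec.subject_pooling == "complete"
                else list(samples.meta["subjects"]))
    # under complete category pooling all categories behave identically;
    # emit the control label so the output is still a valid Dataset
    cats = ([CATEGORIES[0]] if spec.category_pooling == "complete"
            else list(CATEGORIES))

    dv_grid = _common_dv_grid(dataset)
    N_block = int(np.median([b.N for b in dataset.blocks]))

    V = samples.stacked("V")        # (draws, M, C)
    sigma = samples.stacked("sigma")
    omega = samples.stacked("omega")
    loc = samples.stacked("tau_loc")
    scale = samples.stacked("tau_scale")
    df = samples.stacked("tau_df")
    n_total = V.shape[0]

    blocks: list[ChoiceBlock] = []
    session_dates: dict[str, date] = {}
    subject_of: dict[str, str] = {}
    day0 = date(2030, 1, 1)
    for i in range(n_sessions):
        m = i % len(subjects)
        d = int(rng.integers(n_total))
        tau = float(_truncated_t_positive(rng, float(loc[d]), float(scale[d]),
                                          float(df[d]), 1)[0])
        sid = f"ppc_{subjects[m]}_{i:04d}"
        session_dates[sid] = day0 + timedelta(days=i)
        subject_of[sid] = subjects[m]
        for c, cat in enumerate(cats):
            v = rng.normal(V[d, m, c], sigma[d, m])
            for dv in dv_grid:
                eta = (dv + v) / tau
                logit_p = rng.normal(eta, omega[d, m])
                p = 1.0 / (1.0 + np.exp(-logit_p))
                n = int(rng.binomial(N_block, p))
                blocks.append(ChoiceBlock(subjects[m], sid, cat, float(dv),
                                          n, N_block))
    return Dataset(blocks=blocks, session_dates=session_dates,
                   subject_of=subject_of)


# ---------------------------------------------------------------------------
# standard logistic choice-curve refits (logit p ~ b0 + b1 dv)


@dataclass(frozen=True)
class ChoiceCurveFit:
    """Maximum-likelihood logistic choice curve for one trial set.

    ``width = 1/beta1`` (seconds) is the inverse precision of the curve;
    ``pse = -beta0/beta1`` is the indifference point, so the implied image
    value is ``-pse``.  ``converged`` is False under (near-)complete
    separation, in which case the coefficients are reported as fitted but
    should be treated as divergent.
    """

    beta0: float
    beta1: float
    width: float
    pse: float
    converged: bool

    @property
    def value(self) -> float:
        """Implied image value in seconds (= -pse)."""
        return -self.pse


_SEPARATION_SLOPE = 1e3  # |beta1| beyond this (width < 1 ms) flags separation


def fit_choice_curve(blocks: list[ChoiceBlock]) -> ChoiceCurveFit:
    """Fit ``logit p ~ b0 + b1 dv`` by ML to one session x category trial set."""
    import statsmodels.api as sm

    dv = np.array([b.dv for b in blocks])
    if np.unique(dv).size < 2:
        raise ValueError("need >= 2 distinct dv values to fit a choice curve")
    endog = np.column_stack([[b.n for b in blocks],
                             [b.N - b.n for b in blocks]]).astype(float)
    exog = sm.add_constant(dv)
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(maxiter=200)
        beta0, beta1 = (float(res.params[0]), float(res.params[1]))
        converged = bool(res.converged)
    except Exception:
        beta0, beta1, converged = np.nan, np.nan, False
    frac = np.array([b.n / b.N for b in blocks])
    extreme = np.all((frac == 0.0) | (frac == 1.0)) and np.unique(frac).size > 1
    if not np.isfinite(beta0) or not np.isfinite(beta1) \
            or abs(beta1) > _SEPARATION_SLOPE or extreme:
        converged = False
    width = 1.0 / beta1 if beta1 != 0 else np.inf
    pse = -beta0 / beta1 if beta1 != 0 else np.nan
    return ChoiceCurveFit(beta0=beta0, beta1=beta1, width=width, pse=pse,
                          converged=converged)


def refit_choice_curves(dataset: Dataset) -> pd.DataFrame:
    """Per (session, category) choice-curve refits for a whole dataset.

    Returns a frame with subject, session, category, beta0, beta1, width,
    value (= -pse), and the convergence flag — the ingredients of the
    observed-vs-predictive value and width histograms.
    """
    groups: dict[tuple[str, str], list[ChoiceBlock]] = {}
    for b in dataset.blocks:
        groups.setdefault((b.session_id, b.category), []).append(b)
    rows = []
    for (sid, cat), blocks in groups.items():
        if len({b.dv for b in blocks}) < 2:
            continue
        fit = fit_choice_curve(blocks)
        rows.append({
            "subject": blocks[0].subject_id, "session": sid, "category": cat,
            "beta0": fit.beta0, "beta1": fit.beta1, "width": fit.width,
            "pse": fit.pse, "value": fit.value, "converged": fit.converged,
        })
    return pd.DataFrame(rows)
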
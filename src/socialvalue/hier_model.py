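"""Hierarchical overdispersed-logit model of image value, with pooling variants.

The generative model for one block (session *s*, subject *m*, category *c*,
juice differential ``dv``) is

.. math::

    v_{msc} &\\sim \\mathcal N(V_{mc} + \\alpha_{mc} t_s,\\ \\sigma_m^2) \\\\
    \\eta_{msc} &= (dv + v_{msc}) / \\tau_s \\\\
    \\mathrm{logit}\\, p_{msc} &\\sim \\mathcal N(\\eta_{msc},\\ \\omega_m^2) \\\\
    n_{msc} &\\sim \\mathrm{Binomial}(N_{msc},\\ p_{msc})

where :math:`V_{mc}` is the mean image value for a subject and category
(seconds of juice access), :math:`\\sigma_m` the session-to-session value
s.d., :math:`\\tau_s` a session-specific utility scale (the choice-curve
width), :math:`\\omega_m` logit-scale choice overdispersion, and
:math:`\\alpha_{mc}` an optional linear drift of value per unit of the
standardized session-time covariate :math:`t_s` (zero when the time trend
is disabled).  The indifference point (PSE) is ``dv* = -v``.

Pooling variants
----------------
Eight model variants arise from how each factor is pooled:

========  =========================================  =======  ========  =======
Model     Description                                Session  Category  Subject
========  =========================================  =======  ========  =======
0         All sessions independent                   none     none      none
1         One model per (category, subject)          complete none      none
2         One model per subject                      complete complete  none
3         Only session variation                     partial  complete  complete
4         Collapse category, model session           partial  complete  none
5         Collapse subject, model session            partial  none      complete
6         Model session per (category, subject)      partial  none      none
7         Model 6 plus time trend                    partial  none      none
========  =========================================  =======  ========  =======

"Complete" pooling collapses a factor's index to a single group;
"none" keeps independent parameters per level (with shared priors);
"partial" (sessions only) is the Gaussian hierarchy above.  Model 0 drops
the session hierarchy entirely: each (session, category) value gets the
``V`` prior directly, a regularized per-session Bayesian fit.

Densities
---------
``log_likelihood`` contains exactly the observation terms: the Gaussian
density of the latent block logit at :math:`\\eta` and the binomial pmf of
the counts.  ``log_prior`` contains everything above those terms — the
hyperpriors and the latent-level densities (the ``v`` hierarchy, or the
``V``-prior on per-session values in Model 0) — so that
``log_prior + log_likelihood`` is the full joint log density.
``deviance`` is :math:`-2\\times` the binomial terms alone, conditional on
each block's latent choice probability; that is the focus used for DIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, stdtr

from .choice_data import CATEGORIES, Dataset, session_time_covariate

__all__ = [
    "PriorConfig",
    "ModelSpec",
    "ParameterSet",
    "ModelIndex",
    "MODEL_TABLE",
    "log_prior",
    "log_likelihood",
    "deviance",
    "indifference_point",
]

#: Hard floor on the utility scale tau (seconds); eta divides by tau.
TAU_FLOOR = 1e-6

#: Floor on the overdispersion s.d. used when simulating the omega -> 0 limit.
OMEGA_FLOOR = 1e-8


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the weakly informative priors.

    Defaults, on the seconds scale:
    ``V ~ N(0, 0.01 s^2)`` (s.d. 100 ms), ``sigma ~ U(1e-6, 1)``,
    ``log omega ~ U(-6, 2)``, ``tau ~ t+(l, s, nu)`` with
    ``l ~ U(0, 0.5)``, ``s ~ U(1e-4, 0.1)``, ``nu ~ U(0.1, 50)``, and
    ``alpha ~ N(0, 0.01)`` for the time-trend rates.
    """

    V_variance: float = 0.01
    sigma_bounds: tuple[float, float] = (1e-6, 1.0)
    log_omega_bounds: tuple[float, float] = (-6.0, 2.0)
    tau_location_bounds: tuple[float, float] = (0.0, 0.5)
    tau_scale_bounds: tuple[float, float] = (1e-4, 0.1)
    tau_df_bounds: tuple[float, float] = (0.1, 50.0)
    alpha_variance: float = 0.01

    def __post_init__(self) -> None:
        if self.V_variance <= 0 or self.alpha_variance <= 0:
            raise ValueError("variances must be positive")
        for name in ("sigma_bounds", "log_omega_bounds", "tau_location_bounds",
                     "tau_scale_bounds", "tau_df_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be ordered, got ({lo}, {hi})")


POOLING_LEVELS = {"none", "partial", "complete"}

#: model number -> (session, category, subject, time_trend, description)
MODEL_TABLE: dict[int, tuple[str, str, str, bool, str]] = {
    0: ("none", "none", "none", False, "All sessions independent"),
    1: ("complete", "none", "none", False, "One model per (category, subject)"),
    2: ("complete", "complete", "none", False, "One model per subject"),
    3: ("partial", "complete", "complete", False, "Only session variation"),
    4: ("partial", "complete", "none", False, "Collapse category, model session"),
    5: ("partial", "none", "complete", False, "Collapse subject, model session"),
    6: ("partial", "none", "none", False, "Model session per (category, subject)"),
    7: ("partial", "none", "none", True, "Model 6 plus time trend"),
}


@dataclass(frozen=True)
class ModelSpec:
    """Pooling mode per factor, time-trend flag, and prior hyperparameters."""

    session_pooling: str = "partial"
    category_pooling: str = "none"
    subject_pooling: str = "none"
    time_trend: bool = False
    priors: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self) -> None:
        if self.session_pooling not in POOLING_LEVELS:
            raise ValueError(f"bad session_pooling {self.session_pooling!r}")
        if self.category_pooling not in {"none", "complete"}:
            raise ValueError(f"bad category_pooling {self.category_pooling!r}")
        if self.subject_pooling not in {"none", "complete"}:
            raise ValueError(f"bad subject_pooling {self.subject_pooling!r}")
        if self.time_trend and self.session_pooling != "partial":
            raise ValueError("time_trend requires partial session pooling")

    @classmethod
    def from_model_number(cls, number: int, priors: PriorConfig | None = None) -> "ModelSpec":
        """Construct one of the eight canonical variants (``model0``..``model7``)."""
        try:
            sess, cat, subj, trend, _ = MODEL_TABLE[number]
        except KeyError:
            raise ValueError(f"model number must be in 0..7, got {number}") from None
        return cls(sess, cat, subj, trend, priors or PriorConfig())

    @property
    def model_number(self) -> int | None:
        """The canonical model number, or None for a non-canonical combination."""
        key = (self.session_pooling, self.category_pooling, self.subject_pooling,
               self.time_trend)
        for num, (s, c, m, t, _) in MODEL_TABLE.items():
            if (s, c, m, t) == key:
                return num
        return None

    @property
    def description(self) -> str:
        num = self.model_number
        if num is not None:
            return MODEL_TABLE[num][4]
        return (f"session={self.session_pooling}, category={self.category_pooling}, "
                f"subject={self.subject_pooling}, trend={self.time_trend}")

    # -- flat key/value serialization (config-file friendly) ---------------
    def to_mapping(self) -> dict:
        d = {
            "session_pooling": self.session_pooling,
            "category_pooling": self.category_pooling,
            "subject_pooling": self.subject_pooling,
            "time_trend": self.time_trend,
        }
        num = self.model_number
        if num is not None:
            d["model"] = f"model{num}"
        p = self.priors
        d.update(
            V_variance=p.V_variance,
            sigma_bounds=list(p.sigma_bounds),
            log_omega_bounds=list(p.log_omega_bounds),
            tau_location_bounds=list(p.tau_location_bounds),
            tau_scale_bounds=list(p.tau_scale_bounds),
            tau_df_bounds=list(p.tau_df_bounds),
            alpha_variance=p.alpha_variance,
        )
        return d

    @classmethod
    def from_mapping(cls, d: dict) -> "ModelSpec":
        prior_keys = ("V_variance", "sigma_bounds", "log_omega_bounds",
                      "tau_location_bounds", "tau_scale_bounds", "tau_df_bounds",
                      "alpha_variance")
        pkw = {}
        for k in prior_keys:
            if k in d:
                v = d[k]
                pkw[k] = tuple(v) if isinstance(v, (list, tuple)) else float(v)
        priors = PriorConfig(**pkw)
        if "model" in d and not any(
            k in d for k in ("session_pooling", "category_pooling", "subject_pooling")
        ):
            num = int(str(d["model"]).removeprefix("model"))
            spec = cls.from_model_number(num, priors)
            return spec
        return cls(
            session_pooling=d.get("session_pooling", "partial"),
            category_pooling=d.get("category_pooling", "none"),
            subject_pooling=d.get("subject_pooling", "none"),
            time_trend=bool(d.get("time_trend", False)),
            priors=priors,
        )


@dataclass
class ParameterSet:
    """One point in parameter space for a given (ModelSpec, Dataset) pair.

    Array shapes are determined by the pooling structure: ``V`` and
    ``alpha`` are (subject groups, category groups); ``sigma`` and
    ``omega`` are (subject groups,); ``tau`` is (sessions,); ``v`` is
    (sessions, category groups); ``logit_p`` is (blocks,).  Fields that a
    variant does not use are ``None`` (e.g. ``v`` under complete session
    pooling, ``V``/``sigma`` in Model 0, ``alpha`` without a time trend).
    """

    V: np.ndarray | None
    sigma: np.ndarray | None
    omega: np.ndarray
    tau: np.ndarray
    tau_loc: float
    tau_scale: float
    tau_df: float
    alpha: np.ndarray | None
    v: np.ndarray | None
    logit_p: np.ndarray


class ModelIndex:
    """Index arrays linking blocks to the parameter structure of a variant.

    Maps each block to its session, category group, and subject group;
    carries count/dv arrays (dv in seconds) and the standardized
    session-time covariate.
    """

    def __init__(self, dataset: Dataset, spec: ModelSpec):
        if len(dataset) == 0:
            raise ValueError("dataset is empty")
        self.spec = spec
        self.sessions: list[str] = dataset.sessions
        self.subjects: list[str] = dataset.subjects
        sess_ix = {s: i for i, s in enumerate(self.sessions)}
        subj_ix = {m: i for i, m in enumerate(self.subjects)}
        cat_ix = {c: i for i, c in enumerate(CATEGORIES)}

        self.n_subj_groups = 1 if spec.subject_pooling == "complete" else len(self.subjects)
        self.n_cat_groups = 1 if spec.category_pooling == "complete" else len(CATEGORIES)

        nb = len(dataset.blocks)
        self.n_blocks = nb
        self.block_session = np.empty(nb, dtype=np.intp)
        self.block_cat = np.empty(nb, dtype=np.intp)
        self.block_subj = np.empty(nb, dtype=np.intp)
        self.dv = np.empty(nb)
        self.n = np.empty(nb)
        self.N = np.empty(nb)
        for i, b in enumerate(dataset.blocks):
            self.block_session[i] = sess_ix[b.session_id]
            self.block_cat[i] = 0 if self.n_cat_groups == 1 else cat_ix[b.category]
            self.block_subj[i] = 0 if self.n_subj_groups == 1 else subj_ix[b.subject_id]
            self.dv[i] = b.dv
            self.n[i] = b.n
            self.N[i] = b.N

        self.n_sessions = len(self.sessions)
        self.session_subj = np.array(
            [0 if self.n_subj_groups == 1 else subj_ix[dataset.subject_of[s]]
             for s in self.sessions], dtype=np.intp)
        if spec.time_trend:
            tcov = session_time_covariate(dataset)
            self.session_t = np.array([tcov[s] for s in self.sessions])
        else:
            self.session_t = np.zeros(self.n_sessions)

        # flat (session, category-group) cell id per block, for v updates
        self.block_cell = self.block_session * self.n_cat_groups + self.block_cat
        self.n_cells = self.n_sessions * self.n_cat_groups
        # binomial normalization constants log C(N, n)
        self.log_binom_coef = (
            gammaln(self.N + 1) - gammaln(self.n + 1) - gammaln(self.N - self.n + 1)
        )

        self.has_v = spec.session_pooling in ("partial", "none")
        self.has_V = spec.session_pooling != "none"
        self.has_sigma = spec.session_pooling == "partial"
        self.has_alpha = spec.time_trend

    def validate_params(self, params: ParameterSet) -> None:
        """Raise ValueError on any shape mismatch with this variant."""
        def shape_of(x):
            return None if x is None else np.shape(x)

        expect = {
            "V": (self.n_subj_groups, self.n_cat_groups) if self.has_V else None,
            "sigma": (self.n_subj_groups,) if self.has_sigma else None,
            "omega": (self.n_subj_groups,),
            "tau": (self.n_sessions,),
            "alpha": (self.n_subj_groups, self.n_cat_groups) if self.has_alpha else None,
            "v": (self.n_sessions, self.n_cat_groups) if self.has_v else None,
            "logit_p": (self.n_blocks,),
        }
        for name, shape in expect.items():
            got = shape_of(getattr(params, name))
            if got != shape:
                raise ValueError(f"parameter {name!r}: expected shape {shape}, got {got}")


# ---------------------------------------------------------------------------
# density helpers


def _norm_logpdf(x, mean, sd):
    z = (np.asarray(x) - mean) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * np.log(2.0 * np.pi)


def _t_logpdf(x, df, loc, scale):
    """Student-t log density, vectorized with plain numpy/gammaln."""
    z = (np.asarray(x, dtype=float) - loc) / scale
    return (
        gammaln((df + 1.0) / 2.0)
        - gammaln(df / 2.0)
        - 0.5 * np.log(df * np.pi)
        - np.log(scale)
        - 0.5 * (df + 1.0) * np.log1p(z * z / df)
    )


def trunc_t_logpdf(x, df, loc, scale):
    """Log density of the positively truncated t(loc, scale, df).

    Normalized over the positive half-line: P(T > 0) = stdtr(df, loc/scale)
    since (T - loc)/scale is standard t.
    """
    x = np.asarray(x, dtype=float)
    log_mass = np.log(stdtr(df, loc / scale))
    out = _t_logpdf(x, df, loc, scale) - log_mass
    return np.where(x > 0, out, -np.inf)


def binom_logpmf(n, N, logit_p, log_coef=None):
    """Binomial log pmf parameterized by the logit of the success probability."""
    if log_coef is None:
        log_coef = gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1)
    return log_coef + n * logit_p - N * np.logaddexp(0.0, logit_p)


def linear_predictor(params: ParameterSet, index: ModelIndex) -> np.ndarray:
    """Block-level utility eta = (dv + value) / tau for any variant."""
    if index.has_v:
        value = params.v[index.block_session, index.block_cat]
    else:  # complete session pooling: the group mean stands in for v
        value = params.V[index.block_subj, index.block_cat]
    tau_b = params.tau[index.block_session]
    return (index.dv + value) / tau_b


def _uniform_logpdf(x, lo, hi):
    return -np.log(hi - lo) if lo < x < hi else -np.inf


def log_prior(params: ParameterSet, spec: ModelSpec, dataset: Dataset,
              index: ModelIndex | None = None) -> float:
    """Joint log prior, including latent-level densities.

    Covers the hyperpriors (V, sigma, omega, tau hyperparameters, alpha),
    the truncated-t prior on each session's tau, and the latent value
    densities: ``v ~ N(V + alpha t, sigma^2)`` under partial session
    pooling, or ``v ~ N(0, V_variance)`` in Model 0.  The uniform prior on
    sigma and the log-uniform prior on omega are expressed as densities of
    the stored (natural-scale) parameters.  Returns -inf outside the
    support.
    """
    if index is None:
        index = ModelIndex(dataset, spec)
    index.validate_params(params)
    p = spec.priors

    total = 0.0
    # hyperpriors on the tau family
    for val, bounds in ((params.tau_loc, p.tau_location_bounds),
                        (params.tau_scale, p.tau_scale_bounds),
                        (params.tau_df, p.tau_df_bounds)):
        lp = _uniform_logpdf(val, *bounds)
        if not np.isfinite(lp):
            return -np.inf
        total += lp

    # sigma ~ U(bounds); omega: log omega ~ U(bounds) => density 1/(range * omega)
    if index.has_sigma:
        lo, hi = p.sigma_bounds
        if np.any(params.sigma <= lo) or np.any(params.sigma >= hi):
            return -np.inf
        total += -len(params.sigma) * np.log(hi - lo)
    lo, hi = p.log_omega_bounds
    lom = np.log(params.omega)
    if np.any(lom <= lo) or np.any(lom >= hi):
        return -np.inf
    total += float(np.sum(-np.log(hi - lo) - lom))

    # tau ~ truncated t with floor
    if np.any(params.tau < TAU_FLOOR):
        return -np.inf
    lt = trunc_t_logpdf(params.tau, params.tau_df, params.tau_loc, params.tau_scale)
    if not np.all(np.isfinite(lt)):
        return -np.inf
    total += float(np.sum(lt))

    if index.has_V:
        total += float(np.sum(_norm_logpdf(params.V, 0.0, np.sqrt(p.V_variance))))
    if index.has_alpha:
        total += float(np.sum(_norm_logpdf(params.alpha, 0.0, np.sqrt(p.alpha_variance))))

    # latent value level
    if index.has_v:
        if spec.session_pooling == "partial":
            mean = params.V[index.session_subj[:, None],
                            np.arange(index.n_cat_groups)[None, :]]
            if index.has_alpha:
                mean = mean + params.alpha[index.session_subj[:, None],
                                           np.arange(index.n_cat_groups)[None, :]] \
                    * index.session_t[:, None]
            sd = params.sigma[index.session_subj][:, None]
        else:  # Model 0: the V prior applies to each (session, category) value
            mean = 0.0
            sd = np.sqrt(p.V_variance)
        total += float(np.sum(_norm_logpdf(params.v, mean, sd)))

    return total


def log_likelihood(params: ParameterSet, spec: ModelSpec, dataset: Dataset,
                   index: ModelIndex | None = None) -> float:
    """Observation-level log likelihood: latent-logit Gaussian + binomial terms."""
    if index is None:
        index = ModelIndex(dataset, spec)
    index.validate_params(params)
    eta = linear_predictor(params, index)
    if not np.all(np.isfinite(eta)):
        raise FloatingPointError("non-finite utility eta (tau underflow?)")
    omega_b = params.omega[index.block_subj]
    total = float(np.sum(_norm_logpdf(params.logit_p, eta, omega_b)))
    total += float(np.sum(binom_logpmf(index.n, index.N, params.logit_p,
                                       index.log_binom_coef)))
    return total


def deviance(params: ParameterSet, spec: ModelSpec, dataset: Dataset,
             index: ModelIndex | None = None) -> float:
    """-2 x binomial log pmf of the counts given each block's latent p.

    This conditional focus (observed counts given their direct parents) is
    the deviance used for DIC; it excludes all prior and latent-level
    terms, so it is invariant to prior hyperparameters by construction.
    """
    if index is None:
        index = ModelIndex(dataset, spec)
    index.validate_params(params)
    return -2.0 * float(np.sum(binom_logpmf(index.n, index.N, params.logit_p,
                                            index.log_binom_coef)))


def indifference_point(v: float) -> float:
    """PSE in seconds: the juice differential at which choice is 50/50.

    Indifference occurs when dv cancels the image value, so ``dv* = -v``.
    """
    if not np.isfinite(v):
        raise ValueError("image value must be finite")
    return -float(v)
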
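"""Subject-level scientific summaries of a fitted hierarchy.

Converts posterior draws into the quantities a study report presents:
per-(subject, category) mean image values with 95% credible intervals,
across-session standard deviations, time-trend slopes, and joint
cross-category value draws for correlation scatterplots.  All value-like
quantities are reported in **milliseconds** of juice access (1000x the
internal seconds scale); negative values are reported as-is.

Quantile convention: central intervals use linear-interpolation (type 7)
sample quantiles, numpy's default, pooled over chains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .choice_data import CATEGORIES
from .sampler import PosteriorSamples

__all__ = [
    "ValueSummary",
    "TrendSummary",
    "value_summaries",
    "trend_summaries",
    "category_correlation_samples",
    "value_report_frame",
    "trend_report_frame",
]


@dataclass(frozen=True)
class ValueSummary:
    """Posterior summary of one subject x category mean value (ms)."""

    subject: str
    category: str
    posterior_median: float
    ci95: tuple[float, float]
    across_session_sd_median: float
    sd_ci95: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not lo <= self.posterior_median <= hi:
            raise ValueError("median must lie inside its credible interval")


@dataclass(frozen=True)
class TrendSummary:
    """Posterior summary of one subject x category drift rate.

    ``slope_median``/``slope_ci95`` are in ms of juice per standardized
    session-rank unit (the fitting scale); ``slope_per_session_median``
    rescales to ms per session using the subject's rank-to-t conversion
    (1 session step = ``delta_t`` standardized units).
    """

    subject: str
    category: str
    slope_median: float
    slope_ci95: tuple[float, float]
    slope_per_session_median: float

    def __post_init__(self) -> None:
        lo, hi = self.slope_ci95
        if not lo <= self.slope_median <= hi:
            raise ValueError("median must lie inside its credible interval")


def _labels(samples: PosteriorSamples) -> tuple[list[str], list[str]]:
    spec = samples.spec
    n_cat = samples.draws["V"].shape[3] if "V" in samples.draws \
        else samples.meta["n_cat_groups"]
    subjects = (["pooled"] if spec.subject_pooling == "complete"
                else list(samples.meta["subjects"]))
    cats = (["pooled"] if spec.category_pooling == "complete"
            else list(CATEGORIES)[:n_cat])
    return subjects, cats


def _quantiles(draws: np.ndarray) -> tuple[float, float, float]:
    med, lo, hi = np.quantile(draws, [0.5, 0.025, 0.975])
    return float(med), float(lo), float(hi)


def value_summaries(samples: PosteriorSamples) -> list[ValueSummary]:
    """Medians and 95% credible intervals of V_mc and sigma_m, in ms.

    Requires a fit that models mean values and session-to-session
    variation (the hierarchical variants, Models 3-7).
    """
    if "V" not in samples.draws or "sigma" not in samples.draws:
        raise ValueError("samples lack V/sigma draws; fit a hierarchical "
                         "variant (partial session pooling)")
    subjects, cats = _labels(samples)
    V = samples.stacked("V") * 1000.0          # (draws, M, C) in ms
    sigma = samples.stacked("sigma") * 1000.0  # (draws, M)
    out = []
    for m, subj in enumerate(subjects):
        sd_med, sd_lo, sd_hi = _quantiles(sigma[:, m])
        for c, cat in enumerate(cats):
            med, lo, hi = _quantiles(V[:, m, c])
            out.append(ValueSummary(subject=subj, category=cat,
                                    posterior_median=med, ci95=(lo, hi),
                                    across_session_sd_median=sd_med,
                                    sd_ci95=(sd_lo, sd_hi)))
    return out


def trend_summaries(samples: PosteriorSamples) -> list[TrendSummary]:
    """Quantile summaries of the drift rates alpha_mc (time-trend model).

    One summary per subject x category group; raises if the fit had no
    time trend.
    """
    if "alpha" not in samples.draws:
        raise ValueError("samples lack alpha draws; fit the time-trend model")
    subjects, cats = _labels(samples)
    alpha = samples.stacked("alpha") * 1000.0  # ms per standardized t unit

    # per-subject step size in standardized units between consecutive sessions
    session_subjects = samples.meta.get("session_subjects", [])
    n_sessions = {m: session_subjects.count(m) for m in set(session_subjects)}

    out = []
    for m, subj in enumerate(subjects):
        k = n_sessions.get(subj, 0)
        # evenly spaced ranks z-scored with population s.d.: step = sqrt(12/(k^2-1))
        delta_t = float(np.sqrt(12.0 / (k * k - 1.0))) if k >= 2 else np.nan
        for c, cat in enumerate(cats):
            med, lo, hi = _quantiles(alpha[:, m, c])
            out.append(TrendSummary(subject=subj, category=cat,
                                    slope_median=med, slope_ci95=(lo, hi),
                                    slope_per_session_median=med * delta_t))
    return out


def category_correlation_samples(samples: PosteriorSamples, subject: str,
                                 n_points: int = 1000,
                                 rng: np.random.Generator | None = None
                                 ) -> pd.DataFrame:
    """Joint draws of one subject's category values across sessions.

    Each returned row is one whole draw from the joint posterior of the
    category-value vector for a uniformly selected (session, retained
    draw): the within-draw correlation structure across categories is
    preserved, never mixed across draws.  Values are in ms.
    """
    rng = rng or np.random.default_rng()
    if "v" not in samples.draws:
        raise ValueError("samples lack session-value draws")
    subjects = samples.meta["subjects"]
    session_subjects = samples.meta["session_subjects"]
    if subject not in subjects:
        raise KeyError(f"subject {subject!r} not in fit ({subjects})")
    sess_idx = np.array([i for i, m in enumerate(session_subjects) if m == subject])
    if sess_idx.size == 0:
        raise KeyError(f"subject {subject!r} has no sessions")

    v = samples.stacked("v")  # (draws, S, C)
    n_draws = v.shape[0]
    pick_draw = rng.integers(n_draws, size=n_points)
    pick_sess = sess_idx[rng.integers(sess_idx.size, size=n_points)]
    joint = v[pick_draw, pick_sess, :] * 1000.0
    _, cats = _labels(samples)
    frame = pd.DataFrame(joint, columns=cats)
    frame.insert(0, "session", [samples.meta["sessions"][s] for s in pick_sess])
    return frame


def value_report_frame(summaries: list[ValueSummary]) -> pd.DataFrame:
    """Flat delimited-report layout of the value summaries."""
    return pd.DataFrame([
        {"subject": s.subject, "category": s.category,
         "value_median_ms": s.posterior_median,
         "value_lo_ms": s.ci95[0], "value_hi_ms": s.ci95[1],
         "session_sd_median_ms": s.across_session_sd_median,
         "session_sd_lo_ms": s.sd_ci95[0], "session_sd_hi_ms": s.sd_ci95[1]}
        for s in summaries])


def trend_report_frame(summaries: list[TrendSummary]) -> pd.DataFrame:
    """Flat delimited-report layout of the trend summaries."""
    return pd.DataFrame([
        {"subject": s.subject, "category": s.category,
         "slope_median_ms_per_t": s.slope_median,
         "slope_lo_ms_per_t": s.slope_ci95[0],
         "slope_hi_ms_per_t": s.slope_ci95[1],
         "slope_median_ms_per_session": s.slope_per_session_median}
        for s in summaries])
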
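"""Forward simulation of complete valuation studies with known ground truth.

Simulated studies mirror the structure of the archived experiments: a
handful of subjects with unequal session counts, four image categories per
session, a small grid of juice differentials per category, and
tens-of-choices blocks.  Given a :class:`GroundTruth` the simulator draws
session values, overdispersed block logits, and binomial counts exactly as
the hierarchical model assumes, and returns both the observable
:class:`~socialvalue.choice_data.Dataset` and the realized latents so
recovery tests can compare estimates against truth.

Two canonical designs are provided:

* :func:`small_study_design` — the desk-scale fixture (4 subjects x 10
  sessions x 4 categories x 5 dv values x N=30) used throughout the test
  suite, with :func:`small_study_truth` supplying realistic parameter
  values (mean values within +/-45 ms of juice, one all-negative subject,
  session s.d. 10-25 ms, moderate overdispersion).
* :func:`archive_study_design` — the shape of the archived dataset: 8
  subjects with session counts (60, 32, 51, 23, 14, 10, 8, 8).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np

from .choice_data import CATEGORIES, ChoiceBlock, Dataset, standardized_session_ranks
from .hier_model import OMEGA_FLOOR, PriorConfig

__all__ = [
    "GroundTruth",
    "StudyDesign",
    "draw_parameters",
    "simulate_dataset",
    "small_study_design",
    "small_study_truth",
    "archive_study_design",
    "write_ground_truth",
    "read_ground_truth",
]

#: Session counts of the archived study, subjects E, Os, Ot, D, S, C, B, N.
ARCHIVE_SESSION_COUNTS = (60, 32, 51, 23, 14, 10, 8, 8)
ARCHIVE_SUBJECTS = ("E", "Os", "Ot", "D", "S", "C", "B", "N")

#: Default juice-differential grid (seconds): 5 levels spanning +/-60 ms.
DEFAULT_DV_GRID = (-0.060, -0.030, 0.0, 0.030, 0.060)


@dataclass
class StudyDesign:
    """Sizes, labels, dates, and dv grid of a simulated study."""

    subjects: tuple[str, ...]
    session_counts: tuple[int, ...]
    categories: tuple[str, ...] = CATEGORIES
    dv_grid: tuple[float, ...] = DEFAULT_DV_GRID
    N_per_block: int = 30
    start_date: date = date(2008, 1, 1)

    def __post_init__(self) -> None:
        if len(self.subjects) != len(self.session_counts):
            raise ValueError("subjects and session_counts lengths differ")
        if any(k < 1 for k in self.session_counts):
            raise ValueError("session counts must be >= 1")
        if self.N_per_block < 1:
            raise ValueError("N_per_block must be >= 1")
        if len(self.dv_grid) == 0:
            raise ValueError("dv_grid must be non-empty")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_sessions(self) -> int:
        return int(sum(self.session_counts))

    @property
    def sessions(self) -> list[str]:
        """Session ids, subject-major, as ``<subject>_s<k>``."""
        out = []
        for subj, count in zip(self.subjects, self.session_counts):
            out.extend(f"{subj}_s{k:03d}" for k in range(count))
        return out

    @property
    def session_subject(self) -> dict[str, str]:
        return {s: s.rsplit("_s", 1)[0] for s in self.sessions}

    @property
    def session_dates(self) -> dict[str, date]:
        """One session per day per subject, subjects running concurrently."""
        out = {}
        for j, (subj, count) in enumerate(zip(self.subjects, self.session_counts)):
            for k in range(count):
                out[f"{subj}_s{k:03d}"] = self.start_date + timedelta(days=2 * k + j)
        return out

    @property
    def session_subject_index(self) -> np.ndarray:
        ix = {m: i for i, m in enumerate(self.subjects)}
        return np.array([ix[self.session_subject[s]] for s in self.sessions])

    def time_covariate(self) -> np.ndarray:
        """Standardized within-subject session-time covariate, session-major order."""
        tmap = standardized_session_ranks(self.session_dates, self.session_subject)
        return np.array([tmap[s] for s in self.sessions])


@dataclass
class GroundTruth:
    """All latent parameters of a simulated study (seconds / logit units).

    ``v_msc`` and ``p`` start as ``None`` and are filled in by
    :func:`simulate_dataset` with the realized session values and block
    choice probabilities.
    """

    V_mc: np.ndarray          # (n_subjects, n_categories) mean values, s
    sigma_m: np.ndarray       # (n_subjects,) session-to-session value s.d., s
    omega_m: np.ndarray       # (n_subjects,) choice overdispersion s.d., logit units
    tau_s: np.ndarray         # (n_sessions,) utility scale, s
    tau_loc: float
    tau_scale: float
    tau_df: float
    alpha_mc: np.ndarray | None = None   # (n_subjects, n_categories) drift, s per t-unit
    v_msc: np.ndarray | None = None      # (n_sessions, n_categories) realized values, s
    p: np.ndarray | None = None          # (n_blocks,) realized choice probabilities

    def __post_init__(self) -> None:
        if np.any(self.sigma_m <= 0) or np.any(self.omega_m <= 0):
            raise ValueError("sigma_m and omega_m must be positive")
        if np.any(self.tau_s <= 0):
            raise ValueError("tau_s must be positive")


def _truncated_t_positive(rng: np.random.Generator, loc: float, scale: float,
                          df: float, size: int) -> np.ndarray:
    """Draw from t(loc, scale, df) truncated to the positive reals by rejection."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = loc + scale * rng.standard_t(df, size=size - filled)
        keep = draw[draw > 0]
        out[filled:filled + keep.size] = keep
        filled += keep.size
    return out


def draw_parameters(design: StudyDesign, prior_config: PriorConfig,
                    rng: np.random.Generator,
                    fixed: dict | None = None,
                    time_trend: bool = False) -> GroundTruth:
    """Draw a complete ground-truth parameter set from the stated priors.

    Any entry of ``fixed`` (keys matching :class:`GroundTruth` field names)
    overrides the corresponding draw; overrides are validated for shape and
    support.  ``time_trend`` adds drift rates ``alpha_mc ~ N(0, 0.01)``.
    """
    fixed = dict(fixed or {})
    p = prior_config
    M, C, S = design.n_subjects, len(design.categories), design.n_sessions

    def take(name, draw_fn, shape):
        if name in fixed:
            val = np.asarray(fixed.pop(name), dtype=float)
            if np.shape(val) != shape and shape != ():
                raise ValueError(f"fixed {name!r}: expected shape {shape}, "
                                 f"got {np.shape(val)}")
            return float(val) if shape == () else val
        return draw_fn()

    V = take("V_mc", lambda: rng.normal(0.0, np.sqrt(p.V_variance), size=(M, C)), (M, C))
    sigma = take("sigma_m", lambda: rng.uniform(*p.sigma_bounds, size=M), (M,))
    omega = take("omega_m", lambda: np.exp(rng.uniform(*p.log_omega_bounds, size=M)), (M,))
    tau_loc = take("tau_loc", lambda: rng.uniform(*p.tau_location_bounds), ())
    tau_scale = take("tau_scale", lambda: rng.uniform(*p.tau_scale_bounds), ())
    tau_df = take("tau_df", lambda: rng.uniform(*p.tau_df_bounds), ())
    tau = take("tau_s",
               lambda: _truncated_t_positive(rng, tau_loc, tau_scale, tau_df, S), (S,))
    alpha = None
    if time_trend or "alpha_mc" in fixed:
        alpha = take("alpha_mc",
                     lambda: rng.normal(0.0, np.sqrt(p.alpha_variance), size=(M, C)),
                     (M, C))
    if fixed:
        raise ValueError(f"unknown fixed parameter(s): {sorted(fixed)}")
    truth = GroundTruth(V_mc=np.asarray(V, dtype=float),
                        sigma_m=np.asarray(sigma, dtype=float),
                        omega_m=np.asarray(omega, dtype=float),
                        tau_s=np.asarray(tau, dtype=float),
                        tau_loc=float(tau_loc), tau_scale=float(tau_scale),
                        tau_df=float(tau_df),
                        alpha_mc=None if alpha is None else np.asarray(alpha, dtype=float))
    return truth


def simulate_dataset(truth: GroundTruth, design: StudyDesign,
                     rng: np.random.Generator,
                     time_trend: bool = False) -> tuple[Dataset, GroundTruth]:
    """Simulate one complete study from ``truth`` under ``design``.

    For each (session, category) a value ``v ~ N(V + alpha t, sigma^2)`` is
    drawn (the drift term only when ``time_trend``), then for each dv in
    the grid a block logit ``~ N((dv + v)/tau, omega^2)`` and counts
    ``n ~ Binomial(N, p)``.  Omega is floored at 1e-8 so the
    no-overdispersion limit can be exercised.  Returns the dataset and a
    copy of ``truth`` with the realized ``v_msc`` and ``p`` filled in.
    """
    M, C, S = design.n_subjects, len(design.categories), design.n_sessions
    if truth.V_mc.shape != (M, C) or truth.tau_s.shape != (S,):
        raise ValueError("truth dimensions do not match design")
    if time_trend and truth.alpha_mc is None:
        raise ValueError("time_trend simulation requires alpha_mc in truth")

    subj_of_session = design.session_subject_index
    t = design.time_covariate() if time_trend else np.zeros(S)

    mean_v = truth.V_mc[subj_of_session, :]  # (S, C)
    if time_trend:
        mean_v = mean_v + truth.alpha_mc[subj_of_session, :] * t[:, None]
    sigma_s = truth.sigma_m[subj_of_session][:, None]
    v = rng.normal(mean_v, sigma_s)

    sessions = design.sessions
    session_subject = design.session_subject
    dates = design.session_dates
    omega_s = np.maximum(truth.omega_m, OMEGA_FLOOR)[subj_of_session]

    blocks: list[ChoiceBlock] = []
    p_all = np.empty(S * C * len(design.dv_grid))
    i = 0
    for s in range(S):
        sid = sessions[s]
        subj = session_subject[sid]
        for c, cat in enumerate(design.categories):
            for dv in design.dv_grid:
                eta = (dv + v[s, c]) / truth.tau_s[s]
                logit_p = rng.normal(eta, omega_s[s])
                prob = 1.0 / (1.0 + np.exp(-logit_p))
                n = int(rng.binomial(design.N_per_block, prob))
                p_all[i] = prob
                blocks.append(ChoiceBlock(subj, sid, cat, float(dv), n,
                                          design.N_per_block))
                i += 1

    dataset = Dataset(blocks=blocks, session_dates=dict(dates),
                      subject_of=dict(session_subject))
    realized = GroundTruth(
        V_mc=truth.V_mc.copy(), sigma_m=truth.sigma_m.copy(),
        omega_m=truth.omega_m.copy(), tau_s=truth.tau_s.copy(),
        tau_loc=truth.tau_loc, tau_scale=truth.tau_scale, tau_df=truth.tau_df,
        alpha_mc=None if truth.alpha_mc is None else truth.alpha_mc.copy(),
        v_msc=v, p=p_all)
    return dataset, realized


# ---------------------------------------------------------------------------
# canonical designs and fixtures


def small_study_design(N_per_block: int = 30) -> StudyDesign:
    """The desk-scale canonical design: 4 subjects x 10 sessions each."""
    return StudyDesign(subjects=("A", "B", "C", "D"),
                       session_counts=(10, 10, 10, 10),
                       N_per_block=N_per_block)


def small_study_truth(design: StudyDesign | None = None,
                      seed: int = 20130912,
                      time_trend: bool = False) -> GroundTruth:
    """Realistic fixed ground truth for the canonical small design.

    Mean values sit within +/-45 ms of juice access with one all-negative
    subject; session-to-session s.d. is 10-25 ms; overdispersion is
    moderate; tau is drawn once (seeded) from t+(0.05, 0.015, 6), giving
    choice-curve widths around 50 ms.  With ``time_trend`` the first
    subject devalues all categories at 10 ms per standardized session-rank
    unit and the third appreciates at 6 ms.
    """
    design = design or small_study_design()
    rng = np.random.default_rng(seed)
    V = np.array([
        [0.000, 0.030, 0.015, -0.010],
        [-0.005, 0.045, 0.025, 0.005],
        [0.010, -0.020, -0.030, -0.015],
        [0.000, 0.010, 0.005, 0.000],
    ])[:, :len(design.categories)][: design.n_subjects]
    sigma = np.array([0.015, 0.025, 0.020, 0.010])[: design.n_subjects]
    omega = np.array([0.4, 0.6, 0.3, 0.5])[: design.n_subjects]
    tau_loc, tau_scale, tau_df = 0.05, 0.015, 6.0
    tau = _truncated_t_positive(rng, tau_loc, tau_scale, tau_df, design.n_sessions)
    alpha = None
    if time_trend:
        alpha = np.zeros_like(V)
        alpha[0, :] = -0.010
        if design.n_subjects >= 3:
            alpha[2, :] = 0.006
    return GroundTruth(V_mc=V, sigma_m=sigma, omega_m=omega, tau_s=tau,
                       tau_loc=tau_loc, tau_scale=tau_scale, tau_df=tau_df,
                       alpha_mc=alpha)


def archive_study_design(scale: float = 1.0, N_per_block: int = 40) -> StudyDesign:
    """The archived study's shape: 8 subjects, unequal session counts.

    ``scale`` < 1 shrinks every session count proportionally (minimum 2)
    for desk-scale runs while keeping the strong imbalance between
    subjects.
    """
    counts = tuple(max(2, round(k * scale)) for k in ARCHIVE_SESSION_COUNTS)
    return StudyDesign(subjects=ARCHIVE_SUBJECTS, session_counts=counts,
                       N_per_block=N_per_block)


# ---------------------------------------------------------------------------
# ground-truth sidecar I/O (JSON)


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Write a ground-truth sidecar as JSON (arrays as nested lists)."""
    payload = {}
    for name in ("V_mc", "sigma_m", "omega_m", "tau_s", "alpha_mc", "v_msc", "p"):
        val = getattr(truth, name)
        payload[name] = None if val is None else np.asarray(val).tolist()
    for name in ("tau_loc", "tau_scale", "tau_df"):
        payload[name] = getattr(truth, name)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_ground_truth(path) -> GroundTruth:
    """Read a sidecar written by :func:`write_ground_truth`."""
    with open(path) as fh:
        payload = json.load(fh)

    def arr(name):
        val = payload[name]
        return None if val is None else np.asarray(val, dtype=float)

    return GroundTruth(V_mc=arr("V_mc"), sigma_m=arr("sigma_m"),
                       omega_m=arr("omega_m"), tau_s=arr("tau_s"),
                       tau_loc=float(payload["tau_loc"]),
                       tau_scale=float(payload["tau_scale"]),
                       tau_df=float(payload["tau_df"]),
                       alpha_mc=arr("alpha_mc"), v_msc=arr("v_msc"), p=arr("p"))
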
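"""Aggregated choice-count tables for social-image valuation experiments.

The unit of observation is a *block*: all trials in one experimental session
in which a fixed juice differential ``dv`` was paired with one image
category.  A block records how many times the animal chose the
image-plus-juice option (``n``) out of all completed choices (``N``).

Conventions
-----------
* ``dv`` is the juice differential, image-option juice minus blank-option
  juice.  Internally every value-like quantity is expressed in **seconds**
  of juice access; files and reports use **milliseconds** (column
  ``dv_ms``).
* Image categories form a fixed four-level set: a gray-square control,
  female perinea, dominant-male faces, and subordinate-male faces.
* Session dates are ISO-8601 calendar dates; the session-time covariate
  used by the time-trend model is the within-subject rank of the date,
  z-scored with the population (divide-by-n) standard deviation so the
  realized covariate vector has exactly mean 0 and unit variance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from datetime import date, datetime

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "CATEGORIES",
    "ChoiceBlock",
    "Dataset",
    "ValidationError",
    "read_choice_table",
    "write_choice_table",
    "session_time_covariate",
]

#: The four image categories, in canonical order.
CATEGORIES: tuple[str, ...] = ("control", "female", "dominant_male", "subordinate_male")

#: Required file columns, in order.
TABLE_COLUMNS = ("subject", "session", "date", "category", "dv_ms", "n", "N")


class ValidationError(ValueError):
    """Raised when a choice table or block violates a structural invariant."""


@dataclass(frozen=True)
class ChoiceBlock:
    """One aggregated (session, category, juice differential) observation.

    Parameters
    ----------
    subject_id, session_id : str
        Labels for the animal and the experimental session.
    category : str
        One of :data:`CATEGORIES`.
    dv : float
        Juice differential in seconds (image option minus blank option).
    n : int
        Number of image-option choices.
    N : int
        Total number of choices in the block.
    """

    subject_id: str
    session_id: str
    category: str
    dv: float
    n: int
    N: int

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )
        if not math.isfinite(self.dv):
            raise ValidationError(f"dv must be finite, got {self.dv!r}")
        if self.N < 1:
            raise ValidationError(f"N must be >= 1, got {self.N}")
        if not 0 <= self.n <= self.N:
            raise ValidationError(f"need 0 <= n <= N, got n={self.n}, N={self.N}")


@dataclass
class Dataset:
    """A validated collection of choice blocks with session metadata."""

    blocks: list[ChoiceBlock]
    session_dates: dict[str, date]
    subject_of: dict[str, str]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, float]] = set()
        for i, b in enumerate(self.blocks):
            if b.session_id not in self.session_dates:
                raise ValidationError(
                    f"block {i}: session {b.session_id!r} has no date"
                )
            if self.subject_of.get(b.session_id) != b.subject_id:
                raise ValidationError(
                    f"block {i}: session {b.session_id!r} is not mapped to "
                    f"subject {b.subject_id!r}"
                )
            key = (b.session_id, b.category, b.dv)
            if key in seen:
                raise ValidationError(
                    f"block {i}: duplicate (session, category, dv) triple {key}"
                )
            seen.add(key)

    @property
    def sessions(self) -> list[str]:
        """Session ids in order of first appearance."""
        out: list[str] = []
        seen: set[str] = set()
        for b in self.blocks:
            if b.session_id not in seen:
                seen.add(b.session_id)
                out.append(b.session_id)
        return out

    @property
    def subjects(self) -> list[str]:
        """Subject ids in order of first appearance."""
        out: list[str] = []
        seen: set[str] = set()
        for b in self.blocks:
            if b.subject_id not in seen:
                seen.add(b.subject_id)
                out.append(b.subject_id)
        return out

    def __len__(self) -> int:
        return len(self.blocks)

    def to_frame(self) -> pd.DataFrame:
        """Return the file-schema representation (``dv_ms`` in milliseconds)."""
        rows = [
            {
                "subject": b.subject_id,
                "session": b.session_id,
                "date": self.session_dates[b.session_id].isoformat(),
                "category": b.category,
                "dv_ms": b.dv * 1000.0,
                "n": b.n,
                "N": b.N,
            }
            for b in self.blocks
        ]
        return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


def read_choice_table(path) -> Dataset:
    """Read a comma-separated choice table into a validated :class:`Dataset`.

    The file must carry the header columns ``subject, session, date,
    category, dv_ms, n, N``; ``dv_ms`` is converted to seconds internally.
    Malformed rows raise :class:`ValidationError` naming the offending row.
    """
    frame = pd.read_csv(path, dtype={"subject": str, "session": str, "category": str})
    missing = [c for c in TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"missing columns {missing} in {path}")

    blocks: list[ChoiceBlock] = []
    session_dates: dict[str, date] = {}
    subject_of: dict[str, str] = {}
    for idx, row in frame.iterrows():
        try:
            day = datetime.strptime(str(row["date"]), "%Y-%m-%d").date()
            block = ChoiceBlock(
                subject_id=str(row["subject"]),
                session_id=str(row["session"]),
                category=str(row["category"]),
                dv=float(row["dv_ms"]) / 1000.0,
                n=int(row["n"]),
                N=int(row["N"]),
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"row {idx}: {exc}") from exc
        sid = block.session_id
        if sid in session_dates and session_dates[sid] != day:
            raise ValidationError(f"row {idx}: session {sid!r} has conflicting dates")
        if sid in subject_of and subject_of[sid] != block.subject_id:
            raise ValidationError(f"row {idx}: session {sid!r} has conflicting subjects")
        session_dates[sid] = day
        subject_of[sid] = block.subject_id
        blocks.append(block)
    return Dataset(blocks=blocks, session_dates=session_dates, subject_of=subject_of)


def write_choice_table(dataset: Dataset, path) -> None:
    """Write ``dataset`` in the same CSV schema :func:`read_choice_table` accepts."""
    dataset.to_frame().to_csv(path, index=False)


def standardized_session_ranks(
    session_dates: dict[str, date], subject_of: dict[str, str]
) -> dict[str, float]:
    """Within-subject rank-then-z-score transform of session dates.

    Dates are rank ordered within each subject (ties get midranks) and the
    ranks are centered and scaled by their population standard deviation,
    so each subject's covariate vector has mean 0 and unit variance.  A
    subject with a single session gets covariate 0.0 with a warning, since
    the variance is undefined there.
    """
    by_subject: dict[str, list[str]] = {}
    for sid in session_dates:
        by_subject.setdefault(subject_of[sid], []).append(sid)

    out: dict[str, float] = {}
    for subject, sids in by_subject.items():
        if len(sids) == 1:
            warnings.warn(
                f"subject {subject!r} has a single session; "
                "time covariate set to 0 (variance undefined)",
                stacklevel=2,
            )
            out[sids[0]] = 0.0
            continue
        ordinals = np.array([session_dates[s].toordinal() for s in sids], dtype=float)
        ranks = rankdata(ordinals, method="average")
        centered = ranks - ranks.mean()
        sd = np.sqrt(np.mean(centered**2))
        if sd == 0.0:  # all sessions share one date
            warnings.warn(
                f"subject {subject!r}: all sessions share a date; covariate set to 0",
                stacklevel=2,
            )
            vals = np.zeros_like(centered)
        else:
            vals = centered / sd
        for s, t in zip(sids, vals):
            out[s] = float(t)
    return out


def session_time_covariate(dataset: Dataset) -> dict[str, float]:
    """Standardized within-subject session-time covariate for ``dataset``.

    See :func:`standardized_session_ranks` for the transform; this is the
    covariate the time-trend model multiplies by the per-(subject,
    category) drift rate.
    """
    return standardized_session_ranks(dataset.session_dates, dataset.subject_of)
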
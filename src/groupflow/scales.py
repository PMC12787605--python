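"""Flow questionnaire scoring and session-level group summaries.

Two validated instruments are scored:

- **FKS** (Flow Kurtz Scala): 13 seven-point core items (course progression,
  cognitive absorption, task relevance) plus three nine-point items each for
  subjective challenge (A1), skills (A2) and balance (A3).
- **EduFlow**: four dimensions of four seven-point items each — cognitive
  absorption (D1), time transformation (D2), loss of self-consciousness (D3)
  and autotelic experience / well-being (D4); the total is also expressed as a
  percentage of the scale maximum.

The *barriers* statistic condenses the challenge/skill/balance triple into a
single dimensionless group measure of perceived task asperity::

    barriers = (mean A1 - mean A2) / mean A3

Group dimension means average per-student dimension means (unweighted), and all
questionnaire/table statistics use the sample (n-1) standard deviation;
z-normalization uses the population SD so a two-point series maps to (-1, +1).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# item inventories

FKS_CORE_ITEMS: tuple[str, ...] = tuple(
    [f"FKS_P{i}" for i in range(1, 7)]     # course progression
    + [f"FKS_AB{i}" for i in range(1, 5)]  # cognitive absorption
    + [f"FKS_R{i}" for i in range(1, 4)]   # task relevance
)
FKS_A_ITEMS: dict[str, tuple[str, ...]] = {
    "a1": ("A1_1", "A1_2", "A1_3"),
    "a2": ("A2_1", "A2_2", "A2_3"),
    "a3": ("A3_1", "A3_2", "A3_3"),
}
EDUFLOW_ITEMS: dict[str, tuple[str, ...]] = {
    d: tuple(f"{d.upper()}_{i}" for i in range(1, 5)) for d in ("d1", "d2", "d3", "d4")
}
SEVEN_POINT = (1, 7)
NINE_POINT = (1, 9)
EDUFLOW_SCALE_MAX = 84.0  # published scale maximum used for the percent score


class ScoringError(ValueError):
    """An item response is out of range or a required statistic is undefined."""


@dataclass(frozen=True)
class FKSScores:
    """Per-student FKS scores: core total plus the three A-dimension means."""

    core_total: float | None
    a1: float | None
    a2: float | None
    a3: float | None
    n_missing: int = 0


@dataclass(frozen=True)
class EduFlowScores:
    d1: float
    d2: float
    d3: float
    d4: float
    total: float
    percent: float


@dataclass(frozen=True)
class LikertDistribution:
    """Counts over an ordinal scale for one item-group in one session."""

    counts: tuple[int, ...]
    low: int
    high: int

    def __post_init__(self) -> None:
        if len(self.counts) != self.high - self.low + 1:
            raise ValueError("counts length must match scale range")
        if any(c < 0 for c in self.counts) or sum(self.counts) == 0:
            raise ValueError("counts must be non-negative with a positive total")

    @property
    def n(self) -> int:
        return int(sum(self.counts))

    @property
    def probabilities(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float) / self.n


@dataclass(frozen=True)
class SessionSummary:
    """One session's group-level questionnaire and heart-rate summary.

    Fields that cannot be computed from the available inputs (e.g. barriers
    without A-dimension means, HRg without the first span) are ``None`` rather
    than silently imputed.
    """

    group: str
    session: int
    a1_mean: float | None = None
    a2_mean: float | None = None
    a3_mean: float | None = None
    barriers: float | None = None
    d1g: float | None = None
    eduflow_percent: float | None = None
    hrg: float | None = None
    sdg: float | None = None
    easfe_label: str | None = None

    @property
    def hr_missing(self) -> bool:
        return self.hrg is None


@dataclass(frozen=True)
class ZScores:
    """A standardized series together with the transform needed to invert it."""

    values: np.ndarray
    center: float
    scale: float

    def inverse(self) -> np.ndarray:
        return self.values * self.scale + self.center


# ---------------------------------------------------------------------------
# scoring

def _check_range(item: str, value: float, low: int, high: int) -> None:
    if not (low <= value <= high):
        raise ScoringError(f"item {item}: value {value} outside scale [{low}, {high}]")


def _dimension_mean(responses: Mapping[str, float], items: Sequence[str],
                    low: int, high: int, min_answered: int = 2) -> tuple[float | None, int]:
    vals = []
    missing = 0
    for item in items:
        v = responses.get(item)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            missing += 1
            continue
        _check_range(item, v, low, high)
        vals.append(float(v))
    if len(vals) < min_answered:
        return None, missing
    return float(np.mean(vals)), missing


def score_fks(responses: Mapping[str, float]) -> FKSScores:
    """Score one student's FKS response row.

    A-dimension means require at least 2 of 3 items answered, otherwise the
    dimension is reported missing; unanswered items are counted, never imputed.
    """
    missing = 0
    core_vals = []
    for item in FKS_CORE_ITEMS:
        v = responses.get(item)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            missing += 1
            continue
        _check_range(item, v, *SEVEN_POINT)
        core_vals.append(float(v))
    core_total = float(np.sum(core_vals)) if core_vals else None
    dims = {}
    for dim, items in FKS_A_ITEMS.items():
        mean, miss = _dimension_mean(responses, items, *NINE_POINT)
        dims[dim] = mean
        missing += miss
    return FKSScores(core_total, dims["a1"], dims["a2"], dims["a3"], missing)


def score_eduflow(responses: Mapping[str, float], scale_max: float = EDUFLOW_SCALE_MAX) -> EduFlowScores:
    """Score one student's EduFlow response row; percent = total / scale_max * 100."""
    if scale_max <= 0:
        raise ScoringError(f"scale_max must be positive, got {scale_max}")
    sums = {}
    for dim, items in EDUFLOW_ITEMS.items():
        vals = []
        for item in items:
            v = responses.get(item)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                raise ScoringError(f"missing EduFlow item {item}")
            _check_range(item, v, *SEVEN_POINT)
            vals.append(float(v))
        sums[dim] = float(np.sum(vals))
    total = float(sum(sums.values()))
    return EduFlowScores(sums["d1"], sums["d2"], sums["d3"], sums["d4"],
                         total, total / scale_max * 100.0)


def compute_barriers(a1_mean: float, a2_mean: float, a3_mean: float) -> float:
    """Group barriers statistic (mean A1 - mean A2) / mean A3; requires mean A3 > 0."""
    if not a3_mean > 0:
        raise ScoringError(f"barriers undefined: mean A3 must be positive, got {a3_mean}")
    return (a1_mean - a2_mean) / a3_mean


def z_normalize(series, window=None) -> ZScores:
    """Standardize a series to mean 0, SD 1 (population SD) within a window.

    ``window`` optionally selects (boolean mask or index array) the elements
    whose mean/SD define the transform; all elements are transformed with it.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ScoringError("z_normalize requires a 1-D series of length >= 2")
    ref = x if window is None else x[window]
    center = float(np.mean(ref))
    scale = float(np.std(ref))
    if scale == 0.0:
        raise ScoringError("z_normalize: degenerate series with zero variance")
    return ZScores((x - center) / scale, center, scale)


def likert_histogram(responses: Iterable[float], scale_range: tuple[int, int]) -> tuple[LikertDistribution, float, float]:
    """Tally responses over an ordinal scale; returns (distribution, mean, sample SD)."""
    low, high = scale_range
    vals = np.asarray(list(responses), dtype=float)
    if vals.size == 0:
        raise ScoringError("likert_histogram: no responses")
    if ((vals < low) | (vals > high)).any():
        raise ScoringError(f"responses outside scale [{low}, {high}]")
    counts = tuple(int((vals == k).sum()) for k in range(low, high + 1))
    sd = float(vals.std(ddof=1)) if vals.size >= 2 else 0.0
    return LikertDistribution(counts, low, high), float(vals.mean()), sd


# ---------------------------------------------------------------------------
# session-level aggregation

def _responses_by_student(table: pd.DataFrame) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for sid, sub in table.groupby("student_id", sort=True):
        out[str(sid)] = dict(zip(sub["item_id"], sub["value"]))
    return out


def summarize_session(
    group: str,
    session: int,
    fks_table: pd.DataFrame | None,
    eduflow_table: pd.DataFrame | None,
    span0=None,
    eduflow_scale_max: float = EDUFLOW_SCALE_MAX,
) -> SessionSummary:
    """Aggregate one session's questionnaire tables and first-span HR statistics.

    Response tables are long-format frames with columns
    ``student_id, item_id, value``. Group A-dimension means average per-student
    dimension means; barriers follows from those means and is ``None`` whenever
    the FKS A-items are unavailable. HRg/SDg are copied from the first 5-minute
    span summary (``span0``); physiological measures describe session onset
    while questionnaires are answered at the end.
    """
    a_means: dict[str, float | None] = {"a1": None, "a2": None, "a3": None}
    if fks_table is not None and len(fks_table):
        per_student = [score_fks(r) for r in _responses_by_student(fks_table).values()]
        for dim in a_means:
            vals = [getattr(s, dim) for s in per_student if getattr(s, dim) is not None]
            a_means[dim] = float(np.mean(vals)) if vals else None
    barriers = None
    if all(a_means[d] is not None for d in ("a1", "a2", "a3")):
        barriers = compute_barriers(a_means["a1"], a_means["a2"], a_means["a3"])

    d1g = eduflow_percent = None
    if eduflow_table is not None and len(eduflow_table):
        scores = [score_eduflow(r, eduflow_scale_max)
                  for r in _responses_by_student(eduflow_table).values()]
        d1g = float(np.mean([s.d1 for s in scores]))
        eduflow_percent = float(np.mean([s.percent for s in scores]))

    hrg = sdg = None
    if span0 is not None and not span0.empty:
        hrg, sdg = span0.hrg, span0.sdg
    return SessionSummary(group, session, a_means["a1"], a_means["a2"], a_means["a3"],
                          barriers, d1g, eduflow_percent, hrg, sdg)


def z_score_table(
    session_table: pd.DataFrame,
    columns: Mapping[str, str] = None,
) -> pd.DataFrame:
    """Standardize session-summary columns within the table's rows (the window).

    The default maps ``hrg/sdg/eduflow_percent/barriers/d1g`` (those present) to
    ``zhrg/zsdg/zflow/zbarriers/zd1``. The normalization window is the table
    passed in — typically one study arm across all its sessions.
    """
    if columns is None:
        columns = {"zhrg": "hrg", "zsdg": "sdg", "zflow": "eduflow_percent",
                   "zbarriers": "barriers", "zd1": "d1g"}
        columns = {z: c for z, c in columns.items() if c in session_table.columns}
    out = session_table.copy()
    for zname, col in columns.items():
        out[zname] = z_normalize(session_table[col].to_numpy(dtype=float)).values
    return out
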
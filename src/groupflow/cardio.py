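"""Cardiac record ingestion, artifact filtering, span segmentation and group HR statistics.

Beat records are 1-Hz samples per student: a Unix timestamp (seconds), an
instantaneous heart rate (bpm) and the current R-R interval (ms). Sessions are
partitioned into fixed-length spans (5 minutes by default) and summarised per
span with the group mean heart rate (HRg), the group heart-rate standard
deviation (SDg) and the short/long-term Poincare ellipse axes (SD1/SD2) of the
R-R series, averaged over students.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("groupflow")

#: canonical column schema of a beat table (delimited text)
BEAT_COLUMNS = ("group", "session", "student_id", "unix_time_s", "bpm", "rr_ms")

#: default physiological R-R plausibility bounds, ms (~30-200 bpm)
RR_BOUNDS_MS = (300.0, 2000.0)


class SchemaError(ValueError):
    """A delimited input file does not conform to its documented column schema."""


@dataclass(frozen=True)
class BeatSample:
    """One timestamped cardiac observation for one student."""

    student_id: str
    unix_time: int
    bpm: float
    rr_ms: float

    def __post_init__(self) -> None:
        if not self.bpm > 0:
            raise ValueError(f"bpm must be positive, got {self.bpm}")
        if not self.rr_ms > 0:
            raise ValueError(f"rr_ms must be positive, got {self.rr_ms}")


@dataclass(frozen=True)
class SpanSummary:
    """Group heart-rate statistics for one fixed-length span of one session.

    ``hrg``/``sdg`` are in bpm, ``sd1``/``sd2`` in ms. ``n_students`` counts the
    students contributing at least one sample to the span.
    """

    group: str
    session: int
    span_index: int
    hrg: float
    sdg: float
    sd1: float
    sd2: float
    n_students: int

    @property
    def empty(self) -> bool:
        return self.n_students == 0


@dataclass(frozen=True)
class ParseReport:
    n_rows: int
    n_parsed: int
    n_skipped: int
    n_resorted_students: int


def parse_beat_table(path) -> tuple[pd.DataFrame, ParseReport]:
    """Read a beat table, returning time-sorted samples plus a parse report.

    Rows with unparsable or non-positive ``bpm``/``rr_ms`` are dropped and
    counted; students whose timestamps are not non-decreasing are re-sorted
    with a warning. Missing columns raise :class:`SchemaError`.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"student_id": str})
    missing = [c for c in BEAT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"beat table {path} is missing columns: {missing}")
    n_rows = len(df)
    for col in ("unix_time_s", "bpm", "rr_ms"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    ok = df[["unix_time_s", "bpm", "rr_ms"]].notna().all(axis=1)
    ok &= (df["bpm"] > 0) & (df["rr_ms"] > 0)
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning("parse_beat_table: skipped %d malformed rows in %s", n_skipped, path)
    df = df.loc[ok].copy()
    df["unix_time_s"] = df["unix_time_s"].astype(np.int64)

    n_resorted = 0
    for sid, sub in df.groupby("student_id", sort=False):
        if not sub["unix_time_s"].is_monotonic_increasing:
            n_resorted += 1
            logger.warning("parse_beat_table: non-monotone timestamps for student %s; re-sorting", sid)
    df = df.sort_values(["group", "session", "student_id", "unix_time_s"], kind="stable")
    df = df.reset_index(drop=True)
    return df, ParseReport(n_rows, len(df), n_skipped, n_resorted)


def write_beat_table(df: pd.DataFrame, path) -> None:
    """Write a beat table in the canonical delimited-text schema."""
    df.loc[:, list(BEAT_COLUMNS)].to_csv(path, sep="\t", index=False)


def filter_artifacts(
    samples: pd.DataFrame,
    rr_low_ms: float = RR_BOUNDS_MS[0],
    rr_high_ms: float = RR_BOUNDS_MS[1],
) -> tuple[pd.DataFrame, int]:
    """Remove samples whose R-R interval lies outside ``[rr_low_ms, rr_high_ms]``.

    Order is preserved. Returns the filtered frame and the rejection count.
    A crude stand-in for a full artifact-correction pass: spikes from missed or
    spurious beat detections land outside any physiologic R-R range.
    """
    if not 0 < rr_low_ms < rr_high_ms:
        raise ValueError(f"require 0 < rr_low_ms < rr_high_ms, got ({rr_low_ms}, {rr_high_ms})")
    keep = (samples["rr_ms"] >= rr_low_ms) & (samples["rr_ms"] <= rr_high_ms)
    rejected = int((~keep).sum())
    return samples.loc[keep].copy(), rejected


def segment_spans(
    samples: pd.DataFrame,
    session_start: int,
    span_length: int = 300,
    n_spans: int | None = None,
) -> dict[int, pd.DataFrame]:
    """Partition samples into half-open spans ``[start, start + span_length)``.

    A sample at time ``t`` belongs to span ``floor((t - session_start) / span_length)``;
    a sample exactly on a boundary therefore opens the later span. Samples before
    ``session_start`` are excluded with a warning. Spans with no samples are
    returned as empty frames, not dropped; ``n_spans`` forces the number of spans
    reported (defaults to enough to cover the last sample).
    """
    if span_length <= 0:
        raise ValueError(f"span_length must be positive, got {span_length}")
    early = samples["unix_time_s"] < session_start
    if early.any():
        logger.warning("segment_spans: excluded %d samples before session start", int(early.sum()))
        samples = samples.loc[~early]
    idx = ((samples["unix_time_s"] - session_start) // span_length).astype(int)
    if n_spans is None:
        n_spans = (int(idx.max()) + 1) if len(idx) else 0
    out: dict[int, pd.DataFrame] = {k: samples.loc[idx == k] for k in range(n_spans)}
    return out


def poincare_sd(rr_series) -> tuple[float, float]:
    """Short- and long-term Poincare ellipse axes (SD1, SD2) of an R-R series, in ms.

    SD1 is the RMS perpendicular distance of the lag-1 points to the identity
    line, SD2 the dispersion along it::

        sd1 = sqrt(mean(diff(rr)**2) / 2)      # == RMSSD / sqrt(2)
        sd2 = sqrt(2 * var(rr) - sd1**2)

    The second moment of the successive differences is taken about zero (the
    identity line) and var() is the population variance, so closed-form
    identities (e.g. a strictly alternating series having sd1 = step/sqrt(2)
    and sd2 == 0) hold exactly; a radicand negative within 1e-9 is clamped to
    zero.
    """
    rr = np.asarray(rr_series, dtype=float)
    if rr.ndim != 1 or rr.size < 2:
        raise ValueError("poincare_sd requires a 1-D series of length >= 2")
    sd1 = float(np.sqrt(np.mean(np.diff(rr) ** 2) / 2.0))
    radicand = 2.0 * float(np.var(rr)) - sd1 * sd1
    if radicand < 0:
        if radicand < -1e-9:
            raise ValueError(f"negative sd2 radicand {radicand}")
        radicand = 0.0
    return sd1, float(np.sqrt(radicand))


def span_group_stats(
    span_samples: pd.DataFrame,
    group: str = "",
    session: int = 0,
    span_index: int = 0,
    sdg_mode: str = "within_student",
) -> SpanSummary:
    """Summarise one span's samples into group HR statistics.

    HRg is the mean over students of each student's mean bpm. SDg depends on
    ``sdg_mode``:

    - ``"within_student"`` (default): mean over students of each student's own
      bpm standard deviation within the span — a within-person variability
      measure, the reading that ties SDg to parasympathetic modulation.
    - ``"between_students"``: standard deviation across the students' span means.

    Sample (n-1) standard deviations are used in both modes. SD1/SD2 are
    computed per student from the R-R series and group-averaged; students with
    fewer than two samples contribute to HRg but not to SDg/SD1/SD2.
    """
    if sdg_mode not in ("within_student", "between_students"):
        raise ValueError(f"unknown sdg_mode {sdg_mode!r}")
    by_student = span_samples.groupby("student_id", sort=True)
    means, sds, sd1s, sd2s = [], [], [], []
    for _, sub in by_student:
        bpm = sub["bpm"].to_numpy(dtype=float)
        means.append(bpm.mean())
        if len(bpm) >= 2:
            sds.append(bpm.std(ddof=1))
            s1, s2 = poincare_sd(sub["rr_ms"].to_numpy(dtype=float))
            sd1s.append(s1)
            sd2s.append(s2)
    n_students = len(means)
    if n_students == 0:
        return SpanSummary(group, session, span_index, float("nan"), float("nan"),
                           float("nan"), float("nan"), 0)
    hrg = float(np.mean(means))
    if sdg_mode == "within_student":
        sdg = float(np.mean(sds)) if sds else float("nan")
    else:
        sdg = float(np.std(means, ddof=1)) if n_students >= 2 else float("nan")
    sd1 = float(np.mean(sd1s)) if sd1s else float("nan")
    sd2 = float(np.mean(sd2s)) if sd2s else float("nan")
    return SpanSummary(group, session, span_index, hrg, sdg, sd1, sd2, n_students)


def span_summary_table(summaries: Mapping[int, SpanSummary] | list[SpanSummary]) -> pd.DataFrame:
    """Tabulate span summaries (one row per span) in the documented schema."""
    vals = list(summaries.values()) if isinstance(summaries, Mapping) else list(summaries)
    return pd.DataFrame(
        [(s.group, s.session, s.span_index, s.hrg, s.sdg, s.sd1, s.sd2, s.n_students) for s in vals],
        columns=["group", "session", "span_index", "hrg", "sdg", "sd1", "sd2", "n_students"],
    )
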
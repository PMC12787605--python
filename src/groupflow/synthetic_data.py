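"""Synthetic two-arm classroom studies: beat streams, questionnaires, teacher recall.

The study's raw biometric records are not deposited, so this module generates
datasets with the same shape and the same statistical structure the analysis
assumes: per-student 1-Hz cardiac samples (R-R intervals in ms plus the derived
bpm), per-session FKS and EduFlow questionnaire rows, and one teacher recall
score per scale and session.

Mechanics, chosen as the simplest processes reproducing the study's documented
moments:

- **R-R process**: a stationary first-order autoregressive Gaussian on the R-R
  interval (not on bpm) around each student's session mean; this is the minimal
  heart-rate-variability surrogate with nonzero SD1/SD2.
- **Session scripting**: each session receives a group heart-rate offset drawn
  once per study from a uniform range wide enough to reproduce the published
  between-session HRg spread (~74-99 bpm); questionnaire targets are coupled to
  the standardized offset through ``flow_hr_coupling`` / ``barriers_hr_coupling``,
  so opposite-sign couplings across arms reproduce the differential-correlation
  structure. The advisory feedback loop itself is not simulated.
- **Likert responses**: a normal law discretized onto the scale points
  (edge bins absorb the tails), moment-matched to the target mean/SD by a short
  fixed-point iteration, then sampled — yielding unimodal integer distributions.
- **Seeding**: one master seed; every (group, session, purpose) pair gets its
  own substream derived by stable hashing, so adding sessions or students never
  perturbs previously generated data.
"""
from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal, stats

from .scales import EDUFLOW_ITEMS, FKS_A_ITEMS, FKS_CORE_ITEMS

#: fixed epoch anchoring synthetic session-start timestamps (Unix seconds)
EPOCH = 1_600_000_000
#: sessions are one calendar day apart
SESSION_SPACING_S = 86_400

#: smallest |coupling| whose Spearman sign is recovered with >=95% probability
#: on the default 16-session, 14-student configuration (documented detectability
#: threshold; see docs/methods.md)
COUPLING_DETECTABILITY_THRESHOLD = 0.3


class ConfigError(ValueError):
    """A cohort configuration field is invalid; the message names the field."""


@dataclass(frozen=True)
class LikertScaleSpec:
    """One item-group: its items, scale range and target first two moments."""

    name: str
    items: tuple[str, ...]
    low: int
    high: int
    target_mean: float
    target_sd: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ConfigError(f"{self.name}: scale range [{self.low}, {self.high}] invalid")
        if not (self.low <= self.target_mean <= self.high):
            raise ConfigError(
                f"{self.name}: target_mean {self.target_mean} outside scale "
                f"[{self.low}, {self.high}]")
        if self.target_sd < 0:
            raise ConfigError(f"{self.name}: target_sd must be >= 0")


def _default_targets_control() -> dict[str, tuple[float, float]]:
    # (mean, SD) on the native scale; chosen to land near the published
    # control-arm session summaries (barriers ~ -0.5, EduFlow ~ 62%)
    return {
        "fks_core": (5.0, 1.2),
        "a1": (4.2, 1.3), "a2": (6.7, 1.3), "a3": (5.1, 1.1),
        "d1": (3.25, 1.0), "d2": (3.25, 1.0), "d3": (3.25, 1.0), "d4": (3.25, 1.0),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Generating parameters for one study arm (one classroom group)."""

    arm: str = "control"
    group_id: str | None = None
    n_students: int = 14
    n_sessions: int = 9
    session_length: int = 3600
    span_length: int = 300
    hr_baseline_mean: float = 85.0
    hr_between_student_sd: float = 8.0
    hr_within_student_sd: float = 3.0
    rr_ar1_coeff: float = 0.95
    session_hr_offset_range: tuple[float, float] = (-12.0, 12.0)
    flow_hr_coupling: float = 0.0
    barriers_hr_coupling: float = 0.0
    likert_targets: dict[str, tuple[float, float]] = field(default_factory=_default_targets_control)
    teacher_bias: float = 0.0
    teacher_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arm not in ("control", "experimental"):
            raise ConfigError(f"arm: must be 'control' or 'experimental', got {self.arm!r}")
        if self.n_students < 2:
            raise ConfigError(f"n_students: must be >= 2, got {self.n_students}")
        if self.n_sessions < 1:
            raise ConfigError(f"n_sessions: must be >= 1, got {self.n_sessions}")
        if self.session_length <= 0 or self.span_length <= 0:
            raise ConfigError("session_length/span_length: must be positive")
        if self.session_length % self.span_length:
            raise ConfigError(
                f"span_length: {self.span_length} does not divide "
                f"session_length {self.session_length}")
        for name in ("hr_between_student_sd", "hr_within_student_sd", "teacher_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be >= 0")
        if not (0 <= self.rr_ar1_coeff < 1):
            raise ConfigError(f"rr_ar1_coeff: must be in [0, 1), got {self.rr_ar1_coeff}")
        lo, hi = self.session_hr_offset_range
        if lo > hi:
            raise ConfigError("session_hr_offset_range: low > high")
        for name, (mean, sd) in self.likert_targets.items():
            low, high = _scale_range(name)
            if not (low <= mean <= high):
                raise ConfigError(
                    f"likert_targets[{name!r}]: target mean {mean} outside scale [{low}, {high}]")
            if sd < 0:
                raise ConfigError(f"likert_targets[{name!r}]: SD must be >= 0")

    @property
    def group(self) -> str:
        return self.group_id or self.arm

    @property
    def n_spans(self) -> int:
        return self.session_length // self.span_length


def control_config(**overrides) -> CohortConfig:
    """Control-arm defaults: flow decreases and barriers increase with group HR."""
    kw = dict(arm="control", flow_hr_coupling=-0.6, barriers_hr_coupling=0.6)
    kw.update(overrides)
    return CohortConfig(**kw)


def experimental_config(**overrides) -> CohortConfig:
    """Experimental-arm defaults: couplings reversed, higher flow targets."""
    targets = _default_targets_control()
    for d in ("d1", "d2", "d3", "d4"):
        targets[d] = (3.8, 1.0)
    kw = dict(arm="experimental", flow_hr_coupling=0.6, barriers_hr_coupling=-0.6,
              likert_targets=targets)
    kw.update(overrides)
    return CohortConfig(**kw)


# ---------------------------------------------------------------------------
# deterministic substreams

def substream(seed: int, *keys) -> np.random.Generator:
    """Child generator for (seed, *keys); strings are hashed stably (CRC-32)."""
    ints = tuple(zlib.crc32(k.encode()) if isinstance(k, str) else int(k) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=ints))


def session_start_time(session_index: int) -> int:
    """Synthetic Unix start time of a session (one per day from a fixed epoch)."""
    return EPOCH + session_index * SESSION_SPACING_S


def session_hr_offsets(config: CohortConfig) -> np.ndarray:
    """Scripted per-session HRg offsets (bpm), drawn once per study."""
    lo, hi = config.session_hr_offset_range
    rng = substream(config.seed, config.group, "session-offsets")
    return rng.uniform(lo, hi, size=config.n_sessions)


def _standardized_offset(config: CohortConfig, offset: float) -> float:
    """Offset in units of the scripted uniform law's SD (0 if the range is a point)."""
    lo, hi = config.session_hr_offset_range
    sd = (hi - lo) / np.sqrt(12.0)
    return 0.0 if sd == 0 else (offset - (lo + hi) / 2.0) / sd


# ---------------------------------------------------------------------------
# Likert machinery

_SCALE_ITEMS: dict[str, tuple[tuple[str, ...], int, int]] = {
    "fks_core": (FKS_CORE_ITEMS, 1, 7),
    **{d: (items, 1, 9) for d, items in
       zip(("a1", "a2", "a3"), (FKS_A_ITEMS["a1"], FKS_A_ITEMS["a2"], FKS_A_ITEMS["a3"]))},
    **{d: (EDUFLOW_ITEMS[d], 1, 7) for d in ("d1", "d2", "d3", "d4")},
}


def _scale_range(name: str) -> tuple[int, int]:
    try:
        _, low, high = _SCALE_ITEMS[name]
    except KeyError:
        raise ConfigError(f"likert_targets: unknown item-group {name!r}") from None
    return low, high


def scale_spec(name: str, target_mean: float, target_sd: float) -> LikertScaleSpec:
    items, low, high = _SCALE_ITEMS[name]
    return LikertScaleSpec(name, items, low, high, target_mean, target_sd)


def discretized_pmf(low: int, high: int, mu: float, sigma: float) -> np.ndarray:
    """Normal(mu, sigma) discretized onto integer scale points via half-open bins.

    Interior score k receives the mass of (k-1/2, k+1/2]; the edge scores absorb
    the respective tails. sigma == 0 degenerates to a point mass at the nearest
    in-range score.
    """
    scores = np.arange(low, high + 1)
    if sigma == 0:
        p = np.zeros(scores.size)
        p[int(np.clip(round(mu), low, high)) - low] = 1.0
        return p
    edges = np.concatenate(([-np.inf], scores[:-1] + 0.5, [np.inf]))
    cdf = stats.norm.cdf(edges, loc=mu, scale=sigma)
    p = np.diff(cdf)
    return p / p.sum()


def moment_matched_pmf(spec: LikertScaleSpec, max_iter: int = 100) -> np.ndarray:
    """Latent (mu, sigma) fixed-point iteration matching the target mean/SD.

    The mean is matched to numerical precision whenever attainable (it is not
    for targets at the scale edge with positive SD); the SD is matched as
    closely as the discreteness allows.
    """
    scores = np.arange(spec.low, spec.high + 1)
    if spec.target_sd == 0:
        return discretized_pmf(spec.low, spec.high, spec.target_mean, 0.0)
    mu, sigma = spec.target_mean, max(spec.target_sd, 1e-3)
    for _ in range(max_iter):
        p = discretized_pmf(spec.low, spec.high, mu, sigma)
        m = float(scores @ p)
        s = float(np.sqrt(max(scores.astype(float) ** 2 @ p - m * m, 0.0)))
        if abs(m - spec.target_mean) < 1e-10 and abs(s - spec.target_sd) < 1e-6:
            break
        mu += spec.target_mean - m
        mu = float(np.clip(mu, spec.low - 6 * sigma, spec.high + 6 * sigma))
        if s > 1e-9:
            sigma *= float(np.clip(spec.target_sd / s, 0.5, 2.0))
            sigma = max(sigma, 1e-4)
    return discretized_pmf(spec.low, spec.high, mu, sigma)


def generate_likert_responses(
    config: CohortConfig,
    spec: LikertScaleSpec,
    session_index: int,
    n: int | None = None,
) -> pd.DataFrame:
    """Integer responses for one item-group: one row per student per item.

    Every item of the group is drawn independently from the moment-matched
    discretized law. Deterministic given the config seed, group, session and
    item-group name.
    """
    if not 0 <= session_index < config.n_sessions:
        raise ConfigError(f"session_index: {session_index} out of range")
    n = config.n_students if n is None else n
    rng = substream(config.seed, config.group, session_index, "likert", spec.name)
    pmf = moment_matched_pmf(spec)
    scores = np.arange(spec.low, spec.high + 1)
    rows = []
    for i in range(n):
        sid = f"{config.group}-s{i:02d}"
        draws = rng.choice(scores, size=len(spec.items), p=pmf)
        rows.extend((sid, item, int(v)) for item, v in zip(spec.items, draws))
    out = pd.DataFrame(rows, columns=["student_id", "item_id", "value"])
    out.insert(0, "session", session_index)
    out.insert(0, "group", config.group)
    return out


# ---------------------------------------------------------------------------
# cardiac streams

def generate_beat_streams(
    config: CohortConfig,
    session_index: int,
    session_offset: float | None = None,
) -> pd.DataFrame:
    """1-Hz beat samples for every student over one session.

    Each student's session-mean heart rate is drawn from
    Normal(hr_baseline_mean + session offset, hr_between_student_sd); the R-R
    series is a stationary AR(1) around the corresponding mean interval with a
    stationary SD calibrated (to first order) so the bpm fluctuation SD equals
    ``hr_within_student_sd``. bpm = 60000 / RR throughout.
    """
    if not 0 <= session_index < config.n_sessions:
        raise ConfigError(f"session_index: {session_index} out of range")
    if session_offset is None:
        session_offset = float(session_hr_offsets(config)[session_index])
    start = session_start_time(session_index)
    t = np.arange(config.session_length, dtype=np.int64) + start
    phi = config.rr_ar1_coeff
    frames = []
    for i in range(config.n_students):
        sid = f"{config.group}-s{i:02d}"
        rng = substream(config.seed, config.group, session_index, "beats", i)
        m = config.hr_baseline_mean + session_offset \
            + config.hr_between_student_sd * rng.standard_normal()
        m = max(m, 30.0)
        mu_rr = 60000.0 / m
        sd_rr = config.hr_within_student_sd * 60000.0 / (m * m)
        eps = rng.standard_normal(config.session_length) * sd_rr * np.sqrt(1.0 - phi * phi)
        if config.session_length:
            eps[0] = rng.standard_normal() * sd_rr  # stationary start
        x = signal.lfilter([1.0], [1.0, -phi], eps)
        rr = np.maximum(mu_rr + x, 200.0)
        frames.append(pd.DataFrame({
            "group": config.group, "session": session_index, "student_id": sid,
            "unix_time_s": t, "bpm": 60000.0 / rr, "rr_ms": rr,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# teacher recall

def generate_teacher_recall(
    group_mean: float,
    config: CohortConfig,
    scale_range: tuple[float, float],
    session_index: int = 0,
    scale_name: str = "eduflow",
) -> float:
    """Teacher-recalled total score: group mean + systematic bias + noise, clipped.

    A negative ``teacher_bias`` expresses a teacher who consistently reports
    less flow than the averaged pupils.
    """
    lo, hi = scale_range
    if not (lo <= group_mean <= hi):
        raise ConfigError(f"group_mean {group_mean} outside scale range [{lo}, {hi}]")
    rng = substream(config.seed, config.group, session_index, "teacher", scale_name)
    noise = rng.standard_normal() * config.teacher_noise_sd
    return float(np.clip(group_mean + config.teacher_bias + noise, lo, hi))


# ---------------------------------------------------------------------------
# full study

@dataclass
class StudyDataset:
    """One generated two-arm study plus the generating truth for recovery tests."""

    beat_tables: dict[tuple[str, int], pd.DataFrame]
    fks_tables: dict[tuple[str, int], pd.DataFrame]
    eduflow_tables: dict[tuple[str, int], pd.DataFrame]
    teacher_recall: pd.DataFrame
    truth: dict

    @property
    def groups(self) -> list[str]:
        return sorted({g for g, _ in self.beat_tables})

    def sessions(self, group: str) -> list[int]:
        return sorted(s for g, s in self.beat_tables if g == group)


def _session_targets(config: CohortConfig, z_off: float) -> dict[str, tuple[float, float]]:
    """Per-session Likert targets after applying the HR couplings."""
    targets = dict(config.likert_targets)

    def shift(name: str, delta: float) -> None:
        low, high = _scale_range(name)
        mean, sd = targets[name]
        targets[name] = (float(np.clip(mean + delta, low + 0.25, high - 0.25)), sd)

    for d in ("d1", "d2", "d3", "d4"):
        shift(d, config.flow_hr_coupling * z_off)
    # split the barriers coupling between challenge (up) and skills (down) so the
    # (A1 - A2) difference moves by barriers_hr_coupling * z per session
    shift("a1", 0.5 * config.barriers_hr_coupling * z_off)
    shift("a2", -0.5 * config.barriers_hr_coupling * z_off)
    return targets


def generate_cohort(config: CohortConfig) -> StudyDataset:
    """Generate one arm: beat streams, questionnaires and teacher recall."""
    offsets = session_hr_offsets(config)
    beats, fks, edu, teacher_rows = {}, {}, {}, []
    for s in range(config.n_sessions):
        z = _standardized_offset(config, float(offsets[s]))
        targets = _session_targets(config, z)
        beats[(config.group, s)] = generate_beat_streams(config, s, float(offsets[s]))
        fks_parts = [generate_likert_responses(config, scale_spec(nm, *targets[nm]), s)
                     for nm in ("fks_core", "a1", "a2", "a3")]
        edu_parts = [generate_likert_responses(config, scale_spec(nm, *targets[nm]), s)
                     for nm in ("d1", "d2", "d3", "d4")]
        fks[(config.group, s)] = pd.concat(fks_parts, ignore_index=True)
        edu[(config.group, s)] = pd.concat(edu_parts, ignore_index=True)

        core_range = (len(FKS_CORE_ITEMS) * 1.0, len(FKS_CORE_ITEMS) * 7.0)
        edu_range = (16.0, 112.0)
        fks_tab = fks[(config.group, s)]
        fks_mean = float(fks_tab[fks_tab["item_id"].isin(FKS_CORE_ITEMS)]
                         .groupby("student_id")["value"].sum().mean())
        edu_mean = float(edu[(config.group, s)].groupby("student_id")["value"].sum().mean())
        teacher_rows.append((config.group, s, "fks",
                             generate_teacher_recall(fks_mean, config, core_range, s, "fks"),
                             fks_mean))
        teacher_rows.append((config.group, s, "eduflow",
                             generate_teacher_recall(edu_mean, config, edu_range, s, "eduflow"),
                             edu_mean))
    teacher = pd.DataFrame(teacher_rows,
                           columns=["group", "session", "scale", "teacher_score",
                                    "group_mean_score"])
    truth = {"configs": {config.group: dataclasses.asdict(config)},
             "session_hr_offsets": {config.group: offsets.tolist()}}
    return StudyDataset(beats, fks, edu, teacher, truth)


def generate_study(control: CohortConfig, experimental: CohortConfig) -> StudyDataset:
    """Generate a full two-arm study; arms must agree on the session count."""
    if control.n_sessions != experimental.n_sessions:
        raise ConfigError(
            f"n_sessions: conflicting session counts "
            f"({control.n_sessions} vs {experimental.n_sessions})")
    if control.group == experimental.group:
        raise ConfigError("group_id: the two arms must have distinct group ids")
    a, b = generate_cohort(control), generate_cohort(experimental)
    truth = {"configs": {**a.truth["configs"], **b.truth["configs"]},
             "session_hr_offsets": {**a.truth["session_hr_offsets"],
                                    **b.truth["session_hr_offsets"]}}
    return StudyDataset({**a.beat_tables, **b.beat_tables},
                        {**a.fks_tables, **b.fks_tables},
                        {**a.eduflow_tables, **b.eduflow_tables},
                        pd.concat([a.teacher_recall, b.teacher_recall], ignore_index=True),
                        truth)


def write_study(dataset: StudyDataset, outdir) -> None:
    """Write a study as delimited text: beats, questionnaires, teacher, truth."""
    import pathlib

    import yaml

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pd.concat(dataset.beat_tables.values(), ignore_index=True).to_csv(
        out / "beats.tsv", sep="\t", index=False)
    pd.concat(dataset.fks_tables.values(), ignore_index=True).to_csv(
        out / "fks_responses.tsv", sep="\t", index=False)
    pd.concat(dataset.eduflow_tables.values(), ignore_index=True).to_csv(
        out / "eduflow_responses.tsv", sep="\t", index=False)
    dataset.teacher_recall.to_csv(out / "teacher_recall.tsv", sep="\t", index=False)
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(dataset.truth, fh, default_flow_style=False)
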
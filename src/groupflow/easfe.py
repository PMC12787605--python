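"""Offline flow-zone decision layer: calibration fits, classification, advice.

The live early-alert system maps standardized group heart-rate statistics to
four phenomenological flow zones (High / Medium / Low / No Flow) and issues a
teaching action per zone. Its exact internal geometry is unpublished, so the
classifier here is a declared reconstruction: a quadratic prediction of
standardized group flow from standardized group heart rate (matching the convex
flow-vs-HR calibration curve) plus a linear zSDg term, binned by three
increasing cutpoints. Cutpoints default to the quartiles of the calibration
predictions, every parameter is config-exposed, and boundary ties go to the
higher zone.

The paired calibration curves — barriers concave in zHRg, flow convex in zHRg —
together trace the "fish" silhouette of the published relationship; their fits
(least-squares quadratics with the multiple correlation r = sqrt(R^2)) are
provided by :func:`fit_fish_curves`.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class FlowZone(str, Enum):
    NO = "No Flow"
    LOW = "Low"
    MEDIUM = "Medium"
    HIGH = "High"

    @classmethod
    def from_label(cls, label: str) -> "FlowZone":
        for z in cls:
            if z.value == label or z.name.lower() == str(label).strip().lower():
                return z
        raise ValueError(f"unknown flow-zone label {label!r}")


class Action(str, Enum):
    NONE = "none"
    REPEAT_ONCE = "repeat_once"
    REPEAT_TWICE = "repeat_twice"
    BREAK_THEN_REPEAT_TWICE = "break_then_repeat_twice"


#: total advisory mapping: what the teacher does in each zone
ADVICE_MAP: dict[FlowZone, Action] = {
    FlowZone.HIGH: Action.NONE,
    FlowZone.MEDIUM: Action.REPEAT_ONCE,
    FlowZone.LOW: Action.REPEAT_TWICE,
    FlowZone.NO: Action.BREAK_THEN_REPEAT_TWICE,
}


@dataclass(frozen=True)
class Advice:
    label: FlowZone
    action: Action


@dataclass(frozen=True)
class QuadraticFit:
    """Least-squares quadratic y = c0 + c1 x + c2 x^2 with multiple correlation r."""

    c0: float
    c1: float
    c2: float
    r: float

    @property
    def concave(self) -> bool:
        return self.c2 < 0

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.c0 + self.c1 * x + self.c2 * x * x


@dataclass(frozen=True)
class FlowZoneConfig:
    """Calibrated classifier: quadratic flow prediction, zSDg weight, cutpoints."""

    c0: float
    c1: float
    c2: float
    sdg_weight: float
    cutpoints: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not (self.cutpoints[0] < self.cutpoints[1] < self.cutpoints[2]):
            raise ValueError(f"cutpoints must be strictly increasing, got {self.cutpoints}")

    def score(self, zhrg: float, zsdg: float) -> float:
        return self.c0 + self.c1 * zhrg + self.c2 * zhrg * zhrg + self.sdg_weight * zsdg


def _quad_fit(x: np.ndarray, y: np.ndarray) -> QuadraticFit:
    if len(x) < 4:
        raise ValueError("quadratic fit requires >= 4 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: constant predictor")
    c2, c1, c0 = np.polyfit(x, y, 2)
    resid = y - (c0 + c1 * x + c2 * x * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        r = 1.0 if np.allclose(resid, 0) else 0.0
    else:
        r = float(np.sqrt(max(1.0 - float(np.sum(resid**2)) / ss_tot, 0.0)))
    return QuadraticFit(float(c0), float(c1), float(c2), r)


def fit_fish_curves(z_table: pd.DataFrame) -> tuple[QuadraticFit, QuadraticFit]:
    """Fit zBarriers and zFlow as quadratics of zHRg over a session table.

    Returns ``(barriers_fit, flow_fit)``. On the published control-arm pattern
    the barriers curve is concave (negative leading coefficient) and the flow
    curve convex; together they draw the fish silhouette.
    """
    for col in ("zhrg", "zbarriers", "zflow"):
        if col not in z_table.columns:
            raise ValueError(f"fit_fish_curves: missing column {col!r}")
    x = z_table["zhrg"].to_numpy(dtype=float)
    return (_quad_fit(x, z_table["zbarriers"].to_numpy(dtype=float)),
            _quad_fit(x, z_table["zflow"].to_numpy(dtype=float)))


def calibrate_flow_zones(z_table: pd.DataFrame, sdg_weight: float | None = None) -> FlowZoneConfig:
    """Calibrate the classifier on a standardized session table.

    Jointly least-squares fits zflow ~ 1 + zhrg + zhrg^2 + zsdg (unless a fixed
    ``sdg_weight`` is supplied, in which case only the quadratic is fitted) and
    sets cutpoints at the quartiles of the fitted predictions.
    """
    for col in ("zhrg", "zsdg", "zflow"):
        if col not in z_table.columns:
            raise ValueError(f"calibrate_flow_zones: missing column {col!r}")
    x = z_table["zhrg"].to_numpy(dtype=float)
    zsdg = z_table["zsdg"].to_numpy(dtype=float)
    y = z_table["zflow"].to_numpy(dtype=float)
    if len(x) < 4:
        raise ValueError("calibration requires >= 4 sessions")
    if sdg_weight is None:
        design = np.column_stack([np.ones_like(x), x, x * x, zsdg])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        c0, c1, c2, w = (float(b) for b in beta)
    else:
        fit = _quad_fit(x, y - sdg_weight * zsdg)
        c0, c1, c2, w = fit.c0, fit.c1, fit.c2, float(sdg_weight)
    preds = c0 + c1 * x + c2 * x * x + w * zsdg
    q1, q2, q3 = (float(np.quantile(preds, q)) for q in (0.25, 0.5, 0.75))
    if not (q1 < q2 < q3):  # degenerate predictions: spread ties deterministically
        q1, q2, q3 = q1 - 1e-9, q2, q3 + 1e-9
    return FlowZoneConfig(c0, c1, c2, w, (q1, q2, q3))


def classify_flow_zone(zhrg: float, zsdg: float, config: FlowZoneConfig) -> FlowZone:
    """Bin the predicted flow score into a zone; ties go to the higher zone."""
    score = config.score(zhrg, zsdg)
    if score < config.cutpoints[0]:
        return FlowZone.NO
    if score < config.cutpoints[1]:
        return FlowZone.LOW
    if score < config.cutpoints[2]:
        return FlowZone.MEDIUM
    return FlowZone.HIGH


def advise(label: FlowZone | str) -> Advice:
    """Teaching action for a zone: High -> none, Medium -> repeat once,
    Low -> repeat twice, No Flow -> break, then repeat twice."""
    zone = label if isinstance(label, FlowZone) else FlowZone.from_label(label)
    return Advice(zone, ADVICE_MAP[zone])


def label_distribution(labels: Iterable[FlowZone | str]) -> dict[FlowZone, float]:
    """Percentage share of each zone; all four zones present, summing to 100."""
    zones = [z if isinstance(z, FlowZone) else FlowZone.from_label(z) for z in labels]
    if not zones:
        raise ValueError("label_distribution: empty input")
    n = len(zones)
    return {z: 100.0 * zones.count(z) / n for z in FlowZone}


def classify_sessions(z_table: pd.DataFrame, config: FlowZoneConfig) -> list[FlowZone]:
    """Classify every session row of a standardized table."""
    return [classify_flow_zone(r.zhrg, r.zsdg, config) for r in z_table.itertuples()]
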
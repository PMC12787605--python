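"""Nonlinear balance analysis: Shannon entropy and lag-1 return-map trajectories.

Two complementary views of how a group's perceived task balance evolves:

- **Shannon entropy** of the session's Likert response distribution,
  ``H = -sum_i p_i log2 p_i`` with ``p_i = n_i / N`` (bits); lower H means the
  group's responses concentrate on fewer scale points.
- **Lag-1 (return-map) trajectories** of the session-mean balance series: each
  session mean x_t is plotted against x_{t+1} and consecutive points are joined
  into a flow line. The inferred attractor ("vortex") position is
  operationalized as the series centroid (mean, mean); the mean radius about the
  centroid and the total path length quantify how tightly the flow line orbits
  it — no dynamical-systems fitting is attempted.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .scales import LikertDistribution


def shannon_entropy(dist: LikertDistribution) -> float:
    """Shannon entropy (bits) of an ordinal response distribution.

    Zero-count scores contribute nothing (0 * log 0 = 0); the result lies in
    [0, log2(number of scale points)].
    """
    p = dist.probabilities
    p = p[p > 0]
    return float(-(p @ np.log2(p)))


def entropy_table(
    distributions: Mapping[tuple[str, int], LikertDistribution],
    excluded_sessions: Mapping[str, Sequence[int]] | None = None,
) -> pd.DataFrame:
    """Per-session entropies plus per-group means over non-excluded sessions.

    ``excluded_sessions`` maps a group to session numbers left out of that
    group's mean (e.g. sessions taught with different tooling); exclusions are
    recorded in the output's ``excluded`` column.
    """
    if not distributions:
        raise ValueError("entropy_table: no distributions")
    excluded_sessions = excluded_sessions or {}
    rows = [(g, s, shannon_entropy(d), s in set(excluded_sessions.get(g, ())))
            for (g, s), d in sorted(distributions.items())]
    df = pd.DataFrame(rows, columns=["group", "session", "h_bits", "excluded"])
    return df


def group_mean_entropy(
    table: pd.DataFrame,
    excluded_sessions: Mapping[str, Sequence[int]] | None = None,
) -> pd.DataFrame:
    """Per-group mean H over non-excluded sessions, with the n entering each mean.

    Accepts either the output of :func:`entropy_table` or any frame with
    ``group, session, h_bits`` columns (e.g. a published per-session H table).
    """
    excluded_sessions = excluded_sessions or {}
    out = []
    for g, sub in table.groupby("group", sort=True):
        keep = ~sub["session"].isin(set(excluded_sessions.get(g, ())))
        if "excluded" in sub.columns:
            keep &= ~sub["excluded"].astype(bool)
        vals = sub.loc[keep, "h_bits"].to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError(f"group_mean_entropy: no usable sessions for group {g!r}")
        out.append((g, float(vals.mean()), int(vals.size)))
    return pd.DataFrame(out, columns=["group", "mean_h", "n"])


@dataclass(frozen=True)
class Trajectory:
    """Ordered lag-1 point sequence with centroid and path statistics."""

    points: tuple[tuple[float, float], ...]
    centroid: tuple[float, float]
    mean_radius: float
    path_length: float


def lag1_trajectory(series) -> Trajectory:
    """Lag-1 return map of a series: points (x_t, x_{t+1}) in order.

    The centroid is (mean(series), mean(series)) — the inferred attractor
    position; mean_radius is the mean Euclidean distance of the points to the
    centroid; path_length the summed distance along consecutive points.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("lag1_trajectory requires a 1-D series of length >= 2")
    pts = np.column_stack([x[:-1], x[1:]])
    c = float(x.mean())
    radii = np.hypot(pts[:, 0] - c, pts[:, 1] - c)
    steps = np.hypot(np.diff(pts[:, 0]), np.diff(pts[:, 1]))
    return Trajectory(tuple(map(tuple, pts)), (c, c),
                      float(radii.mean()), float(steps.sum()))


def compare_trajectories(
    arm_a: Iterable[Trajectory],
    arm_b: Iterable[Trajectory],
    names: tuple[str, str] = ("a", "b"),
) -> pd.DataFrame:
    """Descriptive dispersion comparison of two collections of flow lines.

    Reports each arm's mean of mean_radius and of path_length, the a-b
    difference and the a/b ratio. Purely descriptive: no inferential claim.
    """
    arms = {names[0]: list(arm_a), names[1]: list(arm_b)}
    for nm, trajs in arms.items():
        if not trajs:
            raise ValueError(f"compare_trajectories: empty arm {nm!r}")
    rows = []
    for metric in ("mean_radius", "path_length"):
        va, vb = (float(np.mean([getattr(t, metric) for t in arms[nm]])) for nm in names)
        ratio = np.inf if vb == 0 and va > 0 else (np.nan if vb == 0 else va / vb)
        rows.append((metric, va, vb, va - vb, ratio))
    return pd.DataFrame(rows, columns=["metric", f"mean_{names[0]}", f"mean_{names[1]}",
                                       "difference", "ratio"])


def plot_lag1(trajectory: Trajectory, ax=None, label: str = "", mark_centroid: bool = True):
    """Lag-1 plane with vector-connected points and the centroid cross."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pts = np.asarray(trajectory.points)
    ax.plot(pts[:, 0], pts[:, 1], marker="o", label=label or None)
    for (x0, y0), (x1, y1) in zip(trajectory.points[:-1], trajectory.points[1:]):
        ax.annotate("", xy=(x1, y1), xytext=(x0, y0),
                    arrowprops=dict(arrowstyle="->", color="grey", lw=0.8))
    if mark_centroid:
        ax.plot(*trajectory.centroid, marker="x", color="black", markersize=10)
    ax.set_xlabel("x(t)")
    ax.set_ylabel("x(t+1)")
    if label:
        ax.legend()
    return ax
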
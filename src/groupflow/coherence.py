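"""Teacher-group agreement: Bland-Altman analysis with RMSE about the balance line.

Agreement between the teacher's recalled flow and the students' group-mean flow
is assessed on the mean-vs-difference plane. Differences are oriented
``teacher - group``, so a teacher who under-reports flow yields a negative bias.
Beyond the classical bias and limits of agreement, the root mean square of the
differences about the zero-difference (balance) line gives a single
scale-relative error figure: ``percent_error = rmse / scale_max * 100``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: two-sided 95% normal quantile used for the limits of agreement
DEFAULT_LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman summary for one group x scale pairing (score points)."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    rmse: float
    percent_error: float
    n: int


def bland_altman(
    pairs: Sequence[tuple[float, float]],
    scale_max: float,
    loa_multiplier: float = DEFAULT_LOA_MULTIPLIER,
) -> AgreementResult:
    """Agreement between paired (teacher, group_mean) scores on one scale.

    bias = mean(d) with d_i = teacher_i - group_i; sd_diff is the sample SD of
    the differences; limits of agreement are bias +/- ``loa_multiplier`` * sd_diff;
    rmse = sqrt(mean(d_i^2)) measures scatter about the balance (zero-difference)
    line and satisfies rmse^2 = bias^2 + (n-1)/n * sd_diff^2.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("bland_altman requires >= 2 (teacher, group_mean) pairs")
    if scale_max <= 0:
        raise ValueError(f"scale_max must be positive, got {scale_max}")
    d = arr[:, 0] - arr[:, 1]
    bias = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    rmse = float(np.sqrt(np.mean(d * d)))
    return AgreementResult(
        bias=bias,
        sd_diff=sd_diff,
        loa_low=bias - loa_multiplier * sd_diff,
        loa_high=bias + loa_multiplier * sd_diff,
        rmse=rmse,
        percent_error=rmse / scale_max * 100.0,
        n=len(d),
    )


def rmse_percent_error(rmse: float, scale_max: float) -> float:
    """Express an RMSE about the balance line as a percentage of the scale maximum."""
    if scale_max <= 0:
        raise ValueError(f"scale_max must be positive, got {scale_max}")
    if rmse < 0:
        raise ValueError(f"rmse must be >= 0, got {rmse}")
    return rmse / scale_max * 100.0


def plot_bland_altman(pairs, result: AgreementResult, ax=None, title: str = ""):
    """Mean-vs-difference plot with the balance line, bias and limits of agreement."""
    import matplotlib.pyplot as plt

    arr = np.asarray(pairs, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    means = arr.mean(axis=1)
    diffs = arr[:, 0] - arr[:, 1]
    ax.scatter(means, diffs, color="tab:blue")
    ax.axhline(0.0, linestyle="--", color="grey", label="balance line")
    ax.axhline(result.bias, color="tab:red", label=f"bias = {result.bias:.2f}")
    for y in (result.loa_low, result.loa_high):
        ax.axhline(y, linestyle=":", color="tab:red")
    ax.set_xlabel("mean of teacher and group scores")
    ax.set_ylabel("teacher - group difference")
    if title:
        ax.set_title(title)
    ax.legend()
    return ax
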
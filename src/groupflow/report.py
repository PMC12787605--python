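"""Statistical batteries, session-table construction and the end-to-end pipeline.

This module glues the stages together: it builds the per-session summary table
(one row per group x session with HRg, SDg, barriers, D1g, EduFlow % and the
flow-zone label), runs the Spearman correlation battery of HRg against the
questionnaire summaries, compares arms with a two-sample t and Cohen's d, and
drives the full simulate -> summarize -> analyze -> report pipeline.

Transcriptions of the published session-summary, balance and entropy tables
ship as package data and load through the ``load_*`` helpers; they are the
inputs for every statistic that is recomputable from print.
"""
from __future__ import annotations

import itertools
import json
import logging
import pathlib
from dataclasses import asdict, dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import cardio, coherence, easfe, nonlinear, scales, synthetic_data

logger = logging.getLogger("groupflow")

#: sessions excluded from per-group mean entropy: the design (5th-grade) cohort's
#: two Roblox Studio lessons, which the experimental design group never ran
ENTROPY_EXCLUSIONS = {"N5_1": (8, 9), "N5_2": (8, 9)}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# packaged fixture tables

def _load_fixture(name: str) -> pd.DataFrame:
    with resources.files("groupflow.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_control_sessions() -> pd.DataFrame:
    """Published control-arm session summaries (16 sessions, 2 groups)."""
    return _load_fixture("control_sessions.tsv")


def load_experimental_sessions() -> pd.DataFrame:
    """Published experimental-arm session summaries incl. flow-zone labels."""
    return _load_fixture("experimental_sessions.tsv")


def load_balance_by_session() -> pd.DataFrame:
    """Published per-session group mean/SD of perceived balance (A3, 9-point)."""
    return _load_fixture("balance_by_session.tsv")


def load_entropy_by_session() -> pd.DataFrame:
    """Published per-session Shannon entropy of the balance distribution (bits)."""
    return _load_fixture("entropy_by_session.tsv")


# ---------------------------------------------------------------------------
# correlation battery

@dataclass(frozen=True)
class CorrelationResult:
    variable_pair: tuple[str, str]
    rho: float
    p_value: float
    n: int


def spearman(x, y, names: tuple[str, str] = ("x", "y"), method: str = "approx") -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    Ranks use average-rank tie handling and rho is the Pearson correlation of
    the ranks. ``method="approx"`` (default) takes the p-value from the t
    approximation with n-2 degrees of freedom; ``method="exact"`` enumerates
    all permutations (allowed for n <= 10, practical below ~9) and reports the
    share with |rho| at least as large as observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("spearman: x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("spearman requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman: constant input")
    rho, p = stats.spearmanr(x, y)
    if method == "exact":
        if n > 10:
            raise ValueError("exact permutation p-value only supported for n <= 10")
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = np.sqrt((rx_c @ rx_c) * (ry_c @ ry_c))
        count = total = 0
        for perm in itertools.permutations(range(n)):
            r = (rx_c @ ry_c[list(perm)]) / denom
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = count / total
    elif method != "approx":
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(names, float(rho), float(p), n)


def spearman_battery(
    table: pd.DataFrame,
    independent: str,
    dependents: Sequence[str],
    method: str = "approx",
) -> tuple[list[CorrelationResult], list[str]]:
    """One Spearman result per dependent column against the independent column.

    Missing dependent columns are returned in the second element (reported,
    never silently skipped); a missing independent column is an error.
    """
    if independent not in table.columns:
        raise KeyError(f"independent column {independent!r} absent")
    results, missing = [], []
    for dep in dependents:
        if dep not in table.columns:
            missing.append(dep)
            logger.warning("spearman_battery: missing column %r", dep)
            continue
        results.append(spearman(table[independent], table[dep],
                                names=(independent, dep), method=method))
    return results, missing


def battery_table(results: Sequence[CorrelationResult], holm: bool = True) -> pd.DataFrame:
    """Tabulate a battery; optionally append a Holm-corrected p column.

    The published battery is uncorrected; the Holm column is an additional,
    clearly labelled safeguard, not a replication of print.
    """
    df = pd.DataFrame(
        [(r.variable_pair[0], r.variable_pair[1], r.rho, r.p_value, r.n) for r in results],
        columns=["independent", "dependent", "rho", "p_value", "n"])
    if holm and len(df):
        order = np.argsort(df["p_value"].to_numpy())
        m = len(df)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * df["p_value"].iloc[idx])
            adj[idx] = min(running, 1.0)
        df["p_holm_nonpaper"] = adj
    return df


# ---------------------------------------------------------------------------
# two-arm comparison

@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int
    t_statistic: float
    df: float
    cohen_d: float
    p_value: float


def compare_groups(values_a, values_b, welch: bool = False) -> GroupComparison:
    """Two-sample comparison: Student t (pooled variance; Welch optional),
    two-sided p, and Cohen's d with the pooled SD. Sample SDs throughout."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("compare_groups requires n >= 2 per group")
    sd_a, sd_b = a.std(ddof=1), b.std(ddof=1)
    if sd_a == 0 and sd_b == 0 and a.mean() != b.mean():
        raise ValueError("compare_groups: degenerate groups with zero variance")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    dof = a.size + b.size - 2 if not welch else float(res.df)
    pooled = np.sqrt(((a.size - 1) * sd_a**2 + (b.size - 1) * sd_b**2)
                     / (a.size + b.size - 2))
    d = 0.0 if pooled == 0 else float((a.mean() - b.mean()) / pooled)
    return GroupComparison(float(a.mean()), float(sd_a), float(b.mean()), float(sd_b),
                           a.size, b.size, float(res.statistic), float(dof), d,
                           float(res.pvalue))


# ---------------------------------------------------------------------------
# session table construction

SESSION_COLUMNS = ["group", "session", "hrg", "sdg", "barriers", "d1g",
                   "eduflow_percent", "easfe_label"]


def build_session_table(
    dataset: synthetic_data.StudyDataset,
    sdg_mode: str = "within_student",
    rr_bounds: tuple[float, float] = cardio.RR_BOUNDS_MS,
    eduflow_scale_max: float = scales.EDUFLOW_SCALE_MAX,
) -> pd.DataFrame:
    """One summary row per group x session from a generated (or parsed) study.

    For each session: artifact-filter the beat table, take the first 5-minute
    span's group statistics, and aggregate the questionnaire tables. Sessions
    lacking cardiac or questionnaire data are flagged via missing fields.
    """
    rows = []
    for group in dataset.groups:
        cfg = dataset.truth["configs"][group]
        for s in dataset.sessions(group):
            beats = dataset.beat_tables[(group, s)]
            beats, _ = cardio.filter_artifacts(beats, *rr_bounds)
            spans = cardio.segment_spans(beats, synthetic_data.session_start_time(s),
                                         cfg["span_length"])
            span0 = cardio.span_group_stats(spans[0], group, s, 0, sdg_mode) if 0 in spans else None
            summ = scales.summarize_session(
                group, s, dataset.fks_tables.get((group, s)),
                dataset.eduflow_tables.get((group, s)), span0, eduflow_scale_max)
            rows.append([group, s, summ.hrg, summ.sdg, summ.barriers, summ.d1g,
                         summ.eduflow_percent, summ.easfe_label])
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def fixture_session_table() -> pd.DataFrame:
    """The published session summaries of both arms, with an ``arm`` column."""
    ctrl = load_control_sessions().assign(arm="control")
    expe = load_experimental_sessions().assign(arm="experimental")
    return pd.concat([ctrl, expe], ignore_index=True)


# ---------------------------------------------------------------------------
# end-to-end pipeline

def _session_arm_tables(session_table: pd.DataFrame, arms: dict[str, list[str]]):
    for arm, groups in arms.items():
        yield arm, session_table[session_table["group"].isin(groups)].reset_index(drop=True)


def run_pipeline(config: dict, out: str | pathlib.Path | None = None) -> dict:
    """Execute simulate -> summarize -> analyze -> report and return the bundle.

    ``config`` keys: ``seed`` (int); optional ``control`` / ``experimental``
    cohort-field overrides; ``sdg_mode``. When ``out`` is given, all tables are
    written as delimited text plus a machine-readable ``results.json``.
    Deterministic given the seed.
    """
    stage = "simulate"
    try:
        seed = int(config.get("seed", 0))
        ctrl = synthetic_data.control_config(
            group_id="control", seed=seed, **config.get("control", {}))
        expe = synthetic_data.experimental_config(
            group_id="experimental", seed=seed + 1, **config.get("experimental", {}))
        dataset = synthetic_data.generate_study(ctrl, expe)

        stage = "summarize"
        session_table = build_session_table(dataset, config.get("sdg_mode", "within_student"))

        stage = "analyze"
        arms = {"control": ["control"], "experimental": ["experimental"]}
        batteries, fish, labels, agreements = {}, {}, {}, {}
        z_tables = {}
        for arm, tab in _session_arm_tables(session_table, arms):
            z = scales.z_score_table(tab)
            z_tables[arm] = z
            res, _ = spearman_battery(tab, "hrg", ["sdg", "barriers", "eduflow_percent"])
            batteries[arm] = battery_table(res)
            bfit, ffit = easfe.fit_fish_curves(z)
            fish[arm] = {"barriers": asdict(bfit), "flow": asdict(ffit)}
        zone_cfg = easfe.calibrate_flow_zones(z_tables["control"])
        exp_labels = easfe.classify_sessions(z_tables["experimental"], zone_cfg)
        session_table.loc[session_table["group"] == "experimental", "easfe_label"] = [
            z.value for z in exp_labels]
        labels = {z.value: pct for z, pct in easfe.label_distribution(exp_labels).items()}

        for (group, scale_name), sub in dataset.teacher_recall.groupby(["group", "scale"]):
            pairs = list(zip(sub["teacher_score"], sub["group_mean_score"]))
            scale_max = 91.0 if scale_name == "fks" else 112.0
            agreements[f"{group}:{scale_name}"] = asdict(
                coherence.bland_altman(pairs, scale_max))

        comparison = compare_groups(
            session_table.loc[session_table["group"] == "control", "eduflow_percent"],
            session_table.loc[session_table["group"] == "experimental", "eduflow_percent"])

        # nonlinear battery on the session-mean balance (A3) series per group
        trajectories = {}
        for group in dataset.groups:
            a3 = []
            for s in dataset.sessions(group):
                fks_tab = dataset.fks_tables[(group, s)]
                a3_vals = fks_tab.loc[fks_tab["item_id"].isin(scales.FKS_A_ITEMS["a3"]), "value"]
                a3.append(float(a3_vals.mean()))
            trajectories[group] = nonlinear.lag1_trajectory(a3)
        dispersion = nonlinear.compare_trajectories(
            [trajectories["control"]], [trajectories["experimental"]],
            names=("control", "experimental"))

        stage = "report"
        bundle = {
            "session_table": session_table,
            "batteries": batteries,
            "fish_fits": fish,
            "label_distribution": labels,
            "agreement": agreements,
            "comparison": asdict(comparison),
            "dispersion": dispersion,
            "truth": dataset.truth,
        }
        if out is not None:
            outdir = pathlib.Path(out)
            outdir.mkdir(parents=True, exist_ok=True)
            synthetic_data.write_study(dataset, outdir / "simulated")
            session_table.to_csv(outdir / "session_table.tsv", sep="\t", index=False)
            for arm, bt in batteries.items():
                bt.to_csv(outdir / f"battery_{arm}.tsv", sep="\t", index=False)
            dispersion.to_csv(outdir / "dispersion.tsv", sep="\t", index=False)
            results = {
                "label_distribution": labels,
                "agreement": agreements,
                "comparison": bundle["comparison"],
                "fish_fits": fish,
            }
            (outdir / "results.json").write_text(json.dumps(results, indent=2, sort_keys=True))
        return bundle
    except Exception as exc:
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc
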
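"""Correlation battery, two-arm comparison, session tables, pipeline plumbing."""
import itertools

import numpy as np
import pandas as pd
import pytest

from groupflow.report import (
    PipelineError,
    battery_table,
    build_session_table,
    compare_groups,
    fixture_session_table,
    load_control_sessions,
    load_experimental_sessions,
    run_pipeline,
    spearman,
    spearman_battery,
)

# the analysis stages need >= 4 sessions (quadratic fits, non-degenerate z-scores)
SMALL_ARMS = dict(
    control={"n_students": 3, "n_sessions": 6, "session_length": 60, "span_length": 60},
    experimental={"n_students": 3, "n_sessions": 6, "session_length": 60, "span_length": 60},
)
TINY_ARMS = dict(
    control={"n_students": 3, "n_sessions": 2, "session_length": 60, "span_length": 60},
    experimental={"n_students": 3, "n_sessions": 2, "session_length": 60, "span_length": 60},
)


def closed_form_rho(x, y):
    """Tie-free closed form: rho = 1 - 6 sum d^2 / (n (n^2 - 1))."""
    n = len(x)
    rx = np.argsort(np.argsort(x))
    ry = np.argsort(np.argsort(y))
    d = rx - ry
    return 1 - 6 * float(d @ d) / (n * (n * n - 1))


def test_monotone_series_give_unit_correlation():
    x = [1.0, 2, 3, 5, 8]
    assert spearman(x, [2.0, 3, 5, 8, 13]).rho == pytest.approx(1.0)
    assert spearman(x, [13.0, 8, 5, 3, 2]).rho == pytest.approx(-1.0)


def test_spearman_input_validation():
    with pytest.raises(ValueError):
        spearman([1, 2, 3], [1, 2])
    with pytest.raises(ValueError):
        spearman([1, 2], [2, 1])
    with pytest.raises(ValueError):
        spearman([1.0, 1.0, 1.0], [1, 2, 3])


def test_spearman_exhaustive_rank_oracle():
    """Closed-form oracle over all permutations for n = 4..6 (tie-free)."""
    for n in (4, 5, 6):
        x = np.arange(1.0, n + 1)
        for perm in itertools.permutations(range(n)):
            y = np.asarray(perm, dtype=float)
            assert spearman(x, y).rho == pytest.approx(closed_form_rho(x, y), abs=1e-12)


def test_exact_permutation_p_matches_enumeration():
    x = np.array([1.0, 2, 3, 4, 5])
    y = np.array([2.0, 1, 4, 3, 5])
    res = spearman(x, y, method="exact")
    obs = closed_form_rho(x, y)
    count = sum(abs(closed_form_rho(x, np.asarray(p, dtype=float))) >= abs(obs) - 1e-12
                for p in itertools.permutations(range(5)))
    assert res.p_value == pytest.approx(count / 120)
    with pytest.raises(ValueError):
        spearman(np.arange(12.0), np.arange(12.0)[::-1], method="exact")


def test_published_control_battery_reproduces():
    """The control-arm battery of HRg against SDg/barriers/flow lands on the
    printed coefficients 0.024 / 0.648 / -0.626 (p = 0.007 and 0.009 for the
    latter two)."""
    tab = load_control_sessions()
    results, missing = spearman_battery(tab, "hrg", ["sdg", "barriers", "eduflow_percent"])
    assert missing == []
    rhos = {r.variable_pair[1]: r for r in results}
    assert rhos["sdg"].rho == pytest.approx(0.024, abs=5e-4)
    assert rhos["barriers"].rho == pytest.approx(0.648, abs=5e-4)
    assert rhos["eduflow_percent"].rho == pytest.approx(-0.626, abs=5e-4)
    assert rhos["barriers"].p_value == pytest.approx(0.007, abs=5e-4)
    assert rhos["eduflow_percent"].p_value == pytest.approx(0.009, abs=5e-4)


def test_battery_reports_missing_columns():
    tab = load_control_sessions()
    results, missing = spearman_battery(tab, "hrg", ["sdg", "challenge"])
    assert missing == ["challenge"] and len(results) == 1
    with pytest.raises(KeyError):
        spearman_battery(tab, "heart_rate", ["sdg"])
    df = battery_table(results)
    assert "p_holm_nonpaper" in df.columns
    assert (df["p_holm_nonpaper"] >= df["p_value"] - 1e-12).all()


def test_self_correlation_is_unity():
    tab = load_control_sessions()
    results, _ = spearman_battery(tab, "hrg", ["hrg"])
    assert results[0].rho == pytest.approx(1.0)


def test_identical_groups_compare_to_zero():
    x = [1.0, 2, 3, 4]
    res = compare_groups(x, x)
    assert res.t_statistic == 0.0 and res.cohen_d == 0.0


def test_published_flow_contrast_moments():
    """Arm-level flow contrast: control M=61.95, SD=6.42; experimental
    M=72.92, SD=7.32 (sample SDs)."""
    res = compare_groups(load_control_sessions()["eduflow_percent"],
                         load_experimental_sessions()["eduflow_percent"])
    assert res.mean_a == pytest.approx(61.95, abs=0.005)
    assert res.sd_a == pytest.approx(6.42, abs=0.005)
    assert res.mean_b == pytest.approx(72.92, abs=0.005)
    assert res.sd_b == pytest.approx(7.32, abs=0.005)
    assert res.df == 30
    assert 0 < res.p_value < 0.001


def test_compare_groups_symmetric_up_to_sign(rng):
    a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
    fwd, rev = compare_groups(a, b), compare_groups(b, a)
    assert rev.t_statistic == pytest.approx(-fwd.t_statistic)
    assert rev.cohen_d == pytest.approx(-fwd.cohen_d)
    assert rev.p_value == pytest.approx(fwd.p_value)


def test_effect_size_recovers_standardized_shift():
    """Monte-Carlo oracle: mean Cohen's d over 500 seeds within 3 SE of the
    true delta/sigma."""
    ds = []
    for seed in range(500):
        rng = np.random.default_rng(seed)
        a = rng.normal(55.0, 10.0, 16)
        b = rng.normal(50.0, 10.0, 16)
        ds.append(compare_groups(a, b).cohen_d)
    ds = np.asarray(ds)
    se = ds.std(ddof=1) / np.sqrt(len(ds))
    assert abs(ds.mean() - 0.5) < 3 * se + 0.02  # + small-sample bias bound


def test_fixture_session_table_round_trips():
    tab = fixture_session_table()
    assert len(tab) == 32
    assert set(tab["arm"]) == {"control", "experimental"}
    ctrl = tab[tab["arm"] == "control"].drop(columns=["arm", "d1g", "easfe_label"])
    pd.testing.assert_frame_equal(ctrl.reset_index(drop=True), load_control_sessions())


def test_synthetic_session_table_shape():
    from groupflow.synthetic_data import control_config, experimental_config, generate_study

    ds = generate_study(
        control_config(group_id="c", seed=1, **TINY_ARMS["control"]),
        experimental_config(group_id="e", seed=2, **TINY_ARMS["experimental"]))
    tab = build_session_table(ds)
    assert len(tab) == 2 * 2
    assert tab["barriers"].notna().all()
    assert tab["hrg"].notna().all()


def test_pipeline_deterministic_given_seed():
    cfg = {"seed": 3, **SMALL_ARMS}
    t1 = run_pipeline(cfg)["session_table"]
    t2 = run_pipeline(cfg)["session_table"]
    pd.testing.assert_frame_equal(t1, t2)


def test_pipeline_failure_names_stage():
    with pytest.raises(PipelineError, match="simulate"):
        run_pipeline({"seed": 1, "control": {"n_students": 1}})


def test_no_silent_nans_in_report_bundle():
    bundle = run_pipeline({"seed": 5, **SMALL_ARMS})
    for arm, bt in bundle["batteries"].items():
        assert bt["p_value"].between(0, 1, inclusive="right").all()
        assert bt["rho"].abs().le(1).all()
        assert not bt[["rho", "p_value"]].isna().any().any()
    assert not np.isnan(bundle["comparison"]["p_value"])


def test_cli_simulate_and_missing_config(tmp_path):
    from click.testing import CliRunner

    from groupflow.cli import main

    cfg = tmp_path / "cfg.yaml"
    cfg.write_text(
        "control: {n_students: 3, n_sessions: 2, session_length: 60, span_length: 60}\n"
        "experimental: {n_students: 3, n_sessions: 2, session_length: 60, span_length: 60}\n")
    runner = CliRunner()
    res = runner.invoke(main, ["simulate", "--config", str(cfg),
                               "--out", str(tmp_path / "out"), "--seed", "4"])
    assert res.exit_code == 0, res.output
    assert (tmp_path / "out" / "beats.tsv").exists()
    res = runner.invoke(main, ["simulate", "--config", str(tmp_path / "nope.yaml"),
                               "--out", str(tmp_path / "out2")])
    assert res.exit_code != 0
    assert "nope.yaml" in res.output
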
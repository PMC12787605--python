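"""Generator contracts: determinism, scale closure, moment targeting, couplings."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from groupflow import cardio, coherence, scales
from groupflow.synthetic_data import (
    CohortConfig,
    ConfigError,
    control_config,
    experimental_config,
    generate_beat_streams,
    generate_likert_responses,
    generate_study,
    generate_teacher_recall,
    scale_spec,
    session_hr_offsets,
)


@pytest.mark.parametrize("field,value", [
    ("n_students", 1),
    ("rr_ar1_coeff", 1.0),
    ("hr_within_student_sd", -1.0),
    ("span_length", 7),            # does not divide session_length
    ("teacher_noise_sd", -0.5),
])
def test_invalid_config_reports_field_name(field, value):
    kw = {"session_length": 120, "span_length": 60, field: value}
    with pytest.raises(ConfigError) as exc:
        CohortConfig(**kw)
    assert field.split("_")[0] in str(exc.value) or field in str(exc.value)


def test_bad_likert_target_rejected():
    with pytest.raises(ConfigError, match="a3"):
        CohortConfig(likert_targets={"a3": (12.0, 1.0)})


def test_zero_noise_beat_streams_are_constant():
    cfg = CohortConfig(n_students=3, n_sessions=1, session_length=120, span_length=60,
                       hr_within_student_sd=0.0, rr_ar1_coeff=0.0, seed=3)
    df = generate_beat_streams(cfg, 0)
    for _, sub in df.groupby("student_id"):
        assert sub["bpm"].nunique() == 1
        assert sub["rr_ms"].nunique() == 1


def test_one_hour_session_has_3600_samples_and_12_spans():
    cfg = CohortConfig(n_students=2, n_sessions=1, seed=5)
    df = generate_beat_streams(cfg, 0)
    counts = df.groupby("student_id").size()
    assert (counts == 3600).all()
    spans = cardio.segment_spans(df, int(df["unix_time_s"].min()), 300)
    assert len(spans) == 12
    assert all(len(v) == 2 * 300 for v in spans.values())


def test_identical_seed_gives_bit_identical_dataset(tiny_config):
    d1 = generate_beat_streams(tiny_config, 0)
    d2 = generate_beat_streams(tiny_config, 0)
    pd.testing.assert_frame_equal(d1, d2)


def test_adding_sessions_never_perturbs_earlier_data():
    base = CohortConfig(n_students=3, n_sessions=2, session_length=60, span_length=60, seed=11)
    more = CohortConfig(n_students=3, n_sessions=5, session_length=60, span_length=60, seed=11)
    pd.testing.assert_frame_equal(generate_beat_streams(base, 1),
                                  generate_beat_streams(more, 1))
    spec = scale_spec("a3", 5.1, 1.1)
    pd.testing.assert_frame_equal(generate_likert_responses(base, spec, 0),
                                  generate_likert_responses(more, spec, 0))


def test_group_mean_heart_rate_recovers_baseline_over_seeds():
    """Monte-Carlo oracle: realized group-mean bpm averages to the configured
    baseline across seeds (within 3 empirical standard errors)."""
    means = []
    for seed in range(200):
        cfg = CohortConfig(n_students=14, n_sessions=1, session_length=60,
                           span_length=60, hr_baseline_mean=85.0,
                           hr_between_student_sd=5.0, seed=seed)
        df = generate_beat_streams(cfg, 0)
        means.append(df.groupby("student_id")["bpm"].mean().mean())
    means = np.asarray(means)
    se = means.std(ddof=1) / np.sqrt(len(means))
    assert abs(means.mean() - 85.0) < 3 * se + 0.15  # + first-order 1/RR bias bound


def test_likert_point_mass_targets():
    cfg = CohortConfig(n_students=10, seed=2)
    top = generate_likert_responses(cfg, scale_spec("a3", 9.0, 0.0), 0)
    assert (top["value"] == 9).all()
    mid = generate_likert_responses(cfg, scale_spec("a1", 5.0, 0.0), 0)
    assert (mid["value"] == 5).all()
    dist, _, sd = scales.likert_histogram(mid["value"], (1, 9))
    assert sd == 0.0


def test_likert_sample_mean_converges_to_target():
    """Law-of-large-numbers check at n = 10,000 responses, one seed."""
    cfg = CohortConfig(n_students=10_000 // 9, seed=13)
    df = generate_likert_responses(cfg, scale_spec("a3", 5.0, 1.1), 0)
    vals = df["value"].to_numpy()
    assert abs(vals.mean() - 5.0) < 0.05
    assert abs(vals.std(ddof=1) - 1.1) < 0.1


@given(mean=st.floats(1.5, 8.5), sd=st.floats(0.0, 2.0))
def test_likert_scale_closure(mean, sd):
    """Every generated response is an integer inside the declared scale."""
    cfg = CohortConfig(n_students=5, seed=17)
    df = generate_likert_responses(cfg, scale_spec("a2", mean, round(sd, 3)), 0)
    assert df["value"].between(1, 9).all()
    assert (df["value"] == df["value"].astype(int)).all()


def test_teacher_recall_noise_free_cases():
    quiet = CohortConfig(teacher_bias=0.0, teacher_noise_sd=0.0, seed=23)
    assert generate_teacher_recall(50.0, quiet, (16, 112)) == 50.0
    biased = CohortConfig(teacher_bias=-3.0, teacher_noise_sd=0.0, seed=23)
    pairs = [(generate_teacher_recall(50.0 + s, biased, (16, 112), s), 50.0 + s)
             for s in range(8)]
    result = coherence.bland_altman(pairs, scale_max=112)
    assert result.bias == pytest.approx(-3.0)
    assert result.sd_diff == pytest.approx(0.0)


def test_teacher_bias_recovered_by_agreement_analysis():
    """Monte-Carlo oracle: mean Bland-Altman bias over 500 seeds within 3 SE of
    the configured teacher bias."""
    biases = []
    for seed in range(500):
        cfg = CohortConfig(teacher_bias=-2.0, teacher_noise_sd=1.0, seed=seed)
        pairs = [(generate_teacher_recall(60.0, cfg, (16, 112), s), 60.0) for s in range(8)]
        biases.append(coherence.bland_altman(pairs, scale_max=112).bias)
    biases = np.asarray(biases)
    se = biases.std(ddof=1) / np.sqrt(len(biases))
    assert abs(biases.mean() - (-2.0)) < 3 * se


def test_zero_coupling_zero_noise_sessions_identical():
    kw = dict(n_students=3, n_sessions=3, session_length=60, span_length=60,
              hr_within_student_sd=0.0, rr_ar1_coeff=0.0, hr_between_student_sd=0.0,
              session_hr_offset_range=(0.0, 0.0), flow_hr_coupling=0.0,
              barriers_hr_coupling=0.0, teacher_noise_sd=0.0)
    targets = {k: (m, 0.0) for k, (m, _) in
               CohortConfig().likert_targets.items()}
    ds = generate_study(
        control_config(group_id="c", seed=1, likert_targets=targets, **kw),
        experimental_config(group_id="e", seed=2, likert_targets=targets, **kw))
    ref = ds.fks_tables[("c", 0)].drop(columns="session")
    for s in (1, 2):
        pd.testing.assert_frame_equal(
            ds.fks_tables[("c", s)].drop(columns="session").reset_index(drop=True), ref)
    # degenerate series: the correlation battery must refuse, not emit NaN
    hrg = [ds.beat_tables[("c", s)]["bpm"].mean() for s in range(3)]
    with pytest.raises(ValueError, match="constant"):
        from groupflow.report import spearman
        spearman(hrg, [1.0, 2.0, 3.0])


def _session_flow_and_hr(config):
    offsets = session_hr_offsets(config)
    hrg, flow = [], []
    for s in range(config.n_sessions):
        beats = generate_beat_streams(config, s, float(offsets[s]))
        hrg.append(beats.groupby("student_id")["bpm"].mean().mean())
        from groupflow.synthetic_data import _session_targets, _standardized_offset
        targets = _session_targets(config, _standardized_offset(config, float(offsets[s])))
        df = generate_likert_responses(config, scale_spec("d1", *targets["d1"]), s)
        flow.append(df["value"].mean())
    return np.asarray(hrg), np.asarray(flow)


@pytest.mark.parametrize("sign", [-1.0, 1.0])
def test_flow_hr_coupling_sign_recovered(sign):
    """Monte-Carlo oracle: with |coupling| at the documented detectability
    threshold and above, Spearman(HRg, flow) recovers the configured sign in
    >= 95% of seeds (16 sessions, moderate noise)."""
    from scipy.stats import spearmanr

    hits = 0
    n_seeds = 200
    for seed in range(n_seeds):
        cfg = CohortConfig(arm="control", n_students=6, n_sessions=16,
                           session_length=30, span_length=30,
                           flow_hr_coupling=sign * 0.6, seed=seed)
        hrg, flow = _session_flow_and_hr(cfg)
        rho = spearmanr(hrg, flow).statistic
        hits += (np.sign(rho) == sign)
    assert hits >= 0.95 * n_seeds


def test_generate_study_rejects_conflicting_session_counts():
    with pytest.raises(ConfigError, match="session counts"):
        generate_study(control_config(n_sessions=8, session_length=3600),
                       experimental_config(n_sessions=9, session_length=3600))


def test_write_study_round_trips_beat_table(tmp_path, tiny_config):
    from groupflow.synthetic_data import experimental_config, write_study

    ds = generate_study(
        tiny_config,
        experimental_config(group_id="e", n_students=4, n_sessions=2,
                            session_length=120, span_length=60, seed=8))
    write_study(ds, tmp_path)
    parsed, rep = cardio.parse_beat_table(tmp_path / "beats.tsv")
    assert rep.n_skipped == 0
    total = sum(len(v) for v in ds.beat_tables.values())
    assert rep.n_parsed == total
    assert (tmp_path / "truth.yaml").exists()
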
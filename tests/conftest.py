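import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from groupflow import synthetic_data

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def tiny_config():
    """A short, cheap cohort: 4 students, 2 sessions of 2 spans."""
    return synthetic_data.CohortConfig(
        arm="control", n_students=4, n_sessions=2,
        session_length=120, span_length=60, seed=7)


@pytest.fixture
def beat_frame(tiny_config):
    return synthetic_data.generate_beat_streams(tiny_config, 0)


def make_beat_frame(times, bpm=None, rr=None, student="s00", group="g", session=0):
    """Hand-build a beat table for oracle tests."""
    times = np.asarray(times)
    if rr is None:
        rr = np.full(times.size, 750.0)
    if bpm is None:
        bpm = 60000.0 / np.asarray(rr, dtype=float)
    return pd.DataFrame({
        "group": group, "session": session, "student_id": student,
        "unix_time_s": times, "bpm": bpm, "rr_ms": rr,
    })
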
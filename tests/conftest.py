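import numpy as np
import pytest

from hranomaly import AnomalySpec, HRSeries, NightProfile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_profile():
    return NightProfile(seed=7)


@pytest.fixture
def default_spec():
    return AnomalySpec(seed=8)


@pytest.fixture
def quiet_profile():
    """A short, deterministic night: no drift, no shifts, no noise."""
    return NightProfile(
        duration_minutes=120,
        interval_seconds=60,
        baseline_bpm=60.0,
        drift_amplitude_bpm=0.0,
        n_stage_shifts=0,
        noise_sd_bpm=0.0,
        seed=1,
    )


def make_series(bpm, interval=60, participant="T", night=0):
    bpm = np.asarray(bpm, dtype=float)
    t = np.arange(len(bpm), dtype=float) * interval
    return HRSeries(participant_id=participant, night_index=night, t=t, bpm=bpm)


@pytest.fixture
def series_factory():
    return make_series
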
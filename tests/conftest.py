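import numpy as np
import pytest

from neuroorganoleptics import AcquisitionConfig, ChannelCalibration
from neuroorganoleptics.ecg_hrv import detect_rpeaks, preprocess
from neuroorganoleptics.sensor_transfer import ecg_to_volts
from neuroorganoleptics.synthetic_session import CohortConfig, simulate_cohort, simulate_rr, synthesize_ecg


@pytest.fixture(scope="session")
def cal() -> ChannelCalibration:
    return ChannelCalibration()


@pytest.fixture(scope="session")
def acq() -> AcquisitionConfig:
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def clean_ecg(acq, cal):
    """A clean 62-s synthetic ECG with its ground truth and detections."""
    rr, beat_times = simulate_rr(61.0, 60.0, 300.0, 300.0, seed=11)
    beat_times = beat_times + 0.5  # keep the first beat clear of the edge
    stream, n_sat = synthesize_ecg(
        beat_times=beat_times, config=acq, amplitude_mv=1.0,
        duration=62.0, noise_mv=0.01, seed=12,
    )
    assert n_sat == 0
    filtered = preprocess(ecg_to_volts(stream, cal), acq.sampling_rate)
    peaks = detect_rpeaks(filtered, acq.sampling_rate)
    return {
        "stream": stream,
        "filtered": filtered,
        "peaks": peaks,
        "beat_times": beat_times,
        "fs": acq.sampling_rate,
    }


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """A two-product, one-subject cohort written to disk (fast to analyse)."""
    out = tmp_path_factory.mktemp("cohort")
    cfg = CohortConfig(
        n_subjects=1, n_sessions=1, products=("A", "B"),
        score_means={"A": 8.0, "B": 4.0}, seed=21,
    )
    sessions, table = simulate_cohort(cfg, out)
    return {"dir": out, "sessions": sessions, "table": table, "config": cfg}
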
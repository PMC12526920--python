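import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cecgkit as ck

settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def template():
    return ck.ECGTemplate.default()


@pytest.fixture(scope="session")
def clean_60bpm_recording(template):
    """60-s clean reference ECG at a metronomic 60 bpm, preprocessed to 125 Hz."""
    truth = ck.gen_rr_series(ck.RRSeriesSpec(mean_hr=60, hr_sd=0, duration=60),
                             seed=11)
    raw = ck.synth_clean_ecg(truth, template, duration=61.0)
    return ck.preprocess_recording(raw), truth


def make_section(mean_hr: float, seed: int = 3, n_seconds: float = 15.0):
    """One preprocessed constant-HR section at 125 Hz (helper, not a fixture)."""
    truth = ck.gen_rr_series(
        ck.RRSeriesSpec(mean_hr=mean_hr, hr_sd=0, duration=n_seconds + 3), seed=seed)
    raw = ck.synth_clean_ecg(truth, duration=n_seconds + 3)
    proc = ck.preprocess_recording(raw)
    return proc.samples[: int(n_seconds * proc.fs)], proc.fs, truth
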
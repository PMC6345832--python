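import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wmosc import EpochSet, make_layout

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def layout16():
    return make_layout(16, 0.70)


@pytest.fixture(scope="session")
def layout4():
    # radius exceeds the disc diameter: complete graph
    return make_layout(4, 2.1)


def make_epochs(
    data: np.ndarray,
    sfreq: float = 250.0,
    t0: float = -1.2,
    sample_onset: float = -0.5,
    condition=None,
    subject_id: str = "S00",
) -> EpochSet:
    n_trials, n_ch, _ = data.shape
    if condition is None:
        condition = np.array(["a"] * n_trials)
    return EpochSet(
        data=data,
        sampling_rate=sfreq,
        t0=t0,
        sample_onset=sample_onset,
        condition=np.asarray(condition),
        subject_id=subject_id,
        channel_names=tuple(f"C{i:02d}" for i in range(n_ch)),
    )


def sinusoid_epochs(freq, amp=1.0, n_trials=1, n_ch=1, sfreq=250.0, duration=4.0, phase=0.0):
    t = np.arange(int(duration * sfreq) + 1) / sfreq
    x = amp * np.cos(2 * np.pi * freq * t + phase)
    data = np.tile(x, (n_trials, n_ch, 1))
    return make_epochs(data, sfreq=sfreq, t0=-1.0, sample_onset=-0.5)
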
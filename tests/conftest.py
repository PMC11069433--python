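import numpy as np
import pytest

from oddmark.epochs import TrialEpochs
from oddmark.montage import SensorMontage, default_montage


@pytest.fixture(scope="session")
def montage64():
    return default_montage()


@pytest.fixture(scope="session")
def small_montage(montage64):
    """Eight-channel subset (keeps FCz/Oz/Pz topography anchors and mastoids)."""
    names = ["Fz", "FCz", "Cz", "Pz", "Oz", "P8", "M1", "M2"]
    pos = np.array([montage64.positions[montage64.index(n)] for n in names])
    return SensorMontage(names, pos)


def make_epochs(montage, data, fs=1000.0, tmin_ms=-100.0, condition="A",
                category=None, subject_id="S00"):
    n_trials, _, n_t = data.shape
    if category is None:
        category = np.array(["standard"] * (n_trials - n_trials // 2)
                            + ["deviant"] * (n_trials // 2), dtype=object)
    time_ms = tmin_ms + 1000.0 / fs * np.arange(n_t)
    return TrialEpochs(data=data, time_ms=time_ms, sampling_rate_hz=fs,
                       condition=condition, category=np.asarray(category, object),
                       subject_id=subject_id, montage=montage)


@pytest.fixture
def epochs_factory(small_montage):
    def _make(data, **kw):
        return make_epochs(small_montage, data, **kw)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
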
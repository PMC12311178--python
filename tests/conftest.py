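import numpy as np
import pytest

from vnsloop import ecg_synth, hr_dsp


@pytest.fixture(scope="session")
def const60_ecg():
    """Noiseless 60-bpm ECG, 60 s at 200 Hz."""
    profile = ecg_synth.make_hr_profile([(0, 60)])
    return ecg_synth.synthesize_ecg(profile, 60, 200)


@pytest.fixture(scope="session")
def filter_spec():
    return hr_dsp.FilterSpec()


@pytest.fixture(scope="session")
def stepped_profile():
    """Step profile aligned to the 5-s analysis grid."""
    return ecg_synth.make_hr_profile([(0, 80), (20, 96), (40, 72)])


def series_of(values, window=5.0):
    values = np.asarray(values, dtype=float)
    return hr_dsp.HRSeries(np.arange(len(values)) * window, values, window)


@pytest.fixture
def make_series():
    return series_of
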
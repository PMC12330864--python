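import numpy as np
import pytest

from fluideeg.core import MultichannelSeries
from fluideeg.synthetic import gen_iid_gaussian, gen_microstate_hmm, gen_var1


@pytest.fixture(scope="session")
def iid_eeg():
    """Small temporally independent multichannel series."""
    return gen_iid_gaussian(10, 3000, seed=11)


@pytest.fixture(scope="session")
def hmm_eeg():
    """Markov-switching topography series with known ground truth."""
    return gen_microstate_hmm(4, 12, 6000, mean_dwell=10, noise_sd=0.3, seed=7)


@pytest.fixture(scope="session")
def ar_eeg():
    """Persistent AR(1) series."""
    return gen_var1(6, 5000, persistence=0.9, seed=13)


@pytest.fixture
def make_series():
    """Factory for small hand-built MultichannelSeries."""

    def _make(values, rate=25.0, **meta):
        return MultichannelSeries(values=np.asarray(values, dtype=float), rate=rate, meta=meta)

    return _make
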
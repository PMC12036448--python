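import numpy as np
import pytest

from gluconet import Spectrum, SynthConfig, make_labeled_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def config():
    return SynthConfig(seed=7, n_per_class=10)


@pytest.fixture
def labeled_dataset(config):
    return make_labeled_dataset(config)


def random_spectrum(rng, scan_id="s", polarity="negative", n_peaks=None,
                    mz_range=(50.0, 400.0), precursor_range=(150.0, 700.0)):
    """Random centroided spectrum helper shared across test modules."""
    n = int(n_peaks if n_peaks is not None else rng.integers(3, 12))
    return Spectrum(
        scan_id=scan_id,
        precursor_mz=float(rng.uniform(*precursor_range)),
        polarity=polarity,
        mz=rng.uniform(*mz_range, size=n),
        intensity=rng.uniform(1.0, 100.0, size=n),
    )
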
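import numpy as np
import pytest

from ofbcnn import BackboneConfig, TrialSet


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_separable_trialset(n_per_class=20, n_channels=6, fs=125.0, duration_s=1.0,
                            seed=0, snr=2.0):
    """Two-class toy set: class 0 carries a 10 Hz rhythm on the first half
    of the channels, class 1 a 20 Hz rhythm on the second half."""
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * fs))
    t = np.arange(n_samples) / fs
    trials, labels = [], []
    for c in (0, 1):
        freq = 10.0 if c == 0 else 20.0
        ch = slice(0, n_channels // 2) if c == 0 else slice(n_channels // 2, n_channels)
        for _ in range(n_per_class):
            x = rng.standard_normal((n_channels, n_samples))
            phase = rng.uniform(0, 2 * np.pi)
            x[ch] += snr * np.sin(2 * np.pi * freq * t + phase)
            trials.append(x)
            labels.append(c)
    order = rng.permutation(len(trials))
    X = np.stack(trials)[order]
    y = np.array(labels)[order]
    return TrialSet.from_arrays(X, y, np.zeros(len(y), int), fs, class_count=2)


@pytest.fixture(scope="session")
def separable_trialset():
    return make_separable_trialset()


@pytest.fixture(scope="session")
def tiny_backbone_config():
    """Shallow config sized for 1 s of 125 Hz data in fast unit tests."""
    return BackboneConfig.shallow(
        n_temporal_filters=4,
        n_spatial_filters=4,
        temporal_kernel_len=13,
        pool_len=25,
        pool_stride=5,
        dropout_rate=0.25,
    )
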
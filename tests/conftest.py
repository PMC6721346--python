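import numpy as np
import pytest
from hypothesis import settings

from mientropic import SynthConfig, generate_dataset

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Strong-contrast dataset at reduced size for unit-level checks."""
    cfg = SynthConfig(n_trials_per_class=4, seed=7)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def one_trial(small_dataset):
    return small_dataset.trials[0]


def two_tone(f1=20.0, f2=4.0, fs=250.0, n=2000):
    t = np.arange(n) / fs
    return np.sin(2 * np.pi * f1 * t) + np.sin(2 * np.pi * f2 * t)


def band_power_fraction(x, fs, low, high):
    """Fraction of FFT power inside [low, high] Hz (independent oracle)."""
    spec = np.abs(np.fft.rfft(np.asarray(x))) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    total = spec.sum()
    return spec[(freqs >= low) & (freqs <= high)].sum() / total


def apen_bruteforce(x, m, r):
    """Direct per-template enumeration of the match counts.

    Independent of the package's incremental Chebyshev structure: for every
    template i the distances to all j are recomputed from the raw embedded
    vectors.
    """
    x = np.asarray(x, dtype=float)
    N = x.size

    def phi(mm):
        n = N - mm + 1
        emb = np.stack([x[i : i + mm] for i in range(n)])
        total = 0.0
        for i in range(n):
            d = np.max(np.abs(emb - emb[i]), axis=1)
            total += np.log(np.count_nonzero(d <= r) / n)
        return total / n

    return phi(m) - phi(m + 1)
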
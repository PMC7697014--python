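import numpy as np
import pytest

from lungsound_dx.audio_io import AudioRecording


@pytest.fixture
def tone():
    """Factory for pure-tone recordings."""

    def _make(freq: float, fs: float = 8000.0, duration: float = 1.0, label=None):
        t = np.arange(int(duration * fs)) / fs
        return AudioRecording(np.sin(2 * np.pi * freq * t), fs, label=label)

    return _make


@pytest.fixture
def noise_rec():
    """Factory for seeded white-noise recordings."""

    def _make(fs: float = 8000.0, duration: float = 1.0, seed: int = 0, scale: float = 1.0):
        rng = np.random.default_rng(seed)
        n = int(duration * fs)
        return AudioRecording(scale * rng.standard_normal(n), fs)

    return _make


def band_energy_fraction(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    """Fraction of periodogram power inside [lo, hi] — shared spectral oracle."""
    from scipy.signal import periodogram

    f, p = periodogram(x, fs=fs)
    total = np.sum(p)
    if total == 0:
        return 0.0
    return float(np.sum(p[(f >= lo) & (f <= hi)]) / total)
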
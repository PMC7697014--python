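"""The 116-dimensional acoustic descriptor of a lung-sound recording.

Four groups, concatenated in a fixed order:

* 19 time-domain statistics (moments, peak ratios, energies, zero-crossing
  derived average frequency and jitter);
* 12 spectral statistics of the one-sided DFT magnitude (moments, centroid,
  spread, flux, roll-off, flatness, crest, decrease, slope);
* 26 cepstral coefficients: 13 MFCC (Mel-warped filter bank, log, DCT-II)
  and 13 GFCC (64-channel gammatone bank on the ERB scale, 100 Hz envelope
  frames, cube-root compression, DCT-II);
* 59 texture features: the normalized uniform local-binary-pattern
  histogram (8 neighbors, radius 1) of the dB spectrogram.

Conventions that matter for reproducibility
-------------------------------------------
Mel warping uses Mel(f) = 2595 log10(1 + f/700).  The ERB-rate scale is
ERB(f) = A log10(1 + 0.00437 f) with A = 1000 ln(10) / (24.7 * 4.37) ~ 21.4.
Spectral moments use population (1/n) normalization of the magnitude
spectrum; spectral kurtosis is reported as excess (Gaussian -> 0).  Log
energies are base 10.  The LBP bit for each neighbor is set when
neighbor >= center, bits ordered counter-clockwise starting at the east
neighbor; the 58 uniform 8-bit codes map to bins 0..57 in increasing code
order and all non-uniform codes pool into bin 58.

Ratio features with a zero denominator (constant or silent input) are
returned as 0 with a warning rather than raising, so batch extraction over
heterogeneous recordings never aborts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, rfft, rfftfreq
from scipy.signal import get_window, lfilter, stft
from scipy.signal import gammatone as _gammatone_design
from scipy.stats import kurtosis as _kurtosis, skew as _skew

from .audio_io import AudioRecording, FeatureTable

__all__ = [
    "SpectrogramParams",
    "FeatureVector",
    "TIME_FEATURE_NAMES",
    "SPECTRAL_FEATURE_NAMES",
    "CEPSTRAL_FEATURE_NAMES",
    "TEXTURE_FEATURE_NAMES",
    "ALL_FEATURE_NAMES",
    "mel_scale",
    "erb_scale",
    "time_features",
    "spectral_features",
    "mfcc",
    "gfcc",
    "lbp_texture",
    "extract_all",
    "extract_table",
]

_EPS = 1e-10


@dataclass(frozen=True)
class SpectrogramParams:
    """Short-time spectrogram geometry for the texture (and flux) features."""

    window_length: int = 20
    hop: int = 10
    window: str = "hann"

    def __post_init__(self) -> None:
        if self.hop < 1 or self.window_length < 2:
            raise ValueError("window_length >= 2 and hop >= 1 required")
        if self.hop > self.window_length:
            raise ValueError("hop larger than window_length leaves gaps")

    @property
    def overlap(self) -> int:
        return self.window_length - self.hop


@dataclass
class FeatureVector:
    """Named, ordered feature values with a group tag per entry."""

    values: np.ndarray
    names: list[str]
    groups: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if not (len(self.values) == len(self.names) == len(self.groups)):
            raise ValueError("values, names and groups must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


TIME_FEATURE_NAMES = [
    "mean",
    "std",
    "skewness",
    "kurtosis",
    "peak_to_peak",
    "rms",
    "crest_factor",
    "shape_factor",
    "impulse_factor",
    "margin_factor",
    "energy",
    "peak_to_rms",
    "root_sum_squares",
    "shannon_energy",
    "log_energy",
    "mean_abs_dev",
    "median_abs_dev",
    "average_frequency",
    "jitter",
]

SPECTRAL_FEATURE_NAMES = [
    "s_mean",
    "s_std",
    "s_skewness",
    "s_kurtosis",
    "s_centroid",
    "s_flux",
    "s_rolloff",
    "s_flatness",
    "s_crest",
    "s_decrease",
    "s_slope",
    "s_spread",
]

CEPSTRAL_FEATURE_NAMES = [f"mfcc_{i}" for i in range(1, 14)] + [
    f"gfcc_{i}" for i in range(1, 14)
]

TEXTURE_FEATURE_NAMES = [f"lbp_{i}" for i in range(59)]

ALL_FEATURE_NAMES = (
    TIME_FEATURE_NAMES + SPECTRAL_FEATURE_NAMES + CEPSTRAL_FEATURE_NAMES + TEXTURE_FEATURE_NAMES
)


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0 or not np.isfinite(den):
        warnings.warn(f"zero denominator in feature {name!r}; returning 0", stacklevel=3)
        return 0.0
    return num / den


# ---------------------------------------------------------------- time domain


def _zero_crossing_instants(x: np.ndarray) -> np.ndarray:
    """Linearly interpolated sign-change instants, in samples."""
    s = np.signbit(x)
    idx = np.nonzero(s[:-1] != s[1:])[0]
    x0, x1 = x[idx], x[idx + 1]
    frac = np.where(x1 != x0, x0 / (x0 - x1), 0.5)
    return idx + frac


def time_features(rec: AudioRecording) -> FeatureVector:
    """The 19 time-domain statistics of a recording."""
    x = rec.samples
    if x.size < 2:
        raise ValueError("time features require at least 2 samples")
    absx = np.abs(x)
    mean = float(np.mean(x))
    sd = float(np.sqrt(np.mean((x - mean) ** 2)))  # population (1/n)
    peak = float(np.max(absx))
    pp = float(np.max(x) - np.min(x))
    energy = float(np.sum(x * x))
    rms = float(np.sqrt(np.mean(x * x)))
    mean_abs = float(np.mean(absx))
    sqrt_mean = float(np.mean(np.sqrt(absx)))

    # scipy returns nan (with a precision warning) on (near-)constant input
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        skewness = float(_skew(x)) if sd > 0 else 0.0
        kurt = float(_kurtosis(x, fisher=True)) if sd > 0 else 0.0
    skewness = skewness if np.isfinite(skewness) else 0.0
    kurt = kurt if np.isfinite(kurt) else 0.0

    # Shannon energy on peak-normalized samples so log arguments are in (0, 1]
    xn2 = (absx / peak) ** 2 if peak > 0 else np.zeros_like(x)
    nz = xn2 > 0
    shannon = float(-np.sum(xn2[nz] * np.log(xn2[nz])))

    log_energy = float(np.log10(energy)) if energy > 0 else 0.0

    crossings = _zero_crossing_instants(x)
    avg_freq = crossings.size / x.size * rec.fs / 2.0
    if crossings.size >= 3:
        periods = np.diff(crossings)
        mean_period = float(np.mean(periods))
        jitter = (
            float(np.mean(np.abs(np.diff(periods)))) / mean_period
            if periods.size >= 2 and mean_period > 0
            else 0.0
        )
    else:
        jitter = 0.0

    values = [
        mean,
        sd,
        skewness,
        kurt,
        pp,
        rms,
        _safe_div(peak, rms, "crest_factor"),
        _safe_div(rms, mean_abs, "shape_factor"),
        _safe_div(peak, mean_abs, "impulse_factor"),
        _safe_div(peak, sqrt_mean**2, "margin_factor"),
        energy,
        _safe_div(peak, rms, "peak_to_rms"),
        float(np.sqrt(energy)),
        shannon,
        log_energy,
        float(np.mean(np.abs(x - mean))),
        float(np.median(np.abs(x - np.median(x)))),
        float(avg_freq),
        float(jitter),
    ]
    return FeatureVector(values, TIME_FEATURE_NAMES, ["time"] * 19)


# ------------------------------------------------------------ spectral domain


def _magnitude_spectrum(x: np.ndarray) -> np.ndarray:
    return np.abs(rfft(x))


def _stft_magnitudes(x: np.ndarray, fs: float, sp: SpectrogramParams) -> np.ndarray:
    """Magnitude STFT, shape (freq_bins, frames)."""
    _, _, z = stft(
        x,
        fs=fs,
        window=sp.window,
        nperseg=sp.window_length,
        noverlap=sp.overlap,
        boundary=None,
        padded=False,
    )
    return np.abs(z)


def spectral_features(rec: AudioRecording, sp: SpectrogramParams = SpectrogramParams()) -> FeatureVector:
    """The 12 statistics of the one-sided DFT magnitude spectrum.

    Flux alone is short-time (mean over consecutive STFT frame pairs of the
    summed squared magnitude difference); everything else is computed on the
    whole-recording spectrum.
    """
    x = rec.samples
    if x.size < 16:
        raise ValueError("spectral features require at least 16 samples")
    mag = _magnitude_spectrum(x)
    freqs = rfftfreq(x.size, d=1.0 / rec.fs)
    n = mag.size
    mu = float(np.mean(mag))
    sigma = float(np.sqrt(np.mean((mag - mu) ** 2)))
    total = float(np.sum(mag))

    skew = float(np.mean((mag - mu) ** 3) / sigma**3) if sigma > 0 else 0.0
    kurt = float(np.mean((mag - mu) ** 4) / sigma**4 - 3.0) if sigma > 0 else 0.0

    centroid = _safe_div(float(np.sum(freqs * mag)), total, "s_centroid")
    spread = (
        float(np.sqrt(np.sum((freqs - centroid) ** 2 * mag) / total)) if total > 0 else 0.0
    )

    # roll-off: lowest frequency below which 95% of the cumulative magnitude lies
    if total > 0:
        rolloff = float(freqs[np.searchsorted(np.cumsum(mag), 0.95 * total)])
    else:
        rolloff = 0.0

    if total > 0:
        flatness = float(np.exp(np.mean(np.log(mag + _EPS))) / (mu + _EPS))
        crest = float(np.max(mag) / mu)
    else:
        flatness = 0.0
        crest = 0.0

    # decrease: average (1/i)-weighted drop relative to the DC magnitude
    i = np.arange(1, n)
    tail = float(np.sum(mag[1:]))
    decrease = _safe_div(float(np.sum((mag[1:] - mag[0]) / i)), tail, "s_decrease")

    slope = float(np.polyfit(freqs, mag, 1)[0]) if n >= 2 else 0.0

    frames = _stft_magnitudes(x, rec.fs, sp)
    if frames.shape[1] >= 2:
        flux = float(np.mean(np.sum(np.diff(frames, axis=1) ** 2, axis=0)))
    else:
        flux = 0.0

    values = [mu, sigma, skew, kurt, centroid, flux, rolloff, flatness, crest, decrease, slope, spread]
    return FeatureVector(values, SPECTRAL_FEATURE_NAMES, ["spectral"] * 12)


# ------------------------------------------------------------------- cepstral


def mel_scale(f: float | np.ndarray) -> np.ndarray:
    """Mel(f) = 2595 log10(1 + f/700)."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_inverse(m: np.ndarray) -> np.ndarray:
    return 700.0 * (10.0 ** (m / 2595.0) - 1.0)


ERB_A = 1000.0 * np.log(10.0) / (24.7 * 4.37)  # ~21.4


def erb_scale(hz: float | np.ndarray) -> np.ndarray:
    """ERB-rate number: A log10(1 + 0.00437 hz), A = 1000 ln10 / (24.7 * 4.37)."""
    return ERB_A * np.log10(1.0 + 0.00437 * np.asarray(hz, dtype=np.float64))


def _erb_inverse(e: np.ndarray) -> np.ndarray:
    return (10.0 ** (e / ERB_A) - 1.0) / 0.00437


def _mel_filterbank(n_filters: int, n_fft: int, fs: float) -> np.ndarray:
    """Triangular filters with edges equally spaced on the Mel scale."""
    edges_mel = np.linspace(0.0, float(mel_scale(fs / 2.0)), n_filters + 2)
    edges_hz = _mel_inverse(edges_mel)
    freqs = rfftfreq(n_fft, d=1.0 / fs)
    fb = np.zeros((n_filters, freqs.size))
    for j in range(n_filters):
        lo, mid, hi = edges_hz[j : j + 3]
        rising = (freqs - lo) / max(mid - lo, _EPS)
        falling = (hi - freqs) / max(hi - mid, _EPS)
        fb[j] = np.clip(np.minimum(rising, falling), 0.0, None)
    return fb


def _frame_signal(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    n_frames = 1 + max(0, (x.size - frame_len)) // hop
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def mfcc(
    rec: AudioRecording,
    n_coeffs: int = 13,
    n_filters: int = 26,
    frame_ms: float = 55.0,
) -> np.ndarray:
    """Per-recording MFCC vector: mean over frames of the DCT-II of the log
    Mel filter-bank magnitudes.

    Frames are ``frame_ms`` long (default 55 ms, in the 50-60 ms range usual
    for respiratory sounds) with 50% hop and a Hann taper.  A silent frame
    is floored at 1e-10 before the log.
    """
    frame_len = max(int(round(frame_ms / 1000.0 * rec.fs)), 16)
    hop = max(frame_len // 2, 1)
    x = rec.samples
    if x.size < frame_len:
        # short recording: single zero-padded frame
        x = np.pad(x, (0, frame_len - x.size))
    frames = _frame_signal(x, frame_len, hop) * get_window("hann", frame_len)
    mags = np.abs(rfft(frames, axis=1))
    fb = _mel_filterbank(n_filters, frame_len, rec.fs)
    energies = mags @ fb.T
    # floor relative to the frame's strongest filter so that amplitude
    # scaling shifts every log energy by the same constant (only c0 moves)
    floor = np.maximum(energies.max(axis=1, keepdims=True) * _EPS, 1e-30)
    logenergies = np.log(np.maximum(energies, floor))
    coeffs = dct(logenergies, type=2, axis=1, norm="ortho")[:, :n_coeffs]
    return coeffs.mean(axis=0)


def _gammatone_center_freqs(n_channels: int, fs: float, f_min: float = 50.0) -> np.ndarray:
    f_max = 0.99 * fs / 2.0
    erbs = np.linspace(float(erb_scale(f_min)), float(erb_scale(f_max)), n_channels)
    return _erb_inverse(erbs)


def gfcc(
    rec: AudioRecording,
    n_coeffs: int = 13,
    n_channels: int = 64,
    frame_rate: float = 100.0,
) -> np.ndarray:
    """Per-recording GFCC vector.

    The signal is passed through a 64-channel gammatone filter bank with
    ERB-spaced center frequencies, rectified, averaged into 100 Hz frames,
    cube-root compressed, and DCT-II transformed across channels; the first
    ``n_coeffs`` coefficients are averaged over frames.  Silence maps to the
    zero vector.
    """
    x = rec.samples
    if x.size < int(0.01 * rec.fs):
        raise ValueError("recording shorter than 10 ms")
    centers = _gammatone_center_freqs(n_channels, rec.fs)
    frame_len = max(int(round(rec.fs / frame_rate)), 1)
    n_frames = x.size // frame_len
    if n_frames == 0:
        n_frames, frame_len = 1, x.size
    envelopes = np.empty((n_channels, n_frames))
    for c, fc in enumerate(centers):
        b, a = _gammatone_design(fc, "iir", fs=rec.fs)
        y = np.abs(lfilter(b, a, x))
        envelopes[c] = y[: n_frames * frame_len].reshape(n_frames, frame_len).mean(axis=1)
    compressed = np.cbrt(envelopes)
    coeffs = dct(compressed, type=2, axis=0, norm="ortho")[:n_coeffs]
    return coeffs.mean(axis=1)


# -------------------------------------------------------------------- texture


def _uniform_lbp_lut() -> np.ndarray:
    """256-entry lookup: uniform codes -> 0..57 (ascending code), others -> 58."""
    lut = np.full(256, 58, dtype=np.intp)
    uniform = []
    for code in range(256):
        bits = [(code >> k) & 1 for k in range(8)]
        transitions = sum(bits[k] != bits[(k + 1) % 8] for k in range(8))
        if transitions <= 2:
            uniform.append(code)
    for rank, code in enumerate(uniform):  # 58 uniform codes
        lut[code] = rank
    return lut


_LBP_LUT = _uniform_lbp_lut()

# (row, col) offsets counter-clockwise from east, in image coordinates
# (row grows downward, so counter-clockwise visits north before south)
_LBP_OFFSETS = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]


def uniform_lbp_histogram(image: np.ndarray) -> np.ndarray:
    """59-bin normalized uniform-LBP histogram of a 2-D image.

    Bit k (weight 2**k) is set when the k-th neighbor (counter-clockwise
    from east, radius 1) is >= the center pixel.  Border pixels are not
    coded.  Bins 0..57 are the uniform codes in ascending order; bin 58
    pools every non-uniform code.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError("LBP requires a 2-D image of at least 3x3 pixels")
    center = img[1:-1, 1:-1]
    codes = np.zeros(center.shape, dtype=np.intp)
    for k, (dr, dc) in enumerate(_LBP_OFFSETS):
        nb = img[1 + dr : img.shape[0] - 1 + dr, 1 + dc : img.shape[1] - 1 + dc]
        codes |= (nb >= center).astype(np.intp) << k
    hist = np.bincount(_LBP_LUT[codes].ravel(), minlength=59).astype(np.float64)
    return hist / hist.sum()


def lbp_texture(rec: AudioRecording, sp: SpectrogramParams = SpectrogramParams()) -> FeatureVector:
    """Uniform-LBP histogram of the dB magnitude spectrogram (59 features)."""
    min_len = sp.window_length + 2 * sp.hop
    if rec.samples.size < min_len:
        raise ValueError(
            f"recording too short for 3 spectrogram frames (needs >= {min_len} samples)"
        )
    mags = _stft_magnitudes(rec.samples, rec.fs, sp)
    image = 20.0 * np.log10(mags + _EPS)
    hist = uniform_lbp_histogram(image)
    return FeatureVector(hist, TEXTURE_FEATURE_NAMES, ["texture"] * 59)


# ------------------------------------------------------------------ composite


def extract_all(rec: AudioRecording, sp: SpectrogramParams = SpectrogramParams()) -> FeatureVector:
    """Full 116-feature descriptor: time(19) | spectral(12) | cepstral(26) |
    texture(59), in the fixed package-wide order."""
    tf = time_features(rec)
    sf = spectral_features(rec, sp)
    mf = mfcc(rec)
    gf = gfcc(rec)
    xf = lbp_texture(rec, sp)
    values = np.concatenate([tf.values, sf.values, mf, gf, xf.values])
    groups = ["time"] * 19 + ["spectral"] * 12 + ["cepstral"] * 26 + ["texture"] * 59
    return FeatureVector(values, ALL_FEATURE_NAMES, groups)


def extract_table(
    recordings: list[AudioRecording], sp: SpectrogramParams = SpectrogramParams()
) -> FeatureTable:
    """Extract the full descriptor for every recording into a feature table."""
    rows = [extract_all(rec, sp).values for rec in recordings]
    labels = [rec.label for rec in recordings]
    return FeatureTable(np.vstack(rows), np.array(labels, dtype=object), list(ALL_FEATURE_NAMES))
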
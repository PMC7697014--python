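"""Synthetic lung-sound generation with class-dependent acoustic structure.

Every recording starts from the same normal-breath model: Gaussian noise
band-passed to the 60-600 Hz tracheal band and amplitude-modulated by a
breath-cycle envelope (default 0.25 Hz, i.e. 15 breaths/min, with a shorter
inspiratory and longer expiratory phase).  Class structure is added on top:

* healthy  — breath base plus mild high-frequency sensor noise and
  low-frequency baseline wander only;
* COPD     — adds wheezes: sustained amplitude-enveloped sinusoids
  (200-800 Hz, 0.3-1 s) placed in expiratory phases, the classic
  obstructive adventitious sound;
* pneumonia — adds crackle trains: brief exponentially damped sinusoids
  (400-2000 Hz center, 5-40 ms decay), the discontinuous adventitious
  sound of consolidation.

Defaults mirror the recording conventions of the focused respiratory
database (21.5 s average duration at 44.1 kHz).  Waveforms are fully
determined by ``SyntheticSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .audio_io import CLASSES, AudioRecording

__all__ = ["WheezeParams", "CrackleParams", "NoiseParams", "SyntheticSpec", "generate", "generate_dataset"]


@dataclass(frozen=True)
class WheezeParams:
    count: int = 3  # wheezes per recording
    freq_range: tuple[float, float] = (200.0, 800.0)
    duration_range: tuple[float, float] = (0.3, 1.0)
    amplitude: float = 1.0  # wheezes are typically as loud as the breath sound


@dataclass(frozen=True)
class CrackleParams:
    rate_per_cycle: float = 8.0
    freq_range: tuple[float, float] = (400.0, 2000.0)
    decay_range_ms: tuple[float, float] = (5.0, 40.0)
    amplitude: float = 1.2  # crackles stand well above the breath floor


@dataclass(frozen=True)
class NoiseParams:
    hf_amplitude: float = 0.05  # broadband sensor noise
    wander_amplitude: float = 0.05  # low-frequency baseline drift


@dataclass(frozen=True)
class SyntheticSpec:
    label: str = "healthy"
    duration: float = 21.5
    fs: float = 44100.0
    breath_rate: float = 0.25
    wheeze: WheezeParams = field(default_factory=WheezeParams)
    crackle: CrackleParams = field(default_factory=CrackleParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"invalid class {self.label!r}; expected one of {CLASSES}")
        if self.duration <= 0 or self.fs <= 0 or self.breath_rate <= 0:
            raise ValueError("duration, fs and breath_rate must be positive")
        nyq = self.fs / 2.0
        for lo, hi in (self.wheeze.freq_range, self.crackle.freq_range):
            if not 0.0 < lo < hi < nyq:
                raise ValueError(f"frequency range ({lo}, {hi}) outside (0, {nyq})")

    @classmethod
    def compact(cls, **overrides) -> "SyntheticSpec":
        """A small profile for fast end-to-end experiments: 3 s at 16 kHz with
        a 0.6 Hz breath rate, so each recording holds ~2 complete breath
        cycles and the adventitious bands (up to 2 kHz) sit well below the
        first intrinsic mode, which then carries only sensor noise."""
        defaults = dict(duration=3.0, fs=16000.0, breath_rate=0.6)
        defaults.update(overrides)
        return cls(**defaults)


def _breath_envelope(t: np.ndarray, breath_rate: float) -> np.ndarray:
    """Smooth two-phase breath-cycle amplitude envelope in [0.15, 1]."""
    phase = (t * breath_rate) % 1.0
    insp = np.sin(np.pi * phase / 0.4) ** 2 * (phase < 0.4)
    exp_ = 0.7 * np.sin(np.pi * (phase - 0.4) / 0.6) ** 2 * (phase >= 0.4)
    return 0.15 + 0.85 * (insp + exp_)


def _bandpass(x: np.ndarray, lo: float, hi: float, fs: float, order: int = 4) -> np.ndarray:
    sos = butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def generate(spec: SyntheticSpec) -> AudioRecording:
    """Generate one labeled recording, fully determined by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    envelope = _breath_envelope(t, spec.breath_rate)

    hi = min(600.0, 0.95 * spec.fs / 2.0)
    base = _bandpass(rng.standard_normal(n), 60.0, hi, spec.fs)
    base /= max(np.sqrt(np.mean(base**2)), 1e-12)  # unit-RMS breath band
    x = base * envelope

    if spec.label == "COPD":
        x = x + _wheezes(rng, t, spec)
    elif spec.label == "pneumonia":
        x = x + _crackles(rng, t, spec)

    # additive high-frequency noise + baseline wander (all classes)
    x = x + spec.noise.hf_amplitude * rng.standard_normal(n)
    wander_f = rng.uniform(0.1, 0.8)
    x = x + spec.noise.wander_amplitude * np.sin(
        2.0 * np.pi * wander_f * t + rng.uniform(0.0, 2.0 * np.pi)
    )

    peak = np.max(np.abs(x))
    if peak > 0:
        x = 0.9 * x / peak
    return AudioRecording(x, spec.fs, spec.label, source_id=f"synthetic-{spec.label}-{spec.seed}")


def _wheezes(rng: np.random.Generator, t: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    """Sustained tones with Hann onset/offset, placed in expiratory phases."""
    out = np.zeros_like(t)
    cycle = 1.0 / spec.breath_rate
    n_cycles = max(int(spec.duration * spec.breath_rate), 1)
    w = spec.wheeze
    for _ in range(w.count):
        k = rng.integers(n_cycles)
        dur = rng.uniform(*w.duration_range)
        start = (k + 0.45) * cycle + rng.uniform(0.0, max(0.55 * cycle - dur, 1e-3))
        f = rng.uniform(*w.freq_range)
        mask = (t >= start) & (t < start + dur)
        tau = t[mask] - start
        if tau.size == 0:
            continue
        taper = np.sin(np.pi * tau / dur) ** 2
        out[mask] += w.amplitude * taper * np.sin(2.0 * np.pi * f * tau + rng.uniform(0, 2 * np.pi))
    return out


def _crackles(rng: np.random.Generator, t: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    """Exponentially damped sinusoid transients scattered through each cycle."""
    out = np.zeros_like(t)
    fs = spec.fs
    n = t.size
    c = spec.crackle
    n_events = max(int(round(c.rate_per_cycle * spec.duration * spec.breath_rate)), 1)
    for _ in range(n_events):
        start = rng.uniform(0.0, spec.duration)
        f = rng.uniform(*c.freq_range)
        tau = rng.uniform(*c.decay_range_ms) / 1000.0
        i0 = int(start * fs)
        length = min(int(6 * tau * fs) + 1, n - i0)
        if length <= 1:
            continue
        tt = np.arange(length) / fs
        out[i0 : i0 + length] += (
            c.amplitude * np.exp(-tt / tau) * np.sin(2.0 * np.pi * f * tt)
        )
    return out


def generate_dataset(
    n_per_class: Dict[str, int],
    base_spec: SyntheticSpec = SyntheticSpec(),
    seed: int = 0,
) -> List[AudioRecording]:
    """Generate a labeled dataset with per-recording parameter jitter.

    Each recording draws its own sub-seed plus mild jitter of breath rate,
    wheeze/crackle frequency placement and event counts, so classes overlap
    yet stay separable.  Class counts may be deliberately imbalanced to
    exercise the balancing stage.
    """
    rng = np.random.default_rng(seed)
    recordings: List[AudioRecording] = []
    for label in sorted(n_per_class):
        count = n_per_class[label]
        if count < 1:
            raise ValueError(f"count for class {label!r} must be >= 1")
        for _ in range(count):
            sub_seed = int(rng.integers(2**31 - 1))
            jrng = np.random.default_rng(sub_seed)
            w = base_spec.wheeze
            c = base_spec.crackle
            spec = replace(
                base_spec,
                label=label,
                seed=sub_seed,
                breath_rate=base_spec.breath_rate * jrng.uniform(0.85, 1.15),
                wheeze=replace(w, count=max(int(w.count + jrng.integers(-1, 2)), 1)),
                crackle=replace(c, rate_per_cycle=c.rate_per_cycle * jrng.uniform(0.7, 1.3)),
            )
            recordings.append(generate(spec))
    return recordings
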
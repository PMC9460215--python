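"""Synthetic bowel-sound recordings with controllable class structure.

Bowel sounds are sporadic short acoustic bursts — gas and luminal contents
moving through the intestine — with dominant spectral energy roughly between
100 and 500 Hz, riding on a broadband noise floor.  In the hour before
defecation the frequency and amplitude of the associated colonic motility
rise, so pre-defecation recordings (label 1) carry more bursts and louder
bursts than quiescent recordings (label 0).

The simulator encodes exactly that structure: a homogeneous Poisson event
process in time (exponential inter-event gaps), each event an exponentially
damped sinusoid with carrier frequency drawn from the burst band, plus
additive Gaussian noise.  Class 1 multiplies both the event rate and the
mean burst amplitude.  All randomness flows through a single
``numpy.random.Generator`` so a (config, label, seed) triple is bit-for-bit
reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile

SAMPLE_RATE = 4_000  # Hz; the electronic stethoscope's export rate
UNLABELED = -1

__all__ = [
    "SAMPLE_RATE", "UNLABELED", "Burst", "Recording", "SynthConfig",
    "generate_recording", "generate_fixture_set", "write_wav", "read_wav",
]


@dataclass(frozen=True)
class Burst:
    """One injected acoustic event (simulator ground truth)."""

    onset_s: float
    duration_s: float
    carrier_hz: float
    amplitude: float


@dataclass
class Recording:
    """A mono amplitude series at 4 kHz with an optional class label.

    ``label`` is 0 (no defecation tendency), 1 (defecation tendency) or
    ``UNLABELED``.  ``events`` is the simulator's injected-burst list; it is
    empty for recordings read from disk.
    """

    samples: np.ndarray
    sample_rate: int = SAMPLE_RATE
    label: int = UNLABELED
    subject_id: str = ""
    events: list[Burst] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D mono series")
        if self.sample_rate != SAMPLE_RATE:
            raise ValueError(f"sample_rate must be {SAMPLE_RATE} Hz")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass(frozen=True)
class SynthConfig:
    """Generative parameters for one simulated acquisition protocol.

    Class-0 recordings use the base rate/amplitude; class-1 recordings use
    ``burst_rate_per_min * burst_rate_multiplier`` events per minute and
    ``burst_amp * burst_amp_multiplier`` mean peak amplitude.  Defaults make
    the classes learnable but not trivially separable.
    """

    burst_rate_per_min: float = 10.0
    burst_rate_multiplier: float = 1.8
    burst_amp: float = 0.25
    burst_amp_multiplier: float = 1.5
    burst_freq_band: tuple[float, float] = (100.0, 500.0)
    burst_duration_ms: tuple[float, float] = (20.0, 200.0)
    damping: float = 5.0  # envelope e-foldings across one burst duration
    noise_floor_rms: float = 0.02
    duration_s: float = 60.0

    def __post_init__(self) -> None:
        low, high = self.burst_freq_band
        if not (0 < low < high <= SAMPLE_RATE / 2):
            raise ValueError(
                f"burst_freq_band must satisfy 0 < low < high <= "
                f"{SAMPLE_RATE // 2} (Nyquist); got {self.burst_freq_band}")
        if self.burst_rate_multiplier < 1 or self.burst_amp_multiplier < 1:
            raise ValueError("class-1 multipliers must be >= 1")
        if self.noise_floor_rms < 0:
            raise ValueError("noise_floor_rms must be >= 0")
        if self.burst_rate_per_min < 0:
            raise ValueError("burst_rate_per_min must be >= 0")

    @classmethod
    def separable(cls) -> "SynthConfig":
        """A well-separated variant (large rate/amplitude contrast, low
        noise floor) for scaled-down learning checks."""
        return cls(burst_rate_per_min=15.0, burst_rate_multiplier=8.0,
                   burst_amp=0.15, burst_amp_multiplier=5.0,
                   noise_floor_rms=0.005)


def _burst_waveform(n: int, fs: int, carrier_hz: float, amplitude: float,
                    damping: float, phase: float) -> np.ndarray:
    t = np.arange(n) / fs
    envelope = np.exp(-damping * t / (n / fs))
    return amplitude * envelope * np.sin(2 * np.pi * carrier_hz * t + phase)


def generate_recording(config: SynthConfig, label: int,
                       rng_seed: int) -> Recording:
    """Simulate one labeled recording (default 60 s -> 240,000 samples).

    Burst onsets follow a homogeneous Poisson process (exponential gaps) at
    the class-appropriate rate; each burst is a damped sinusoid whose
    carrier is uniform over ``burst_freq_band``; Gaussian noise at
    ``noise_floor_rms`` is added and the sum is clipped to [-1, 1].
    """
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label!r}")
    rng = np.random.default_rng(rng_seed)
    fs = SAMPLE_RATE
    n = round(config.duration_s * fs)
    samples = np.zeros(n)
    rate_per_s = config.burst_rate_per_min / 60.0
    amp_mean = config.burst_amp
    if label == 1:
        rate_per_s *= config.burst_rate_multiplier
        amp_mean *= config.burst_amp_multiplier

    events: list[Burst] = []
    t = 0.0
    lo_ms, hi_ms = config.burst_duration_ms
    while rate_per_s > 0:
        t += rng.exponential(1.0 / rate_per_s)
        if t >= config.duration_s:
            break
        dur = rng.uniform(lo_ms, hi_ms) / 1000.0
        carrier = rng.uniform(*config.burst_freq_band)
        # log-normal scatter around the class mean peak amplitude
        amp = amp_mean * rng.lognormal(mean=0.0, sigma=0.25)
        phase = rng.uniform(0, 2 * np.pi)
        start = int(t * fs)
        length = min(int(dur * fs), n - start)
        if length > 0:
            samples[start:start + length] += _burst_waveform(
                length, fs, carrier, amp, config.damping, phase)
            events.append(Burst(t, dur, carrier, amp))
    if config.noise_floor_rms > 0:
        samples += rng.normal(0.0, config.noise_floor_rms, n)
    np.clip(samples, -1.0, 1.0, out=samples)
    return Recording(samples, fs, label, subject_id=f"synth-{rng_seed}",
                     events=events)


def generate_fixture_set(config: SynthConfig, n_total: int = 200,
                         n_positive: int = 60, rng_seed: int = 0):
    """Build a labeled test set of preprocessed spectral frames.

    Builds an evaluation set of the standard composition: ``n_total``
    segments of which
    exactly ``n_positive`` carry label 1 (defaults 200 / 60).  Recordings
    are simulated per class, segmented into 10,000-sample windows and
    FFT-transformed; surplus segments are discarded.

    Returns ``(frames, labels)`` with frames of shape (n_total, 10000).
    """
    from . import preprocess  # segment/FFT pipeline lives there

    if not 0 <= n_positive <= n_total:
        raise ValueError("need 0 <= n_positive <= n_total")
    seed_rng = np.random.default_rng(rng_seed)
    frames_parts, labels_parts = [], []
    for label, need in ((1, n_positive), (0, n_total - n_positive)):
        collected = []
        while sum(len(c) for c in collected) < need:
            rec = generate_recording(
                config, label, int(seed_rng.integers(0, 2 ** 31)))
            segs = preprocess.segment_recording(rec)
            collected.append(np.stack(
                [preprocess.fft_transform(s).values for s in segs]))
        if collected:
            stacked = np.concatenate(collected)[:need]
            frames_parts.append(stacked)
            labels_parts.append(np.full(need, label, dtype=np.int64))
    if not frames_parts:
        return (np.empty((0, preprocess.WINDOW), dtype=np.float32),
                np.empty(0, dtype=np.int64))
    return np.concatenate(frames_parts), np.concatenate(labels_parts)


def write_wav(recording: Recording, path) -> None:
    """Write a Recording as 16-bit PCM mono WAV."""
    scaled = np.clip(recording.samples, -1.0, 1.0)
    pcm = np.round(scaled * 32767.0).astype(np.int16)
    wavfile.write(str(path), recording.sample_rate, pcm)


def read_wav(path, *, label: int = UNLABELED,
             strict_rate: bool = True) -> Recording:
    """Read a mono PCM WAV back into a Recording.

    Rejects stereo files.  A sample rate other than 4 kHz raises by
    default; with ``strict_rate=False`` the signal is resampled to 4 kHz
    (polyphase) with a warning.
    """
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"expected mono WAV, got {data.ndim} channels")
    if np.issubdtype(data.dtype, np.integer):
        samples = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        samples = data.astype(np.float64)
    if rate != SAMPLE_RATE:
        if strict_rate:
            raise ValueError(
                f"expected {SAMPLE_RATE} Hz, got {rate} Hz "
                "(pass strict_rate=False to resample)")
        from scipy.signal import resample_poly
        from math import gcd
        g = gcd(SAMPLE_RATE, rate)
        warnings.warn(f"resampling {rate} Hz -> {SAMPLE_RATE} Hz")
        samples = resample_poly(samples, SAMPLE_RATE // g, rate // g)
    return Recording(samples, SAMPLE_RATE, label,
                     subject_id=Path(path).stem)
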
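"""Recording -> network-input pipeline: segmentation, FFT, train/test split.

A 60 s recording at 4 kHz is cut into 24 non-overlapping 10,000-sample
windows (2.5 s each), the unit of classification.  Each window is mapped to
its full two-sided 10,000-point DFT magnitude, compressed with log1p and
min-max rescaled to [-1, 1] so real frames share the range of the
generator's Tanh output — a requirement for the adversarial game to be
well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synth import Recording, UNLABELED

WINDOW = 10_000

__all__ = ["WINDOW", "Segment", "SpectralFrame", "segment_recording",
           "fft_transform", "build_dataset"]


@dataclass
class Segment:
    """One fixed-length time-domain window of a recording."""

    values: np.ndarray
    label: int = UNLABELED
    source_recording_id: str = ""
    window_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


@dataclass
class SpectralFrame:
    """A segment's normalized magnitude spectrum; the classifier's input."""

    values: np.ndarray
    label: int = UNLABELED
    source_recording_id: str = ""
    window_index: int = 0


def segment_recording(recording: Recording,
                      window: int = WINDOW) -> list[Segment]:
    """Split into consecutive non-overlapping windows; remainder dropped.

    A nominal 240,000-sample recording yields exactly 24 segments.  Every
    segment inherits the recording's label.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    n = len(recording.samples)
    if n == 0:
        raise ValueError("empty recording")
    n_windows = n // window
    return [
        Segment(recording.samples[i * window:(i + 1) * window],
                label=recording.label,
                source_recording_id=recording.subject_id,
                window_index=i)
        for i in range(n_windows)
    ]


def fft_transform(segment: Segment) -> SpectralFrame:
    """Full two-sided DFT magnitude, log1p-compressed, min-max to [-1, 1].

    The two-sided spectrum keeps the input length at 10,000 so the
    classifier sees the same shape in either domain.  A degenerate frame
    (max == min, e.g. all-zero input) maps to the constant -1.
    """
    x = segment.values
    if len(x) != WINDOW:
        raise ValueError(f"segment length must be {WINDOW}, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise ValueError("segment contains non-finite values")
    mag = np.abs(np.fft.fft(x))
    compressed = np.log1p(mag)
    lo, hi = compressed.min(), compressed.max()
    if hi - lo == 0:
        values = np.full(WINDOW, -1.0, dtype=np.float32)
    else:
        values = (2.0 * (compressed - lo) / (hi - lo) - 1.0).astype(np.float32)
    return SpectralFrame(values, label=segment.label,
                         source_recording_id=segment.source_recording_id,
                         window_index=segment.window_index)


@dataclass
class DatasetSplit:
    """Frames grouped by role; labels stripped from the unlabeled pool."""

    labeled_frames: np.ndarray
    labeled_labels: np.ndarray
    unlabeled_frames: np.ndarray
    test_frames: np.ndarray
    test_labels: np.ndarray
    train_recording_ids: list[str] = field(default_factory=list)
    test_recording_ids: list[str] = field(default_factory=list)


def build_dataset(recordings: list[Recording], labeled_fraction: float = 1.0,
                  rng_seed: int = 0, *,
                  test_fraction: float = 0.25) -> DatasetSplit:
    """Split labeled recordings into labeled / unlabeled train pools and a
    held-out test pool, then segment + FFT everything.

    The split is at the *recording* level so no recording contributes
    segments to both train and test.  Within the training portion,
    ``labeled_fraction`` of recordings (per class, rounded up) keep their
    labels; the rest are stripped to form the unlabeled pool.  Deterministic
    under ``rng_seed``.
    """
    if not 0 < labeled_fraction <= 1:
        raise ValueError("labeled_fraction must be in (0, 1]")
    by_class: dict[int, list[Recording]] = {0: [], 1: []}
    for rec in recordings:
        if rec.label not in (0, 1):
            raise ValueError("build_dataset needs labeled recordings")
        by_class[rec.label].append(rec)
    for cls, recs in by_class.items():
        if len(recs) < 2:
            raise ValueError(
                f"need at least 2 recordings of class {cls}, got {len(recs)}")

    rng = np.random.default_rng(rng_seed)
    train: list[Recording] = []
    test: list[Recording] = []
    for cls in (0, 1):
        recs = by_class[cls]
        order = rng.permutation(len(recs))
        n_test = max(1, int(round(test_fraction * len(recs))))
        n_test = min(n_test, len(recs) - 1)  # keep >= 1 train recording
        test.extend(recs[i] for i in order[:n_test])
        train.extend(recs[i] for i in order[n_test:])

    def frames_of(recs: list[Recording]):
        frames, labels, ids = [], [], []
        for rec in recs:
            for seg in segment_recording(rec):
                frame = fft_transform(seg)
                frames.append(frame.values)
                labels.append(frame.label)
            ids.append(rec.subject_id)
        return (np.stack(frames) if frames else
                np.empty((0, WINDOW), dtype=np.float32),
                np.asarray(labels, dtype=np.int64), ids)

    # per-class labeled/unlabeled assignment inside the training pool
    labeled_recs: list[Recording] = []
    unlabeled_recs: list[Recording] = []
    for cls in (0, 1):
        recs = [r for r in train if r.label == cls]
        order = rng.permutation(len(recs))
        n_lab = max(1, int(np.ceil(labeled_fraction * len(recs))))
        labeled_recs.extend(recs[i] for i in order[:n_lab])
        unlabeled_recs.extend(recs[i] for i in order[n_lab:])

    lab_frames, lab_labels, _ = frames_of(labeled_recs)
    unl_frames, _, _ = frames_of(unlabeled_recs)  # labels stripped
    test_frames, test_labels, test_ids = frames_of(test)
    train_ids = [r.subject_id for r in labeled_recs + unlabeled_recs]
    return DatasetSplit(lab_frames, lab_labels, unl_frames,
                        test_frames, test_labels, train_ids, test_ids)
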
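"""Filtering, normalization, beat segmentation and subject-level splitting.

The preprocessing contract: each recording is bandpass filtered
(fourth-order Butterworth, 0.5-100 Hz) and notch filtered at the
power-line frequency, both applied forward-backward so the filtering is
zero-phase (phase distortion would corrupt the geometry of the image
encodings); the recording is z-score normalized; beats are located with a
Pan-Tompkins-style detector adapted to magnetic signals by rectifying the
signal first (magnetic polarity depends on sensor placement); each beat
is cut to a window around its peak, linearly resampled to exactly 224
samples and min-max scaled to [0, 1] as the direct input to the image
encoders; and subjects are split 70/10/20 into train/validation/test
strata per class so no subject's cycles straddle splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import DegenerateInputError, InvalidInputError, InvalidParameterError

__all__ = [
    "FilterSpec",
    "CardiacCycle",
    "SplitAssignment",
    "CYCLE_LENGTH",
    "zscore_normalize",
    "minmax_normalize",
    "bandpass_filter",
    "notch_filter",
    "detect_beats",
    "segment_cycles",
    "split_subjects",
]

CYCLE_LENGTH = 224  # samples per resampled beat; matches the CNN input side


@dataclass
class FilterSpec:
    bandpass_order: int = 4
    bandpass_low: float = 0.5
    bandpass_high: float = 100.0
    notch_freq: float = 50.0
    notch_q: float = 30.0

    def validate(self, fs: float) -> None:
        if not (0 < self.bandpass_low < self.bandpass_high < fs / 2):
            raise InvalidParameterError(
                f"need 0 < low < high < fs/2, got ({self.bandpass_low}, "
                f"{self.bandpass_high}) at fs={fs}"
            )
        if self.bandpass_order < 2 or self.bandpass_order % 2:
            raise InvalidParameterError("bandpass_order must be even and >= 2")


@dataclass
class CardiacCycle:
    """One beat resampled to 224 samples and min-max scaled to [0, 1]."""

    subject_id: str
    label: int
    x: np.ndarray
    peak_time: float


@dataclass
class SplitAssignment:
    """Maps each subject id to exactly one of train / val / test."""

    assignment: dict[str, str] = field(default_factory=dict)

    def subjects(self, partition: str) -> list[str]:
        return [s for s, p in self.assignment.items() if p == partition]

    def __getitem__(self, subject_id: str) -> str:
        return self.assignment[subject_id]


def zscore_normalize(x: np.ndarray) -> np.ndarray:
    """(x - mean) / population standard deviation, at recording level."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise InvalidInputError("need at least 2 samples")
    sigma = x.std()  # ddof=0: the recording is treated as the population
    if sigma == 0:
        raise DegenerateInputError("constant recording has zero variance")
    return (x - x.mean()) / sigma


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Map to [0, 1] linearly; the direct input to the image encoders."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise InvalidInputError("need at least 2 samples")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateInputError("flat cycle cannot be min-max scaled")
    return (x - lo) / (hi - lo)


def bandpass_filter(x: np.ndarray, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase Butterworth bandpass (default fourth order, 0.5-100 Hz)."""
    spec = spec if spec is not None else FilterSpec()
    spec.validate(fs)
    sos = signal.butter(
        spec.bandpass_order,
        [spec.bandpass_low, spec.bandpass_high],
        btype="bandpass",
        output="sos",
        fs=fs,
    )
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def notch_filter(x: np.ndarray, fs: float, notch_freq: float = 50.0, notch_q: float = 30.0) -> np.ndarray:
    """Zero-phase second-order IIR notch at ``notch_freq``."""
    if not (0 < notch_freq < fs / 2):
        raise InvalidParameterError("notch frequency must lie in (0, fs/2)")
    b, a = signal.iirnotch(notch_freq, notch_q, fs=fs)
    return signal.filtfilt(b, a, np.asarray(x, dtype=float))


def detect_beats(
    x: np.ndarray,
    fs: float,
    *,
    refractory: float = 0.20,
    integration_window: float = 0.15,
    threshold_fraction: float = 0.4,
) -> np.ndarray:
    """Pan-Tompkins-style beat detector on the rectified signal.

    Chain: |x| -> 5-15 Hz bandpass -> derivative -> squaring -> 150 ms
    moving-window integration -> adaptive threshold (``threshold_fraction``
    times the running mean of the last 8 accepted integrated peaks) with a
    200 ms refractory period.  Rectification makes the detector invariant
    to magnetic polarity.  Returns strictly increasing sample indices of
    the beat peaks (maxima of the rectified band signal), or an empty
    array when nothing crosses threshold.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 * fs:
        raise InvalidInputError("need at least 2 s of signal")
    if not np.any(x):
        return np.array([], dtype=int)

    rect = np.abs(x)
    sos = signal.butter(2, [5.0, 15.0], btype="bandpass", output="sos", fs=fs)
    band = signal.sosfiltfilt(sos, rect)
    deriv = np.gradient(band)
    squared = deriv**2
    win = max(int(round(integration_window * fs)), 1)
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")

    min_dist = max(int(round(refractory * fs)), 1)
    cand, _ = signal.find_peaks(integrated, distance=min_dist)
    if cand.size == 0:
        return np.array([], dtype=int)

    # adaptive threshold over the candidate sequence
    heights = integrated[cand]
    level = threshold_fraction * float(np.mean(heights))
    recent: list[float] = []
    accepted = []
    for idx, h in zip(cand, heights):
        if h >= level:
            accepted.append(idx)
            recent.append(h)
            if len(recent) > 8:
                recent.pop(0)
            level = threshold_fraction * float(np.mean(recent))
    if not accepted:
        return np.array([], dtype=int)

    # refine each detection to the local maximum of the rectified band signal
    half = int(round(0.10 * fs))
    peaks = []
    for idx in accepted:
        lo, hi = max(idx - half, 0), min(idx + half + 1, x.size)
        peaks.append(lo + int(np.argmax(np.abs(band[lo:hi]))))
    peaks = np.unique(peaks)
    return peaks.astype(int)


def segment_cycles(
    x: np.ndarray,
    fs: float,
    peaks: np.ndarray,
    *,
    subject_id: str = "",
    label: int = 0,
    pre_fraction: float = 0.3,
    post_fraction: float = 0.5,
    n_samples: int = CYCLE_LENGTH,
) -> list[CardiacCycle]:
    """Cut a window around each peak, resample to ``n_samples``, min-max scale.

    The window is [peak - 0.3 RRmed, peak + 0.5 RRmed] where RRmed is the
    median inter-peak interval, covering the P-through-T analogue span.
    Windows exceeding the signal bounds and flat (degenerate) windows are
    dropped.
    """
    x = np.asarray(x, dtype=float)
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size < 2:
        return []
    rr_med = float(np.median(np.diff(peaks)))
    pre = int(round(pre_fraction * rr_med))
    post = int(round(post_fraction * rr_med))
    cycles = []
    for p in peaks:
        lo, hi = p - pre, p + post
        if lo < 0 or hi > x.size:
            continue
        window = x[lo:hi]
        grid = np.linspace(0, window.size - 1, n_samples)
        resampled = np.interp(grid, np.arange(window.size), window)
        try:
            scaled = minmax_normalize(resampled)
        except DegenerateInputError:
            continue
        cycles.append(
            CardiacCycle(subject_id=subject_id, label=label, x=scaled, peak_time=p / fs)
        )
    return cycles


def split_subjects(
    subjects: list[tuple[str, int]],
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 42,
) -> SplitAssignment:
    """Stratified subject-level split into train/val/test.

    Per class: shuffle with ``seed``, assign floor(test_fraction * n) to
    test and floor(val_fraction * n) to val, the remainder to train.  The
    floor rule reproduces a 423-subject test partition for a cohort of
    1135 + 983.
    """
    train_f, val_f, test_f = fractions
    if not np.isclose(train_f + val_f + test_f, 1.0):
        raise InvalidParameterError("fractions must sum to 1")
    by_class: dict[int, list[str]] = {}
    seen = set()
    for sid, label in subjects:
        if sid in seen:
            raise InvalidInputError(f"duplicate subject id {sid!r}")
        seen.add(sid)
        by_class.setdefault(int(label), []).append(sid)
    if len(by_class) < 2 or any(len(v) == 0 for v in by_class.values()):
        raise InvalidInputError("need at least one subject in each class")

    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for label in sorted(by_class):
        ids = sorted(by_class[label])
        rng.shuffle(ids)
        n = len(ids)
        n_test = int(np.floor(test_f * n))
        n_val = int(np.floor(val_f * n))
        for sid in ids[:n_test]:
            assignment[sid] = "test"
        for sid in ids[n_test : n_test + n_val]:
            assignment[sid] = "val"
        for sid in ids[n_test + n_val :]:
            assignment[sid] = "train"
    return SplitAssignment(assignment=assignment)
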
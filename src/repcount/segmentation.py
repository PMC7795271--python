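"""Peak detection on the energy envelope and single-motion segment extraction.

A sample is a motion peak when it is the strict maximum of a centered
sliding window (default 0.25 s — short enough that even the fastest
running cadence, just under four steps per second, puts at most one step
in a window).  The raw 3-axis data between two consecutive peaks is one
candidate motion segment; implausibly short or long candidates are
discarded by configurable duration bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core_signal import AccelSeries, EnergyEnvelope, odd_window_samples
from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "PeakList",
    "MotionSegment",
    "detect_peaks",
    "extract_segments",
    "segmentation_recall",
]

#: default admissible segment duration bounds, milliseconds
DEFAULT_MIN_MS = 80.0
DEFAULT_MAX_MS = 2000.0


@dataclass(frozen=True)
class PeakList:
    """Strictly increasing sample indices of detected motion peaks."""

    indices: np.ndarray
    window_samples: int = 0

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.intp)
        if idx.size > 1 and not np.all(np.diff(idx) > 0):
            raise InvalidInputError("peak indices must be strictly increasing")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class MotionSegment:
    """Raw 3-axis acceleration between two consecutive detected peaks.

    ``label`` is optional ground-truth/bookkeeping metadata (a template-class
    name on synthetic or annotated data); the runtime pipeline leaves it
    ``None``.
    """

    start_idx: int
    end_idx: int
    data: np.ndarray = field(repr=False)  # (n, 3) columns x, y, z
    fs: float
    position: str = "chest"
    label: str | None = None

    def __post_init__(self) -> None:
        if self.end_idx <= self.start_idx:
            raise InvalidInputError(
                f"segment [{self.start_idx}, {self.end_idx}) is empty or reversed"
            )
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[1] != 3:
            raise InvalidInputError(f"segment data must be (n, 3), got {data.shape}")
        if data.shape[0] != self.end_idx - self.start_idx:
            raise InvalidInputError(
                f"data length {data.shape[0]} != end-start "
                f"{self.end_idx - self.start_idx}"
            )
        object.__setattr__(self, "data", data)

    def __len__(self) -> int:
        return self.end_idx - self.start_idx

    @property
    def duration_ms(self) -> float:
        return 1000.0 * len(self) / self.fs

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start_idx + self.end_idx)


def detect_peaks(
    env: EnergyEnvelope,
    window_s: float = 0.25,
    min_height: float | None = None,
    min_height_frac: float | None = None,
) -> PeakList:
    """Strict-maximum peaks of the envelope under a centered sliding window.

    Index ``k`` is a peak iff ``env[k]`` is strictly greater than every
    other value in the centered window of ``odd_window_samples(window_s,
    fs)`` samples (ties never qualify), and, when a height floor is set,
    ``env[k] >= min_height`` and/or ``env[k] >= min_height_frac *
    max(env)``.  Both floors default to off — smoothing alone is then
    relied on to suppress small ripples, so low-level noise maxima in
    long quiet stretches *will* be reported.  Peaks closer than half a
    window to either end of the envelope are suppressed (no full window
    exists there).

    An envelope shorter than one window yields an empty list.
    """
    w = odd_window_samples(window_s, env.fs)
    if w < 3:
        raise InvalidParameterError(
            f"peak window must span >= 3 samples, got {w} at fs={env.fs}"
        )
    v = env.values
    n = len(v)
    if n < w:
        return PeakList(indices=np.empty(0, dtype=np.intp), window_samples=w)
    half = w // 2
    windows = sliding_window_view(v, w)  # (n - w + 1, w)
    center = v[half : n - half]
    wmax = windows.max(axis=1)
    n_at_max = (windows == wmax[:, None]).sum(axis=1)
    is_peak = (center == wmax) & (n_at_max == 1)
    if min_height is not None:
        is_peak &= center >= min_height
    if min_height_frac is not None:
        is_peak &= center >= min_height_frac * v.max()
    idx = np.flatnonzero(is_peak) + half
    return PeakList(indices=idx, window_samples=w)


def extract_segments(
    series: AccelSeries,
    peaks: PeakList,
    min_ms: float = DEFAULT_MIN_MS,
    max_ms: float = DEFAULT_MAX_MS,
) -> list[MotionSegment]:
    """Cut the raw stream at consecutive peaks and filter by duration.

    One candidate per consecutive peak pair ``[peaks[i], peaks[i+1])``;
    candidates whose duration falls outside ``[min_ms, max_ms]`` are
    dropped.  Fewer than two peaks yield an empty list.
    """
    if min_ms <= 0 or max_ms < min_ms:
        raise InvalidParameterError(f"bad duration bounds [{min_ms}, {max_ms}] ms")
    idx = peaks.indices
    segments: list[MotionSegment] = []
    data = series.as_array()
    for a, b in zip(idx[:-1], idx[1:]):
        duration_ms = 1000.0 * (b - a) / series.fs
        if min_ms <= duration_ms <= max_ms:
            segments.append(
                MotionSegment(
                    start_idx=int(a),
                    end_idx=int(b),
                    data=data[a:b],
                    fs=series.fs,
                    position=series.position.value,
                )
            )
    return segments


def segmentation_recall(
    segments: Sequence[MotionSegment],
    cycle_boundaries: Sequence[int] | np.ndarray,
    true_count: int | None = None,
) -> float:
    """Fraction of true motion cycles recovered by segmentation.

    A ground-truth cycle counts as recovered when at least one segment
    midpoint falls inside it; each cycle is matched at most once, and the
    ratio is capped at 1.0.  ``cycle_boundaries`` are the ``n_cycles + 1``
    sample indices delimiting the true cycles; ``true_count`` defaults to
    ``len(cycle_boundaries) - 1``.
    """
    bounds = np.asarray(cycle_boundaries, dtype=float)
    if true_count is None:
        true_count = len(bounds) - 1
    if true_count <= 0:
        raise InvalidInputError(f"true_count must be > 0, got {true_count}")
    matched: set[int] = set()
    for seg in segments:
        c = int(np.searchsorted(bounds, seg.midpoint, side="right")) - 1
        if 0 <= c < len(bounds) - 1:
            matched.add(c)
    return min(1.0, len(matched) / true_count)
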
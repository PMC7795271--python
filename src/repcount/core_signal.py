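"""Signal containers, magnitude computation and short-term-energy smoothing.

The motion-detection pipeline works on the combined magnitude ("synthetic
acceleration") of a 3-axis accelerometer stream.  Because the raw magnitude
is dominated by the ~1 g gravity offset and by sensor noise, a short-term
energy transform — a centered sliding mean of the squared, baseline-removed
magnitude — is applied before peak detection.  It emphasizes motion bursts
and smooths away small ripples so that one energy peak marks one motion.

All durations are specified in seconds and converted to sample counts by
rounding against the sampling rate ``fs``; windows are forced to an odd
number of samples so they can be centered exactly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "WearPosition",
    "AccelSeries",
    "MagnitudeSeries",
    "EnergyEnvelope",
    "compute_magnitude",
    "short_term_energy",
    "odd_window_samples",
]


class WearPosition(str, enum.Enum):
    """Body placement of the sensing device."""

    EAR = "ear"
    CHEST = "chest"
    UPPER_ARM = "upper_arm"
    WRIST = "wrist"


def _as_float_array(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError(f"{name} must be one-dimensional, got ndim={arr.ndim}")
    return arr


@dataclass(frozen=True)
class AccelSeries:
    """Uniformly sampled 3-axis acceleration record.

    Parameters
    ----------
    fs
        Sampling rate in Hz (> 0).
    x, y, z
        Equal-length per-axis acceleration in g.
    position
        Wear position of the device that produced the record.
    t0
        Time of the first sample in seconds; sample ``k`` is at
        ``t0 + k / fs``.
    """

    fs: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    position: WearPosition = WearPosition.CHEST
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", _as_float_array(self.x, "x"))
        object.__setattr__(self, "y", _as_float_array(self.y, "y"))
        object.__setattr__(self, "z", _as_float_array(self.z, "z"))
        object.__setattr__(self, "position", WearPosition(self.position))
        if self.fs <= 0:
            raise InvalidParameterError(f"fs must be > 0, got {self.fs}")
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise InvalidInputError(
                f"axis lengths differ: x={len(self.x)} y={len(self.y)} z={len(self.z)}"
            )

    def __len__(self) -> int:
        return len(self.x)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.fs

    def as_array(self) -> np.ndarray:
        """Return the signal as an ``(n, 3)`` array (columns x, y, z)."""
        return np.column_stack([self.x, self.y, self.z])

    def slice(self, start: int, end: int) -> "AccelSeries":
        """Half-open sample slice ``[start, end)`` as a new series."""
        return AccelSeries(
            fs=self.fs,
            x=self.x[start:end],
            y=self.y[start:end],
            z=self.z[start:end],
            position=self.position,
            t0=self.t0 + start / self.fs,
        )


@dataclass(frozen=True)
class MagnitudeSeries:
    """Per-sample Euclidean magnitude of a 3-axis signal, in g."""

    fs: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _as_float_array(self.values, "values"))
        if self.fs <= 0:
            raise InvalidParameterError(f"fs must be > 0, got {self.fs}")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class EnergyEnvelope:
    """Smoothed short-term energy of a magnitude series, in g^2."""

    fs: float
    values: np.ndarray = field(repr=False)
    window_s: float = 0.25

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _as_float_array(self.values, "values"))
        if self.fs <= 0:
            raise InvalidParameterError(f"fs must be > 0, got {self.fs}")

    def __len__(self) -> int:
        return len(self.values)


def odd_window_samples(window_s: float, fs: float) -> int:
    """Convert a duration to an odd, centered window length in samples.

    ``round(window_s * fs)`` rounded up to the next odd integer, so the
    window has a well-defined center sample.
    """
    if window_s <= 0:
        raise InvalidParameterError(f"window_s must be > 0, got {window_s}")
    w = int(round(window_s * fs))
    if w < 1:
        raise InvalidParameterError(
            f"window of {window_s} s is shorter than one sample at fs={fs} Hz"
        )
    return w if w % 2 == 1 else w + 1


def compute_magnitude(series: AccelSeries) -> MagnitudeSeries:
    """Per-sample Euclidean norm sqrt(x^2 + y^2 + z^2) of a 3-axis series."""
    if len(series) == 0:
        raise InvalidInputError("cannot compute magnitude of an empty series")
    values = np.sqrt(series.x**2 + series.y**2 + series.z**2)
    return MagnitudeSeries(fs=series.fs, values=values)


def short_term_energy(
    mag: MagnitudeSeries,
    window_s: float = 0.25,
    detrend_s: float | None = 1.0,
) -> EnergyEnvelope:
    """Centered sliding mean of the squared, baseline-removed magnitude.

    The baseline is a centered moving average over ``detrend_s`` seconds; it
    removes the ~1 g gravity offset so that small motions are not swamped by
    the static component.  Pass ``detrend_s=None`` to disable baseline
    removal.  Both windows use reflect padding at the edges, so the output
    has the same length as the input.

    Parameters
    ----------
    mag
        Magnitude series to transform.
    window_s
        Energy window length in seconds (must cover >= 1 sample).
    detrend_s
        Baseline window length in seconds, or ``None`` to disable
        detrending.  Must be >= ``window_s`` when enabled.
    """
    if len(mag) == 0:
        raise InvalidInputError("cannot compute energy of an empty series")
    w = odd_window_samples(window_s, mag.fs)
    values = mag.values
    if detrend_s is not None:
        if detrend_s < window_s:
            raise InvalidParameterError(
                f"detrend_s={detrend_s} must be >= window_s={window_s} (or None)"
            )
        dw = odd_window_samples(detrend_s, mag.fs)
        baseline = uniform_filter1d(values, size=dw, mode="reflect")
        deviation = values - baseline
    else:
        deviation = values
    energy = uniform_filter1d(deviation**2, size=w, mode="reflect")
    # mean of squares is non-negative; clip away negative rounding dust
    np.clip(energy, 0.0, None, out=energy)
    return EnergyEnvelope(fs=mag.fs, values=energy, window_s=window_s)
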
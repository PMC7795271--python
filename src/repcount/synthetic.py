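"""Parametric generator of labeled multi-position accelerometer recordings.

The study data this package targets (five exercises — running, walking,
jumping, push-ups, sit-ups — recorded at ear, chest, upper arm and wrist)
are not publicly available, so every pipeline stage is exercised against
this generator instead.  It renders each exercise as a stylized
amplitude-modulated oscillation in a body frame:

* one motion cycle = one repetition (one step, one jump, ...);
* per-cycle duration and amplitude are jittered around the exercise's
  base period (coefficient-of-variation parameters);
* a unimodal energy envelope per cycle guarantees one dominant energy
  peak per motion — except the sit-up, whose renderer emits three energy
  bumps per cycle with a migrating dominant axis (the circular trunk
  motion), reproducing the known multi-peak segmentation hazard; the
  rising "wake-up" span is the canonical sit-up motion;
* a fixed per-position transform (rotation, attenuation, arm-swing with
  right/left asymmetry at arm and wrist, extra bob noise at the ear) maps
  the body frame to each sensor frame, plus 1 g of gravity along the
  transformed vertical and white Gaussian noise.

Ground truth records every cycle span, its label and stride side, the
analytic energy-peak sample, and the per-cycle *motion window* (the
peak-to-peak span of the canonical motion; for sit-ups the wake-up span) —
enough to score segmentation recall and to build labeled segment pools.

All randomness flows from ``numpy.random.default_rng`` (the PCG64
generator), seeded explicitly; identical seeds give bit-identical output.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.spatial.transform import Rotation

from .classification import (
    ExerciseLabel,
    Registry,
    Template,
    TemplateClass,
    build_registry,
    required_classes,
)
from .core_signal import AccelSeries, WearPosition
from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "ExerciseWaveformSpec",
    "PositionTransform",
    "GroundTruth",
    "CyclePlan",
    "DEFAULT_SPECS",
    "DEFAULT_TRANSFORMS",
    "DEFAULT_CIRCUIT_REPS",
    "DEFAULT_FS",
    "plan_cycles",
    "generate_exercise",
    "generate_circuit",
    "render_template",
    "default_template_bank",
]

DEFAULT_FS = 100.0
GAIT_LABELS = (ExerciseLabel.RUNNING, ExerciseLabel.WALKING)

_SHAPES = ("impulse_train", "sinusoid", "asymmetric_ramp", "axis_rotation")


@dataclass(frozen=True)
class ExerciseWaveformSpec:
    """Waveform model of one exercise in the body frame.

    ``amplitude_g`` is the per-axis peak motion amplitude (x lateral,
    y fore-aft, z vertical).  ``carrier_cycles`` oscillations per motion
    give the signal its in-burst structure; ``envelope_floor`` keeps a
    small residual motion between bursts; ``peak_phase`` locates the
    energy maximum inside the cycle.  ``tempo_jitter`` and
    ``amplitude_jitter`` are coefficients of variation of the per-cycle
    duration and amplitude; ``noise_sd`` is the white-noise level in g.
    """

    label: ExerciseLabel
    shape: str
    base_period_s: float
    amplitude_g: tuple[float, float, float]
    peak_phase: float = 0.3
    carrier_cycles: int = 3
    envelope_floor: float = 0.15
    envelope_power: float = 1.0
    width: float = 0.1
    tempo_jitter: float = 0.1
    amplitude_jitter: float = 0.1
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", ExerciseLabel(self.label))
        if self.shape not in _SHAPES:
            raise ConfigurationError(f"unknown shape '{self.shape}'; one of {_SHAPES}")
        if self.base_period_s <= 0:
            raise ConfigurationError(f"base_period_s must be > 0, got {self.base_period_s}")
        if self.tempo_jitter < 0 or self.amplitude_jitter < 0 or self.noise_sd < 0:
            raise ConfigurationError("jitters and noise_sd must be >= 0")
        if not 0.0 < self.peak_phase < 1.0:
            raise ConfigurationError(f"peak_phase must be in (0, 1), got {self.peak_phase}")
        if self.label is ExerciseLabel.SIT_UP and self.shape != "axis_rotation":
            raise ConfigurationError("the sit-up spec must use the axis_rotation shape")


@dataclass(frozen=True)
class PositionTransform:
    """Body-frame to sensor-frame mapping for one wear position."""

    position: WearPosition
    rotation: np.ndarray = field(repr=False)  # 3x3 orthonormal
    attenuation: tuple[float, float, float] = (1.0, 1.0, 1.0)
    swing_amplitude_g: float = 0.0  # gait arm-swing added on the sensor y axis
    side_asymmetry: float = 0.0  # right/left gain split of the arm swing (arm/wrist)
    bob_noise_sd: float = 0.0  # extra noise (loose ear mount)

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", WearPosition(self.position))
        rot = np.asarray(self.rotation, dtype=float)
        if rot.shape != (3, 3) or not np.allclose(rot @ rot.T, np.eye(3), atol=1e-9):
            raise ConfigurationError("rotation must be a 3x3 orthonormal matrix")
        object.__setattr__(self, "rotation", rot)
        if any(a <= 0 for a in self.attenuation):
            raise ConfigurationError("attenuations must be > 0")

    @property
    def gravity_vector(self) -> np.ndarray:
        """1 g of gravity expressed in the sensor frame."""
        return self.rotation @ np.array([0.0, 0.0, 1.0])

    @property
    def swing_direction(self) -> np.ndarray:
        """Sensor-frame arm-swing direction: the y axis made orthogonal to
        gravity, so the swing shapes the 3-axis waveform without
        dominating the magnitude envelope."""
        g = self.gravity_vector
        y = np.array([0.0, 1.0, 0.0])
        d = y - (y @ g) * g
        n = np.linalg.norm(d)
        if n < 1e-6:  # y axis happens to be vertical; fall back to x
            d = np.array([1.0, 0.0, 0.0]) - g[0] * g
            n = np.linalg.norm(d)
        return d / n

    def side_gain(self, side: str) -> float:
        if side == "right":
            return 1.0 - 0.5 * self.side_asymmetry
        if side == "left":
            return 1.0 + 0.5 * self.side_asymmetry
        return 1.0


@dataclass(frozen=True)
class GroundTruth:
    """Per-cycle annotations of a generated recording.

    ``starts``/``ends`` are half-open cycle spans in samples; consecutive
    cycles of one bout are contiguous, while circuit recordings leave rest
    gaps between exercises that belong to no cycle.
    """

    starts: np.ndarray
    ends: np.ndarray
    labels: tuple[str, ...]  # per-cycle exercise label
    sides: tuple[str, ...]  # per-cycle stride side: right | left | none
    peak_samples: np.ndarray  # analytic main energy-peak index per cycle
    motion_windows: np.ndarray  # (n_cycles, 2) canonical motion spans
    counts: dict[str, int]
    fs: float

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=np.intp)
        ends = np.asarray(self.ends, dtype=np.intp)
        if np.any(ends <= starts) or np.any(np.diff(starts) <= 0):
            raise InvalidInputError("cycle spans must be increasing and non-empty")
        if np.any(starts[1:] < ends[:-1]):
            raise InvalidInputError("cycle spans must not overlap")
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        object.__setattr__(self, "peak_samples", np.asarray(self.peak_samples, dtype=np.intp))
        object.__setattr__(self, "motion_windows", np.asarray(self.motion_windows, dtype=np.intp))
        n = len(starts)
        if not (len(self.labels) == len(self.sides) == len(ends) == n == len(self.motion_windows)):
            raise InvalidInputError("per-cycle annotation lengths are inconsistent")
        if dict(Counter(self.labels)) != {k: v for k, v in self.counts.items() if v}:
            raise InvalidInputError("counts are inconsistent with the cycle labels")

    @property
    def n_cycles(self) -> int:
        return len(self.starts)

    @property
    def boundaries(self) -> np.ndarray:
        """Boundary list ``[starts..., last end]`` for contiguous recordings."""
        return np.concatenate([self.starts, self.ends[-1:]])

    def cycle_of_sample(self, sample: float) -> int:
        """Index of the cycle containing ``sample``, or -1 if in no cycle."""
        i = int(np.searchsorted(self.starts, sample, side="right")) - 1
        if 0 <= i < self.n_cycles and sample < self.ends[i]:
            return i
        return -1


@dataclass(frozen=True)
class CyclePlan:
    """Seeded per-cycle timing shared by all position renderings."""

    label: ExerciseLabel
    durations_s: np.ndarray
    amp_scales: np.ndarray
    sides: tuple[str, ...]


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

DEFAULT_SPECS: dict[ExerciseLabel, ExerciseWaveformSpec] = {
    ExerciseLabel.RUNNING: ExerciseWaveformSpec(
        label=ExerciseLabel.RUNNING, shape="impulse_train", base_period_s=0.35,
        amplitude_g=(0.5, 0.8, 2.2), peak_phase=0.25, carrier_cycles=3,
        envelope_floor=0.15, envelope_power=3.0, tempo_jitter=0.08,
    ),
    ExerciseLabel.WALKING: ExerciseWaveformSpec(
        label=ExerciseLabel.WALKING, shape="sinusoid", base_period_s=0.6,
        amplitude_g=(0.3, 0.5, 0.9), peak_phase=0.37, carrier_cycles=6,
        envelope_floor=0.2, envelope_power=2.0, tempo_jitter=0.08,
    ),
    ExerciseLabel.JUMPING: ExerciseWaveformSpec(
        label=ExerciseLabel.JUMPING, shape="asymmetric_ramp", base_period_s=0.7,
        amplitude_g=(0.4, 0.6, 2.8), peak_phase=0.25, carrier_cycles=7,
        envelope_floor=0.08, width=0.22, tempo_jitter=0.08,
    ),
    ExerciseLabel.PUSH_UP: ExerciseWaveformSpec(
        label=ExerciseLabel.PUSH_UP, shape="sinusoid", base_period_s=1.1,
        amplitude_g=(0.3, 0.9, 0.5), peak_phase=0.31, carrier_cycles=11,
        envelope_floor=0.25, envelope_power=2.0, tempo_jitter=0.15,
    ),
    ExerciseLabel.SIT_UP: ExerciseWaveformSpec(
        label=ExerciseLabel.SIT_UP, shape="axis_rotation", base_period_s=0.9,
        amplitude_g=(0.15, 1.2, 1.2), peak_phase=0.745, carrier_cycles=9,
        envelope_floor=0.08, tempo_jitter=0.1,
    ),
}

#: sit-up sub-bump structure: (phase, relative amplitude, width in cycles);
#: the third (largest) bump starts the wake-up motion.  Bump centers sit on
#: carrier antinodes ((2k+1)/(4*carrier_cycles)) so no bump is nulled.
_SITUP_BUMPS = ((0.085, 0.5, 0.05), (0.415, 0.55, 0.05), (0.745, 1.0, 0.075))
#: the wake-up span runs from the third bump to the next cycle's first bump
_SITUP_WAKEUP = (0.745, 1.085)


def _rotation(deg_xyz) -> np.ndarray:
    return Rotation.from_euler("xyz", deg_xyz, degrees=True).as_matrix()


DEFAULT_TRANSFORMS: dict[WearPosition, PositionTransform] = {
    WearPosition.CHEST: PositionTransform(
        position=WearPosition.CHEST, rotation=np.eye(3),
    ),
    WearPosition.EAR: PositionTransform(
        position=WearPosition.EAR, rotation=_rotation([8.0, -5.0, 3.0]),
        attenuation=(0.5, 0.5, 0.55), bob_noise_sd=0.02,
    ),
    WearPosition.UPPER_ARM: PositionTransform(
        position=WearPosition.UPPER_ARM, rotation=_rotation([25.0, 10.0, -15.0]),
        attenuation=(0.8, 0.85, 0.8), swing_amplitude_g=0.2, side_asymmetry=0.5,
    ),
    WearPosition.WRIST: PositionTransform(
        position=WearPosition.WRIST, rotation=_rotation([40.0, -20.0, 30.0]),
        attenuation=(0.7, 0.75, 0.7), swing_amplitude_g=0.3, side_asymmetry=0.6,
        bob_noise_sd=0.01,
    ),
}

#: circuit repetitions: >20 steps of each gait, ~10 reps of the others
DEFAULT_CIRCUIT_REPS: dict[ExerciseLabel, int] = {
    ExerciseLabel.RUNNING: 24,
    ExerciseLabel.WALKING: 24,
    ExerciseLabel.JUMPING: 10,
    ExerciseLabel.PUSH_UP: 10,
    ExerciseLabel.SIT_UP: 10,
}


# ---------------------------------------------------------------------------
# waveform rendering
# ---------------------------------------------------------------------------

def _raised_cosine(phase: np.ndarray, peak: float) -> np.ndarray:
    """Periodic unimodal envelope in [0, 1], maximal at ``peak``."""
    return 0.5 * (1.0 + np.cos(2.0 * np.pi * (phase - peak)))


def _wrapped_offset(phase: np.ndarray, center: float) -> np.ndarray:
    return (phase - center + 0.5) % 1.0 - 0.5


def _cycle_motion(spec: ExerciseWaveformSpec, phase: np.ndarray) -> np.ndarray:
    """Body-frame motion of one cycle at unit amplitude scale, shape (n, 3)."""
    carrier = np.sin(2.0 * np.pi * spec.carrier_cycles * phase)
    floor = spec.envelope_floor
    if spec.shape in ("impulse_train", "sinusoid"):
        env = floor + (1.0 - floor) * _raised_cosine(phase, spec.peak_phase) ** spec.envelope_power
        return np.outer(env * carrier, spec.amplitude_g)
    if spec.shape == "asymmetric_ramp":
        d = _wrapped_offset(phase, spec.peak_phase)
        sigma = np.where(d < 0, 0.27 * spec.width, spec.width)
        env = floor + (1.0 - floor) * np.exp(-0.5 * (d / sigma) ** 2)
        return np.outer(env * carrier, spec.amplitude_g)
    # axis_rotation (sit-up): three bumps, direction migrating z -> y
    env = np.full_like(phase, floor)
    for p, amp, w in _SITUP_BUMPS:
        env = env + amp * np.exp(-0.5 * (_wrapped_offset(phase, p) / w) ** 2)
    theta = 0.5 * np.pi * phase
    ax, ay, az = spec.amplitude_g
    direction = np.column_stack(
        [np.full_like(phase, ax), ay * np.sin(theta), az * np.cos(theta)]
    )
    return (env * carrier)[:, None] * direction


def plan_cycles(
    spec: ExerciseWaveformSpec, n_reps: int, rng: np.random.Generator
) -> CyclePlan:
    """Draw the seeded per-cycle durations, amplitude scales and stride sides."""
    if n_reps < 1:
        raise ConfigurationError(f"n_reps must be >= 1, got {n_reps}")
    durations = spec.base_period_s * np.clip(
        1.0 + spec.tempo_jitter * rng.standard_normal(n_reps), 0.3, None
    )
    amp_scales = np.clip(
        1.0 + spec.amplitude_jitter * rng.standard_normal(n_reps), 0.1, None
    )
    if spec.label in GAIT_LABELS:
        sides = tuple("right" if k % 2 == 0 else "left" for k in range(n_reps))
    else:
        sides = ("none",) * n_reps
    return CyclePlan(label=spec.label, durations_s=durations, amp_scales=amp_scales, sides=sides)


def _render_cycles(
    plan: CyclePlan,
    spec: ExerciseWaveformSpec,
    transform: PositionTransform,
    fs: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free sensor-frame motion of all cycles; returns (signal, boundaries)."""
    lengths = np.maximum(2, np.round(plan.durations_s * fs).astype(int))
    boundaries = np.concatenate([[0], np.cumsum(lengths)])
    rot_t = transform.rotation.T
    atten = np.asarray(transform.attenuation)
    chunks = []
    gait = spec.label in GAIT_LABELS
    for n_k, scale, side in zip(lengths, plan.amp_scales, plan.sides):
        phase = (np.arange(n_k) + 0.5) / n_k
        body = _cycle_motion(spec, phase) * scale
        gain = transform.side_gain(side)
        sensor = (body @ rot_t) * atten
        if gait and transform.swing_amplitude_g > 0.0:
            swing = (
                transform.swing_amplitude_g
                * gain
                * _raised_cosine(phase, spec.peak_phase) ** 2
                * np.sin(2.0 * np.pi * spec.carrier_cycles * phase)
            )
            sensor += swing[:, None] * transform.swing_direction
        chunks.append(sensor)
    motion = np.concatenate(chunks, axis=0)
    # smooth onset/offset taper (half a cycle) so the bout edges do not
    # produce an energy step that the peak detector would pick up
    n_head = int(lengths[0] // 2)
    n_tail = int(lengths[-1] // 2)
    if n_head > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * (np.arange(n_head) + 0.5) / n_head))
        motion[:n_head] *= ramp[:, None]
    if n_tail > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * (np.arange(n_tail) + 0.5) / n_tail))
        motion[-n_tail:] *= ramp[::-1, None]
    return motion, boundaries


def _cycle_annotations(
    spec: ExerciseWaveformSpec, boundaries: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic main-peak samples and motion windows per cycle.

    ``boundaries`` already carries any global sample offset; the motion
    window of the last cycle is truncated at the bout's end.
    """
    lengths = np.diff(boundaries)
    peaks = boundaries[:-1] + np.round(spec.peak_phase * lengths).astype(int)
    if spec.shape == "axis_rotation":
        w0, w1 = _SITUP_WAKEUP
        starts = boundaries[:-1] + np.round(w0 * lengths).astype(int)
        ends = np.empty_like(starts)
        ends[:-1] = boundaries[1:-1] + np.round((w1 - 1.0) * lengths[1:]).astype(int)
        ends[-1] = boundaries[-1]
    else:
        starts = peaks
        ends = np.empty_like(starts)
        ends[:-1] = peaks[1:]
        ends[-1] = boundaries[-1]
    return peaks, np.column_stack([starts, ends])


def generate_exercise(
    spec: ExerciseWaveformSpec,
    transform: PositionTransform,
    n_reps: int,
    fs: float = DEFAULT_FS,
    seed: int = 0,
    pad_s: float = 0.5,
) -> tuple[AccelSeries, GroundTruth]:
    """Render one exercise bout at one position, with per-cycle ground truth.

    The recording is padded with ``pad_s`` seconds of quiet standing
    (gravity + noise) on both sides so that edge motions keep a full peak
    detection window.  A fixed ``seed`` makes the output bit-reproducible.
    """
    rng = np.random.default_rng(seed)
    plan = plan_cycles(spec, n_reps, rng)
    motion, boundaries = _render_cycles(plan, spec, transform, fs)
    pad = int(round(pad_s * fs))
    n_active = motion.shape[0]
    signal = np.zeros((n_active + 2 * pad, 3))
    signal[pad : pad + n_active] = motion
    signal += transform.gravity_vector
    if spec.noise_sd > 0.0:
        sd = float(np.hypot(spec.noise_sd, transform.bob_noise_sd))
        signal += rng.normal(0.0, sd, size=signal.shape)
    peaks, windows = _cycle_annotations(spec, boundaries + pad)
    truth = GroundTruth(
        starts=boundaries[:-1] + pad,
        ends=boundaries[1:] + pad,
        labels=(spec.label.value,) * n_reps,
        sides=plan.sides,
        peak_samples=peaks,
        motion_windows=windows,
        counts={spec.label.value: n_reps},
        fs=fs,
    )
    series = AccelSeries(
        fs=fs, x=signal[:, 0], y=signal[:, 1], z=signal[:, 2], position=transform.position
    )
    return series, truth


def generate_circuit(
    specs: Mapping[ExerciseLabel, ExerciseWaveformSpec] | None = None,
    transforms: Mapping[WearPosition, PositionTransform] | None = None,
    n_reps: Mapping[ExerciseLabel, int] | None = None,
    fs: float = DEFAULT_FS,
    order_seed: int = 0,
    rest_s: float = 3.0,
    rest_noise_sd: float = 0.02,
) -> dict[WearPosition, tuple[AccelSeries, GroundTruth]]:
    """One seeded-random-order circuit of the five exercises at every position.

    The exercise order and all cycle timing are drawn once and shared by
    every position (the devices record the same physical movement), while
    sensor noise is drawn independently per position.  Exercises are
    separated by ``rest_s`` seconds of quiet standing (gravity + noise).
    """
    specs = dict(DEFAULT_SPECS) if specs is None else dict(specs)
    transforms = dict(DEFAULT_TRANSFORMS) if transforms is None else dict(transforms)
    n_reps = dict(DEFAULT_CIRCUIT_REPS) if n_reps is None else dict(n_reps)
    root = np.random.SeedSequence(order_seed)
    order_seq, plan_seq, noise_seq = root.spawn(3)
    order_rng = np.random.default_rng(order_seq)
    labels = list(specs)
    order = [labels[i] for i in order_rng.permutation(len(labels))]
    plan_rng = np.random.default_rng(plan_seq)
    plans = {label: plan_cycles(specs[label], n_reps[label], plan_rng) for label in order}
    noise_seeds = dict(zip(transforms, noise_seq.spawn(len(transforms))))

    rest_n = int(round(rest_s * fs))
    out: dict[WearPosition, tuple[AccelSeries, GroundTruth]] = {}
    for pos, transform in transforms.items():
        noise_rng = np.random.default_rng(noise_seeds[pos])
        chunks: list[np.ndarray] = [np.zeros((rest_n, 3))]
        noise_sds: list[tuple[int, float]] = [(rest_n, rest_noise_sd)]
        starts_all: list[np.ndarray] = []
        ends_all: list[np.ndarray] = []
        labels_all: list[str] = []
        sides_all: list[str] = []
        peaks_all: list[np.ndarray] = []
        windows_all: list[np.ndarray] = []
        offset = rest_n
        for label in order:
            spec = specs[label]
            motion, boundaries = _render_cycles(plans[label], spec, transform, fs)
            peaks, windows = _cycle_annotations(spec, boundaries + offset)
            chunks.append(motion)
            noise_sds.append((motion.shape[0], spec.noise_sd))
            starts_all.append(boundaries[:-1] + offset)
            ends_all.append(boundaries[1:] + offset)
            labels_all.extend([label.value] * plans[label].durations_s.size)
            sides_all.extend(plans[label].sides)
            peaks_all.append(peaks)
            windows_all.append(windows)
            offset += motion.shape[0]
            chunks.append(np.zeros((rest_n, 3)))
            noise_sds.append((rest_n, rest_noise_sd))
            offset += rest_n
        signal = np.concatenate(chunks, axis=0) + transform.gravity_vector
        for (n_span, sd), start in zip(
            noise_sds, np.concatenate([[0], np.cumsum([n for n, _ in noise_sds])])
        ):
            sd_eff = float(np.hypot(sd, transform.bob_noise_sd))
            if sd_eff > 0.0:
                signal[start : start + n_span] += noise_rng.normal(
                    0.0, sd_eff, size=(n_span, 3)
                )
        truth = GroundTruth(
            starts=np.concatenate(starts_all),
            ends=np.concatenate(ends_all),
            labels=tuple(labels_all),
            sides=tuple(sides_all),
            peak_samples=np.concatenate(peaks_all),
            motion_windows=np.concatenate(windows_all),
            counts={label.value: n_reps[label] for label in order},
            fs=fs,
        )
        series = AccelSeries(
            fs=fs, x=signal[:, 0], y=signal[:, 1], z=signal[:, 2], position=pos
        )
        out[pos] = (series, truth)
    return out


# ---------------------------------------------------------------------------
# template bank
# ---------------------------------------------------------------------------

_CLASS_SIDE = {
    TemplateClass.RUNNING: (ExerciseLabel.RUNNING, "none"),
    TemplateClass.RUNNING_RIGHT: (ExerciseLabel.RUNNING, "right"),
    TemplateClass.RUNNING_LEFT: (ExerciseLabel.RUNNING, "left"),
    TemplateClass.WALKING: (ExerciseLabel.WALKING, "none"),
    TemplateClass.WALKING_RIGHT: (ExerciseLabel.WALKING, "right"),
    TemplateClass.WALKING_LEFT: (ExerciseLabel.WALKING, "left"),
    TemplateClass.JUMPING: (ExerciseLabel.JUMPING, "none"),
    TemplateClass.PUSH_UP: (ExerciseLabel.PUSH_UP, "none"),
    TemplateClass.SIT_UP: (ExerciseLabel.SIT_UP, "none"),
}


def render_template(
    template_class: TemplateClass,
    transform: PositionTransform,
    fs: float = DEFAULT_FS,
    specs: Mapping[ExerciseLabel, ExerciseWaveformSpec] | None = None,
) -> Template:
    """One noiseless, jitter-free single-motion template rendering.

    A short exactly periodic bout is rendered and segmented by the
    pipeline's own peak detector — mirroring how a user records a
    template motion — and the inter-peak slice starting at the central
    cycle's main energy peak is kept: one stride / jump / push-up, or the
    sit-up wake-up span.
    """
    # local import: segmentation sits above this module in the pipeline
    from .core_signal import compute_magnitude, short_term_energy
    from .segmentation import detect_peaks

    specs = DEFAULT_SPECS if specs is None else specs
    label, side = _CLASS_SIDE[TemplateClass(template_class)]
    spec = replace(specs[label], tempo_jitter=0.0, amplitude_jitter=0.0, noise_sd=0.0)
    n_cycles = 5
    n_k = max(2, int(round(spec.base_period_s * fs)))
    plan = CyclePlan(
        label=label,
        durations_s=np.full(n_cycles, spec.base_period_s),
        amp_scales=np.ones(n_cycles),
        sides=(side,) * n_cycles,
    )
    motion, boundaries = _render_cycles(plan, spec, transform, fs)
    motion = motion + transform.gravity_vector
    series = AccelSeries(
        fs=fs, x=motion[:, 0], y=motion[:, 1], z=motion[:, 2],
        position=transform.position,
    )
    env = short_term_energy(compute_magnitude(series))
    peaks = detect_peaks(env).indices
    if len(peaks) < 2:
        raise ConfigurationError(
            f"template rendering for {TemplateClass(template_class).value} at "
            f"{transform.position.value} produced {len(peaks)} energy peaks"
        )
    # main energy peak of the central cycle (cycle index 2 of 5)
    anchor = boundaries[2] + int(round(spec.peak_phase * n_k))
    i = int(np.argmin(np.abs(peaks - anchor)))
    if i + 1 >= len(peaks):
        i = len(peaks) - 2
    return Template(
        template_class=template_class,
        position=transform.position,
        fs=fs,
        data=motion[peaks[i] : peaks[i + 1]],
    )


def default_template_bank(
    fs: float = DEFAULT_FS,
    seed: int = 0,
    specs: Mapping[ExerciseLabel, ExerciseWaveformSpec] | None = None,
    transforms: Mapping[WearPosition, PositionTransform] | None = None,
) -> dict[WearPosition, Registry]:
    """Noiseless single-motion template registries for all four positions.

    The renderings are deterministic; ``seed`` is accepted for interface
    symmetry with the other generators and does not alter the output.
    """
    del seed  # deterministic by construction
    transforms = DEFAULT_TRANSFORMS if transforms is None else transforms
    bank: dict[WearPosition, Registry] = {}
    for pos, transform in transforms.items():
        templates = [
            render_template(tc, transform, fs=fs, specs=specs)
            for tc in required_classes(pos)
        ]
        bank[pos] = build_registry(templates, pos)
    return bank
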
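"""Minimum-DTW template classification of motion segments.

Each extracted segment is compared, as a 3-axis sequence, against one
pre-recorded template per exercise class for the segment's wear position;
the class with the minimum dynamic-time-warping distance wins.  The DTW
recurrence is the classic unnormalized form

    D[i, j] = cost(i, j) + min(D[i-1, j], D[i, j-1], D[i-1, j-1])

with Euclidean per-cell cost ||s_i - t_j|| over the 3-vectors, D[0, 0] = 0
and an infinite first row/column; the returned distance is D[n, m] with no
path-length normalization and no warping-window constraint.

Ear- and chest-mounted sensors cannot tell a right step from a left step,
so those registries carry five templates (one per exercise).  Arm and wrist
motion differs between strides, so those registries split running and
walking into right/left variants — seven templates — whose predictions are
merged back to the five exercise labels for reporting.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .core_signal import WearPosition
from .errors import ConfigurationError, InvalidInputError
from .segmentation import MotionSegment

__all__ = [
    "ExerciseLabel",
    "TemplateClass",
    "Template",
    "Registry",
    "ClassificationResult",
    "dtw_distance",
    "merge_class",
    "required_classes",
    "build_registry",
    "classify_segment",
]


class ExerciseLabel(str, enum.Enum):
    """The five target exercises."""

    RUNNING = "running"
    WALKING = "walking"
    JUMPING = "jumping"
    PUSH_UP = "push_up"
    SIT_UP = "sit_up"


class TemplateClass(str, enum.Enum):
    """Template identities, including the right/left gait split.

    Arm/wrist registries use the seven side-split classes; ear/chest
    registries use the five merged ones.
    """

    RUNNING = "running"
    RUNNING_RIGHT = "running_right"
    RUNNING_LEFT = "running_left"
    WALKING = "walking"
    WALKING_RIGHT = "walking_right"
    WALKING_LEFT = "walking_left"
    JUMPING = "jumping"
    PUSH_UP = "push_up"
    SIT_UP = "sit_up"


_MERGE: dict[TemplateClass, ExerciseLabel] = {
    TemplateClass.RUNNING: ExerciseLabel.RUNNING,
    TemplateClass.RUNNING_RIGHT: ExerciseLabel.RUNNING,
    TemplateClass.RUNNING_LEFT: ExerciseLabel.RUNNING,
    TemplateClass.WALKING: ExerciseLabel.WALKING,
    TemplateClass.WALKING_RIGHT: ExerciseLabel.WALKING,
    TemplateClass.WALKING_LEFT: ExerciseLabel.WALKING,
    TemplateClass.JUMPING: ExerciseLabel.JUMPING,
    TemplateClass.PUSH_UP: ExerciseLabel.PUSH_UP,
    TemplateClass.SIT_UP: ExerciseLabel.SIT_UP,
}

#: canonical registry (and tie-break) order per position family
MERGED_CLASSES: tuple[TemplateClass, ...] = (
    TemplateClass.RUNNING,
    TemplateClass.WALKING,
    TemplateClass.JUMPING,
    TemplateClass.PUSH_UP,
    TemplateClass.SIT_UP,
)
SIDE_SPLIT_CLASSES: tuple[TemplateClass, ...] = (
    TemplateClass.RUNNING_RIGHT,
    TemplateClass.RUNNING_LEFT,
    TemplateClass.WALKING_RIGHT,
    TemplateClass.WALKING_LEFT,
    TemplateClass.JUMPING,
    TemplateClass.PUSH_UP,
    TemplateClass.SIT_UP,
)


def merge_class(tc: TemplateClass) -> ExerciseLabel:
    """Collapse right/left gait template classes to their exercise label."""
    return _MERGE[TemplateClass(tc)]


def required_classes(position: WearPosition) -> tuple[TemplateClass, ...]:
    """Template classes a registry must cover for a wear position."""
    position = WearPosition(position)
    if position in (WearPosition.EAR, WearPosition.CHEST):
        return MERGED_CLASSES
    return SIDE_SPLIT_CLASSES


# ---------------------------------------------------------------------------
# dynamic time warping
# ---------------------------------------------------------------------------

def _dtw_accumulate(cost: np.ndarray) -> float:
    n, m = cost.shape
    prev = np.full(m + 1, np.inf)
    curr = np.full(m + 1, np.inf)
    prev[0] = 0.0
    for i in range(n):
        curr[0] = np.inf
        for j in range(m):
            best = prev[j]
            if prev[j + 1] < best:
                best = prev[j + 1]
            if curr[j] < best:
                best = curr[j]
            curr[j + 1] = cost[i, j] + best
        prev, curr = curr, prev
    return prev[m]


try:  # JIT-compile the O(n*m) inner loop; fall back to pure Python
    from numba import njit

    _dtw_accumulate_fast = njit(cache=True)(_dtw_accumulate)
except ImportError:  # pragma: no cover - numba is a declared dependency
    _dtw_accumulate_fast = _dtw_accumulate


def _as_seq3(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise InvalidInputError(f"{name} must be a (n, d) sequence, got ndim={arr.ndim}")
    if arr.shape[0] == 0:
        raise InvalidInputError(f"{name} is empty")
    return arr


def dtw_distance(s, t, normalize: bool = False) -> float:
    """Unnormalized DTW distance between two multi-axis sequences.

    Parameters
    ----------
    s, t
        Arrays of shape ``(n, d)`` (1-D input is treated as ``d = 1``);
        both must share ``d`` and be non-empty.
    normalize
        If True, divide the accumulated distance by ``n + m`` — an
        optional experimentation mode; the classifier default is the raw
        accumulated distance.
    """
    s = _as_seq3(s, "s")
    t = _as_seq3(t, "t")
    if s.shape[1] != t.shape[1]:
        raise InvalidInputError(
            f"dimension mismatch: s has {s.shape[1]} axes, t has {t.shape[1]}"
        )
    diff = s[:, None, :] - t[None, :, :]
    cost = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    d = float(_dtw_accumulate_fast(cost))
    if normalize:
        d /= s.shape[0] + t.shape[0]
    return d


# ---------------------------------------------------------------------------
# templates and registries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Template:
    """One pre-recorded single-motion reference per class and position."""

    template_class: TemplateClass
    position: WearPosition
    fs: float
    data: np.ndarray = field(repr=False)  # (n, 3)

    def __post_init__(self) -> None:
        object.__setattr__(self, "template_class", TemplateClass(self.template_class))
        object.__setattr__(self, "position", WearPosition(self.position))
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[1] != 3 or data.shape[0] < 2:
            raise InvalidInputError(
                f"template data must be (n >= 2, 3), got {data.shape}"
            )
        object.__setattr__(self, "data", data)

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class Registry:
    """A validated, canonically ordered template set for one position."""

    position: WearPosition
    templates: tuple[Template, ...]

    def __len__(self) -> int:
        return len(self.templates)

    def __iter__(self):
        return iter(self.templates)

    def get(self, tc: TemplateClass) -> Template:
        for tpl in self.templates:
            if tpl.template_class == tc:
                return tpl
        raise KeyError(tc)


def build_registry(templates: Iterable[Template], position: WearPosition) -> Registry:
    """Validate an exact one-template-per-class cover and order it canonically.

    Raises :class:`ConfigurationError` naming any missing, duplicated or
    unexpected classes for the position.
    """
    position = WearPosition(position)
    required = required_classes(position)
    by_class: dict[TemplateClass, Template] = {}
    duplicates: list[str] = []
    wrong_position: list[str] = []
    for tpl in templates:
        if tpl.position != position:
            wrong_position.append(tpl.template_class.value)
            continue
        if tpl.template_class in by_class:
            duplicates.append(tpl.template_class.value)
        by_class[tpl.template_class] = tpl
    missing = [tc.value for tc in required if tc not in by_class]
    extra = [tc.value for tc in by_class if tc not in required]
    problems = []
    if missing:
        problems.append(f"missing classes: {missing}")
    if duplicates:
        problems.append(f"duplicate classes: {sorted(set(duplicates))}")
    if extra:
        problems.append(f"unexpected classes: {extra}")
    if wrong_position:
        problems.append(f"templates for another position: {wrong_position}")
    if problems:
        raise ConfigurationError(
            f"invalid registry for position '{position.value}': " + "; ".join(problems)
        )
    ordered = tuple(by_class[tc] for tc in required)
    return Registry(position=position, templates=ordered)


@dataclass(frozen=True)
class ClassificationResult:
    """Argmin-DTW decision for one segment, with the full score map."""

    template_class: TemplateClass
    label: ExerciseLabel
    score: float
    all_scores: Mapping[TemplateClass, float]
    rejected: bool = False


def _resample_to_fs(data: np.ndarray, fs_from: float, fs_to: float) -> np.ndarray:
    """Linear resampling of an (n, 3) slice onto another sampling rate."""
    n = data.shape[0]
    m = max(2, int(round(n * fs_to / fs_from)))
    t_old = np.arange(n) / fs_from
    t_new = np.arange(m) * (t_old[-1] / (m - 1)) if m > 1 else np.zeros(1)
    return np.column_stack(
        [np.interp(t_new, t_old, data[:, k]) for k in range(data.shape[1])]
    )


def classify_segment(
    seg: MotionSegment,
    registry: Registry,
    reject_threshold: float | None = None,
) -> ClassificationResult:
    """Assign a segment to the template class with minimum DTW distance.

    Ties are broken by the canonical registry order (running, walking,
    jumping, push-up, sit-up; right before left).  With
    ``reject_threshold`` set (distance units per query sample), a result
    whose winning score exceeds ``reject_threshold * len(seg)`` is marked
    rejected — the documented mitigation for spurious sub-segments (e.g.,
    the non-wake-up parts of a sit-up) that resemble no template.
    """
    if len(registry) == 0:
        raise ConfigurationError("registry is empty")
    if WearPosition(seg.position) != registry.position:
        raise ConfigurationError(
            f"segment position '{seg.position}' does not match registry "
            f"position '{registry.position.value}'"
        )
    query = seg.data
    scores: dict[TemplateClass, float] = {}
    best_tc: TemplateClass | None = None
    best_score = np.inf
    for tpl in registry:
        q = query
        if not np.isclose(seg.fs, tpl.fs, rtol=1e-9):
            q = _resample_to_fs(query, seg.fs, tpl.fs)
        d = dtw_distance(q, tpl.data)
        scores[tpl.template_class] = d
        if d < best_score:  # strict: first template wins ties
            best_score = d
            best_tc = tpl.template_class
    assert best_tc is not None
    rejected = (
        reject_threshold is not None and best_score > reject_threshold * len(seg)
    )
    return ClassificationResult(
        template_class=best_tc,
        label=merge_class(best_tc),
        score=best_score,
        all_scores=scores,
        rejected=rejected,
    )
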
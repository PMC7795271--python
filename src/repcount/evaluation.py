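"""Evaluation protocols: segmentation-recall tables and random-template validation.

The validation protocol mirrors the single-template philosophy of the
method itself: from a pool of correctly segmented, labeled motion
segments, one template per class is drawn uniformly at random, every
remaining segment is classified against that registry, and accuracy plus
per-class F1 are recorded; the draw is repeated (50 iterations by
default) and mean / SD / max / min accuracy are reported.

Accuracy is micro accuracy — correctly labeled segments divided by tested
segments — with right/left gait classes merged before the correctness
check.  The SD is the sample (n-1) standard deviation.  A class that is
never predicted in an iteration scores F1 = 0 for that iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classification import (
    ExerciseLabel,
    Template,
    TemplateClass,
    build_registry,
    classify_segment,
    merge_class,
    required_classes,
)
from .core_signal import WearPosition
from .errors import ConfigurationError, InvalidInputError
from .segmentation import MotionSegment
from .synthetic import GAIT_LABELS, GroundTruth

__all__ = [
    "ValidationConfig",
    "EvaluationReport",
    "build_labeled_pool",
    "random_template_validation",
    "f1_per_class",
    "segmentation_recall_table",
]


@dataclass(frozen=True)
class ValidationConfig:
    """Settings of one random-template validation run."""

    position: WearPosition
    n_iterations: int = 50
    seed: int = 0
    reject_threshold: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", WearPosition(self.position))
        if self.n_iterations < 1:
            raise ConfigurationError(
                f"n_iterations must be >= 1, got {self.n_iterations}"
            )


@dataclass(frozen=True)
class EvaluationReport:
    """Aggregated outcome of repeated random-template validation."""

    config: ValidationConfig
    per_iteration_accuracy: np.ndarray
    f1_by_class: dict[str, np.ndarray]  # per-iteration F1 per merged label
    confusion: pd.DataFrame  # summed over iterations, true x predicted
    template_indices: tuple[tuple[int, ...], ...]  # pool indices drawn per iteration

    def __post_init__(self) -> None:
        acc = np.asarray(self.per_iteration_accuracy, dtype=float)
        object.__setattr__(self, "per_iteration_accuracy", acc)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_iteration_accuracy))

    @property
    def sd_accuracy(self) -> float:
        acc = self.per_iteration_accuracy
        return float(np.std(acc, ddof=1)) if len(acc) > 1 else 0.0

    @property
    def max_accuracy(self) -> float:
        return float(np.max(self.per_iteration_accuracy))

    @property
    def min_accuracy(self) -> float:
        return float(np.min(self.per_iteration_accuracy))

    def to_dict(self) -> dict:
        return {
            "position": self.config.position.value,
            "n_iterations": int(self.config.n_iterations),
            "seed": int(self.config.seed),
            "accuracy": {
                "mean": self.mean_accuracy,
                "sd": self.sd_accuracy,
                "max": self.max_accuracy,
                "min": self.min_accuracy,
                "per_iteration": [float(a) for a in self.per_iteration_accuracy],
            },
            "f1": {
                label: {
                    "mean": float(np.mean(scores)),
                    "sd": float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0,
                }
                for label, scores in self.f1_by_class.items()
            },
            "confusion": self.confusion.to_dict(),
            "template_indices": [list(t) for t in self.template_indices],
        }

    def format_table(self) -> str:
        """Text rendering: per-class F1 (SD) plus accuracy statistics."""
        rows = []
        for label, scores in self.f1_by_class.items():
            sd = float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0
            rows.append(f"  {label:<10} F1 {np.mean(scores):.3f} (SD {sd:.3f})")
        head = (
            f"position: {self.config.position.value}  "
            f"iterations: {self.config.n_iterations}"
        )
        acc = (
            f"  accuracy   mean {self.mean_accuracy:.3f} (SD {self.sd_accuracy:.3f})"
            f"  max {self.max_accuracy:.3f}  min {self.min_accuracy:.3f}"
        )
        return "\n".join([head, *rows, acc])


def build_labeled_pool(
    segments: Sequence[MotionSegment],
    truth: GroundTruth,
    min_coverage: float = 0.6,
) -> list[MotionSegment]:
    """Keep the correctly segmented motions and attach template-class labels.

    For every ground-truth cycle, the segment whose midpoint falls inside
    the cycle's canonical motion window — and which overlaps at least
    ``min_coverage`` of that window — is kept (closest midpoint wins when
    several qualify); all other segments — rest-gap noise, split
    fragments, sit-up sub-segments other than the wake-up — are
    discarded.  This mirrors validating classification only on the
    accurately extracted segments.  At arm/wrist the gait labels carry
    the stride side (e.g. ``running_left``), so the pool can seed a
    side-split registry.
    """
    if not segments:
        return []
    position = WearPosition(segments[0].position)
    side_split = position in (WearPosition.UPPER_ARM, WearPosition.WRIST)
    windows = truth.motion_windows
    centers = windows.mean(axis=1)
    best: dict[int, tuple[float, MotionSegment]] = {}
    for seg in segments:
        mid = seg.midpoint
        k = int(np.searchsorted(windows[:, 0], mid, side="right")) - 1
        if k < 0 or mid >= windows[k, 1]:
            continue
        w0, w1 = windows[k]
        overlap = min(seg.end_idx, w1) - max(seg.start_idx, w0)
        if overlap < min_coverage * (w1 - w0):
            continue
        dist = abs(mid - centers[k])
        if k not in best or dist < best[k][0]:
            best[k] = (dist, seg)
    pool: list[MotionSegment] = []
    for k in sorted(best):
        _, seg = best[k]
        label = truth.labels[k]
        if side_split and ExerciseLabel(label) in GAIT_LABELS:
            label = f"{label}_{truth.sides[k]}"
        pool.append(replace(seg, label=label))
    return pool


def random_template_validation(
    pool: Sequence[MotionSegment], config: ValidationConfig
) -> EvaluationReport:
    """Repeated draw-one-template-per-class validation over a labeled pool.

    Every pool segment must carry a template-class label appropriate for
    ``config.position``; each class needs at least two segments (one to
    serve as template, one to test).  Drawn templates are excluded from
    their iteration's test set.
    """
    classes = required_classes(config.position)
    by_class: dict[TemplateClass, list[int]] = {tc: [] for tc in classes}
    for i, seg in enumerate(pool):
        if seg.label is None:
            raise ConfigurationError(f"pool segment {i} has no label")
        tc = TemplateClass(seg.label)
        if tc not in by_class:
            raise ConfigurationError(
                f"label '{tc.value}' is not a template class for position "
                f"'{config.position.value}'"
            )
        by_class[tc].append(i)
    thin = [tc.value for tc, idx in by_class.items() if len(idx) < 2]
    if thin:
        raise ConfigurationError(
            f"classes with fewer than 2 pool segments: {thin}"
        )

    merged = [label.value for label in ExerciseLabel]
    rng = np.random.default_rng(config.seed)
    accuracies = np.empty(config.n_iterations)
    f1_scores = {label: np.empty(config.n_iterations) for label in merged}
    confusion = pd.DataFrame(0, index=merged, columns=merged, dtype=int)
    drawn: list[tuple[int, ...]] = []
    for it in range(config.n_iterations):
        chosen = {tc: int(rng.choice(idx)) for tc, idx in by_class.items()}
        drawn.append(tuple(chosen[tc] for tc in classes))
        registry = build_registry(
            [
                Template(
                    template_class=tc,
                    position=config.position,
                    fs=pool[i].fs,
                    data=pool[i].data,
                )
                for tc, i in chosen.items()
            ],
            config.position,
        )
        excluded = set(chosen.values())
        iter_confusion = pd.DataFrame(0, index=merged, columns=merged, dtype=int)
        for i, seg in enumerate(pool):
            if i in excluded:
                continue
            result = classify_segment(seg, registry, config.reject_threshold)
            if result.rejected:
                continue
            true_label = merge_class(TemplateClass(seg.label)).value
            iter_confusion.loc[true_label, result.label.value] += 1
        total = int(iter_confusion.values.sum())
        correct = int(np.trace(iter_confusion.values))
        accuracies[it] = correct / total if total else 0.0
        f1 = f1_per_class(iter_confusion.values)
        for j, label in enumerate(merged):
            f1_scores[label][it] = f1[j]
        confusion += iter_confusion
    return EvaluationReport(
        config=config,
        per_iteration_accuracy=accuracies,
        f1_by_class=f1_scores,
        confusion=confusion,
        template_indices=tuple(drawn),
    )


def f1_per_class(confusion: np.ndarray) -> np.ndarray:
    """Per-class F1 from a square confusion matrix (rows true, cols predicted).

    F1 is 0 by convention when precision + recall is 0 (a class that is
    absent and never predicted).
    """
    conf = np.asarray(confusion, dtype=float)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
        raise InvalidInputError(f"confusion matrix must be square, got {conf.shape}")
    if np.any(conf < 0):
        raise InvalidInputError("confusion matrix must be non-negative")
    tp = np.diag(conf)
    predicted = conf.sum(axis=0)
    actual = conf.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(predicted > 0, tp / predicted, 0.0)
        recall = np.where(actual > 0, tp / actual, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2.0 * precision * recall / denom, 0.0)
    return f1


def segmentation_recall_table(
    recalls: Mapping[WearPosition | str, Mapping[ExerciseLabel | str, tuple[float, int]]],
) -> pd.DataFrame:
    """Position x exercise recall matrix with a segment-weighted total column.

    ``recalls[position][exercise]`` is ``(recall, n_true_reps)``; the total
    per position is the mean of the per-exercise recalls weighted by their
    true repetition counts.
    """
    rows = {}
    for pos, by_label in recalls.items():
        pos = WearPosition(pos).value
        row = {}
        weights = []
        values = []
        for label, (recall, n_true) in by_label.items():
            label = ExerciseLabel(label).value
            if not 0.0 <= recall <= 1.0:
                raise InvalidInputError(f"recall {recall} outside [0, 1]")
            row[label] = recall
            values.append(recall)
            weights.append(n_true)
        row["total"] = float(np.average(values, weights=weights))
        rows[pos] = row
    return pd.DataFrame(rows).T
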
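"""Repetition counting from the stream of classification results.

Counting is deliberately simple: every accepted classification increments
its exercise's counter by one.  Rejected results (optional threshold mode)
are logged in the event stream but never counted, so the sum of counters
always equals the number of accepted segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

from .classification import ClassificationResult, ExerciseLabel, TemplateClass

__all__ = ["CountEvent", "CountState", "update_counts", "count_report", "format_count_report"]


class CountEvent(NamedTuple):
    segment_index: int
    template_class: TemplateClass
    label: ExerciseLabel
    score: float
    rejected: bool


@dataclass
class CountState:
    """Per-exercise counters plus the ordered event log of a run."""

    counts: dict[ExerciseLabel, int] = field(
        default_factory=lambda: {label: 0 for label in ExerciseLabel}
    )
    events: list[CountEvent] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def update_counts(
    state: CountState, result: ClassificationResult, segment_index: int | None = None
) -> CountState:
    """Record one classification result; increment its label unless rejected."""
    if segment_index is None:
        segment_index = len(state.events)
    state.events.append(
        CountEvent(
            segment_index=segment_index,
            template_class=result.template_class,
            label=result.label,
            score=result.score,
            rejected=result.rejected,
        )
    )
    if not result.rejected:
        state.counts[result.label] += 1
    return state


def count_report(state: CountState) -> dict:
    """Per-label totals plus right/left gait sub-totals and rejection count.

    The right/left sub-totals are reconstructed from the event log, so they
    are only non-zero when side-split (arm/wrist) templates were in use.
    """
    sides: dict[str, dict[str, int]] = {
        ExerciseLabel.RUNNING.value: {"right": 0, "left": 0},
        ExerciseLabel.WALKING.value: {"right": 0, "left": 0},
    }
    rejected = 0
    for ev in state.events:
        if ev.rejected:
            rejected += 1
            continue
        name = ev.template_class.value
        for exercise, tally in sides.items():
            if name == f"{exercise}_right":
                tally["right"] += 1
            elif name == f"{exercise}_left":
                tally["left"] += 1
    return {
        "counts": {label.value: n for label, n in state.counts.items()},
        "total": state.total,
        "sides": sides,
        "rejected": rejected,
        "n_events": len(state.events),
    }


def format_count_report(state: CountState) -> str:
    """Human-readable table of the count report."""
    report = count_report(state)
    lines = [f"{'exercise':<12}{'count':>7}{'right':>7}{'left':>7}"]
    for label in ExerciseLabel:
        side = report["sides"].get(label.value, {})
        right = str(side.get("right", "")) if side else ""
        left = str(side.get("left", "")) if side else ""
        lines.append(
            f"{label.value:<12}{report['counts'][label.value]:>7}{right:>7}{left:>7}"
        )
    lines.append(f"{'total':<12}{report['total']:>7}")
    if report["rejected"]:
        lines.append(f"{'rejected':<12}{report['rejected']:>7}")
    return "\n".join(lines)
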
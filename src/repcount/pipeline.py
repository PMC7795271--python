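"""Pipeline configuration and end-to-end orchestration.

The runtime phase chains: magnitude -> short-term energy -> peak
detection -> segment extraction -> minimum-DTW classification -> counting.
The preprocessing phase (recording one template per exercise) is served
by the template store and, for synthetic work, the template bank.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from .classification import ClassificationResult, Registry, classify_segment
from .core_signal import AccelSeries, WearPosition, compute_magnitude, short_term_energy
from .counting import CountState, update_counts
from .errors import ConfigurationError
from .segmentation import (
    DEFAULT_MAX_MS,
    DEFAULT_MIN_MS,
    MotionSegment,
    detect_peaks,
    extract_segments,
)

logger = logging.getLogger("repcount")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of one pipeline run.

    Durations are seconds unless suffixed ``_ms``.  ``reject_threshold``
    is a DTW distance per query sample; ``None`` disables rejection (the
    default: every segment is assigned its argmin class).
    """

    position: WearPosition = WearPosition.CHEST
    energy_window_s: float = 0.25
    detrend_s: float | None = 1.0
    peak_window_s: float = 0.25
    min_ms: float = DEFAULT_MIN_MS
    max_ms: float = DEFAULT_MAX_MS
    min_height: float | None = None
    min_height_frac: float | None = None
    reject_threshold: float | None = None
    template_path: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", WearPosition(self.position))
        for name in ("energy_window_s", "peak_window_s", "min_ms", "max_ms"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.detrend_s is not None and self.detrend_s <= 0:
            raise ConfigurationError("detrend_s must be > 0 or None")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["position"] = self.position.value
        return d

    @classmethod
    def from_dict(cls, data: dict, **overrides) -> "PipelineConfig":
        merged = {**data, **{k: v for k, v in overrides.items() if v is not None}}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(merged) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**merged)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data, **overrides)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass(frozen=True)
class PipelineResult:
    segments: tuple[MotionSegment, ...]
    results: tuple[ClassificationResult, ...]
    state: CountState


def run_pipeline(
    config: PipelineConfig, signal: AccelSeries, registry: Registry
) -> PipelineResult:
    """Segment, classify and count one recorded stream.

    An empty signal produces empty outputs and zero counts.  Stage
    failures are re-raised with the failing stage named.
    """
    if len(signal) == 0:
        return PipelineResult(segments=(), results=(), state=CountState())
    stage = "magnitude"
    try:
        mag = compute_magnitude(signal)
        stage = "energy"
        env = short_term_energy(mag, config.energy_window_s, config.detrend_s)
        stage = "peak detection"
        peaks = detect_peaks(
            env, config.peak_window_s, config.min_height, config.min_height_frac
        )
        stage = "segment extraction"
        segments = extract_segments(signal, peaks, config.min_ms, config.max_ms)
        stage = "classification"
        results = [
            classify_segment(seg, registry, config.reject_threshold)
            for seg in segments
        ]
        stage = "counting"
        state = CountState()
        for i, result in enumerate(results):
            update_counts(state, result, segment_index=i)
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc
    logger.debug(
        "pipeline: %d peaks, %d segments, %d counted",
        len(peaks), len(segments), state.total,
    )
    return PipelineResult(
        segments=tuple(segments), results=tuple(results), state=state
    )
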
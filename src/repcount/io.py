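"""Readers and writers for the package's plain-text interchange formats.

* signal CSV — header ``t,x,y,z``, time in seconds, acceleration in g;
* template store — one JSON file per registry (schema versioned, floats
  round-trip bit-exactly through the JSON shortest-repr encoding);
* segments — JSON-lines, one record per motion segment;
* count reports — JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .classification import Registry, Template, build_registry
from .core_signal import AccelSeries, WearPosition
from .counting import CountState, count_report
from .errors import InvalidInputError
from .segmentation import MotionSegment

logger = logging.getLogger("repcount")

TEMPLATE_SCHEMA_VERSION = 1
#: g per m/s^2, for converting foreign recordings at the reader layer
G = 9.80665

__all__ = [
    "read_signal_csv",
    "write_signal_csv",
    "save_registry",
    "load_registry",
    "write_segments_jsonl",
    "read_segments_jsonl",
    "write_count_report",
]


def read_signal_csv(
    path: str | Path,
    position: WearPosition | str = WearPosition.CHEST,
    uniform_rtol: float = 1e-3,
    from_m_s2: bool = False,
) -> AccelSeries:
    """Load a ``t,x,y,z`` CSV as a uniformly sampled acceleration series.

    Timestamps must be strictly increasing.  If the sampling intervals
    deviate from their median by more than ``uniform_rtol`` (relative),
    the signal is resampled onto a uniform grid by linear interpolation
    and a warning is logged.  ``from_m_s2=True`` converts the axis
    columns from m/s^2 to g on the way in.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pandas reports the offending line itself
        raise InvalidInputError(f"cannot parse {path}: {exc}") from exc
    expected = ["t", "x", "y", "z"]
    if list(frame.columns) != expected:
        raise InvalidInputError(
            f"{path}: expected header {expected}, got {list(frame.columns)}"
        )
    if len(frame) < 2:
        raise InvalidInputError(f"{path}: need at least 2 samples, got {len(frame)}")
    numeric = frame[expected].apply(pd.to_numeric, errors="coerce")
    bad_rows = numeric.isna().any(axis=1)
    if bad_rows.any():
        line = int(numeric.index[bad_rows][0]) + 2  # header is line 1
        raise InvalidInputError(f"{path}: malformed row at line {line}")
    frame = numeric
    t = frame["t"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0)) + 2
        raise InvalidInputError(
            f"{path}: non-increasing timestamp at line {bad + 1} "
            "(duplicated or out-of-order time)"
        )
    xyz = frame[["x", "y", "z"]].to_numpy(dtype=float)
    if from_m_s2:
        xyz = xyz / G
    med = float(np.median(dt))
    fs = 1.0 / med
    if np.max(np.abs(dt - med)) > uniform_rtol * med:
        logger.warning(
            "%s: non-uniform sampling (max deviation %.2g of median interval); "
            "resampling to %.6g Hz by linear interpolation",
            path,
            float(np.max(np.abs(dt - med)) / med),
            fs,
        )
        n = int(np.floor((t[-1] - t[0]) / med)) + 1
        grid = t[0] + np.arange(n) * med
        xyz = np.column_stack([np.interp(grid, t, xyz[:, k]) for k in range(3)])
    return AccelSeries(
        fs=fs, x=xyz[:, 0], y=xyz[:, 1], z=xyz[:, 2],
        position=WearPosition(position), t0=float(t[0]),
    )


def write_signal_csv(series: AccelSeries, path: str | Path) -> None:
    """Write a series as a ``t,x,y,z`` CSV with full float precision."""
    frame = pd.DataFrame(
        {"t": series.times, "x": series.x, "y": series.y, "z": series.z}
    )
    # %.17g round-trips IEEE doubles exactly through the text format
    frame.to_csv(path, index=False, float_format="%.17g")


def save_registry(registry: Registry, path: str | Path) -> None:
    """Serialize a template registry to a versioned JSON store."""
    payload = {
        "schema_version": TEMPLATE_SCHEMA_VERSION,
        "position": registry.position.value,
        "templates": [
            {
                "class": tpl.template_class.value,
                "fs": tpl.fs,
                "x": tpl.data[:, 0].tolist(),
                "y": tpl.data[:, 1].tolist(),
                "z": tpl.data[:, 2].tolist(),
            }
            for tpl in registry
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_registry(path: str | Path) -> Registry:
    """Load and validate a registry from its JSON store."""
    payload = json.loads(Path(path).read_text())
    version = payload.get("schema_version")
    if version != TEMPLATE_SCHEMA_VERSION:
        raise InvalidInputError(
            f"{path}: unsupported template schema version {version}"
        )
    position = WearPosition(payload["position"])
    templates = [
        Template(
            template_class=entry["class"],
            position=position,
            fs=float(entry["fs"]),
            data=np.column_stack(
                [entry["x"], entry["y"], entry["z"]]
            ),
        )
        for entry in payload["templates"]
    ]
    return build_registry(templates, position)


def write_segments_jsonl(segments, path: str | Path) -> None:
    """One JSON record per segment: indices, fs, position and inline axes."""
    with open(path, "w") as fh:
        for seg in segments:
            record = {
                "start_idx": int(seg.start_idx),
                "end_idx": int(seg.end_idx),
                "fs": seg.fs,
                "position": seg.position,
                "label": seg.label,
                "x": seg.data[:, 0].tolist(),
                "y": seg.data[:, 1].tolist(),
                "z": seg.data[:, 2].tolist(),
            }
            fh.write(json.dumps(record) + "\n")


def read_segments_jsonl(path: str | Path) -> list[MotionSegment]:
    segments = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            segments.append(
                MotionSegment(
                    start_idx=rec["start_idx"],
                    end_idx=rec["end_idx"],
                    data=np.column_stack([rec["x"], rec["y"], rec["z"]]),
                    fs=rec["fs"],
                    position=rec["position"],
                    label=rec.get("label"),
                )
            )
    return segments


def write_count_report(state: CountState, path: str | Path) -> None:
    Path(path).write_text(json.dumps(count_report(state), indent=1))
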
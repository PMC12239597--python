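"""File I/O: multi-page TIFF, events JSON-lines, report JSON with provenance.

TIFF is written as uncompressed baseline grayscale with a JSON side-car
(``<name>.meta.json``) carrying pixel size and frame interval, since baseline
TIFF has no standard slot for them.  Every output file declares its schema
version.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile

from .errors import FormatError
from .synth import VideoMeta, VideoStack

VIDEO_SCHEMA = "gearbelt-video-v1"
EVENTS_SCHEMA = "gearbelt-events-v1"
REPORT_SCHEMA = "gearbelt-report-v1"


def write_video(path, stack: VideoStack) -> None:
    """Write an uncompressed grayscale multi-page TIFF plus meta side-car."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames, photometric="minisblack", compression=None)
    meta = {
        "schema": VIDEO_SCHEMA,
        "pixel_size_um": stack.meta.pixel_size_um,
        "frame_interval_s": stack.meta.frame_interval_s,
        "n_frames": stack.meta.n_frames,
        "shape_px": list(stack.meta.shape_px),
        "bit_depth": stack.meta.bit_depth,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2)
    )


def read_video(
    path,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> VideoStack:
    """Read a multi-page TIFF; calibration comes from the side-car unless
    overridden by the arguments."""
    path = Path(path)
    try:
        frames = tifffile.imread(path)
    except Exception as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise FormatError(f"{path}: expected a grayscale stack, got shape {frames.shape}")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    px, dt = pixel_size_um, frame_interval_s
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        px = px if px is not None else meta.get("pixel_size_um")
        dt = dt if dt is not None else meta.get("frame_interval_s")
    if px is None or dt is None:
        raise FormatError(
            f"{path}: pixel size / frame interval unknown; pass them explicitly "
            "or provide a .meta.json side-car"
        )
    bit_depth = 16 if frames.dtype.itemsize > 1 else 8
    meta = VideoMeta(
        n_frames=frames.shape[0],
        pixel_size_um=float(px),
        frame_interval_s=float(dt),
        shape_px=(frames.shape[1], frames.shape[2]),
        bit_depth=bit_depth,
    )
    return VideoStack(meta=meta, frames=frames)


def write_events_jsonl(path, events) -> None:
    """Write simulator events as JSON-lines (one {time_s, kind} per line)."""
    with open(path, "w") as fh:
        fh.write(json.dumps({"schema": EVENTS_SCHEMA}) + "\n")
        for t, kind in events:
            fh.write(json.dumps({"time_s": t, "kind": kind}) + "\n")


def read_events_jsonl(path) -> list[tuple[float, str]]:
    events = []
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            if "schema" in rec:
                continue
            events.append((float(rec["time_s"]), str(rec["kind"])))
    return events


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_report(path, payload: dict, config: dict | None = None,
                 seed: int | None = None, inputs: list | None = None) -> None:
    """Write a result JSON with a provenance block."""
    from . import __version__

    report = {
        "schema": REPORT_SCHEMA,
        "provenance": {
            "software": f"gearbelt {__version__}",
            "seed": seed,
            "config": config or {},
            "inputs": [
                {"path": str(p), "sha256": sha256_of(p)} for p in (inputs or [])
            ],
        },
    }
    report.update(payload)
    Path(path).write_text(json.dumps(report, indent=2, default=_jsonable) + "\n")
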
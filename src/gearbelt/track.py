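"""Shared trajectory container and its CSV serialization.

A :class:`Track` is the common currency between the simulator, the renderers
and every analysis stage: time-stamped 2D positions in micrometers, with an
optional per-sample intensity.  The on-disk format is a plain CSV with
columns ``track_id, frame, t_s, x_um, y_um[, intensity]`` preceded by a
schema header comment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError

TRACK_SCHEMA = "gearbelt-track-v1"

_SOURCES = ("cell", "spot", "simulated")


@dataclass
class Track:
    """Time-stamped 2D trajectory of one cell or spot.

    Parameters
    ----------
    track_id : int
        Identifier, unique within one file/collection.
    t_s, x_um, y_um : array-like
        Sample times (seconds, strictly increasing) and positions (µm).
    intensity : array-like, optional
        Per-sample integrated intensity (arbitrary units).
    source : {"cell", "spot", "simulated"}
    """

    track_id: int
    t_s: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    intensity: np.ndarray | None = None
    source: str = "simulated"
    frame: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=float)
            if self.intensity.shape != self.t_s.shape:
                raise ValueError("intensity length mismatch")
        if not (self.t_s.shape == self.x_um.shape == self.y_um.shape):
            raise ValueError("t_s, x_um, y_um must have equal length")
        if self.t_s.size >= 2 and not np.all(np.diff(self.t_s) > 0):
            raise ValueError("track times must be strictly increasing")
        if self.source not in _SOURCES:
            raise ValueError(f"unknown track source {self.source!r}")
        if self.frame is None:
            self.frame = np.arange(self.t_s.size)
        else:
            self.frame = np.asarray(self.frame, dtype=int)

    def __len__(self) -> int:
        return int(self.t_s.size)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of positions in µm."""
        return np.column_stack([self.x_um, self.y_um])

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])

    def path_length_um(self) -> float:
        d = np.diff(self.positions, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Concatenate tracks into the canonical long-format table."""
    rows = []
    has_intensity = any(t.intensity is not None for t in tracks)
    for t in tracks:
        d = {
            "track_id": t.track_id,
            "frame": t.frame,
            "t_s": t.t_s,
            "x_um": t.x_um,
            "y_um": t.y_um,
        }
        if has_intensity:
            d["intensity"] = (
                t.intensity if t.intensity is not None else np.full(len(t), np.nan)
            )
        rows.append(pd.DataFrame(d))
    if not rows:
        cols = ["track_id", "frame", "t_s", "x_um", "y_um"]
        return pd.DataFrame(columns=cols)
    return pd.concat(rows, ignore_index=True)


def write_tracks_csv(path, tracks: list[Track]) -> None:
    """Write tracks as CSV with a schema header comment."""
    df = tracks_to_frame(tracks)
    with open(path, "w") as fh:
        fh.write(f"# schema: {TRACK_SCHEMA}\n")
        df.to_csv(fh, index=False)


def read_tracks_csv(path, source: str = "simulated") -> list[Track]:
    """Read tracks written by :func:`write_tracks_csv` (or any CSV with the
    same columns)."""
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse track CSV {path}: {exc}") from exc
    required = {"track_id", "t_s", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"track CSV {path} missing columns {sorted(missing)}")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("t_s")
        tracks.append(
            Track(
                track_id=int(tid),
                t_s=grp["t_s"].to_numpy(),
                x_um=grp["x_um"].to_numpy(),
                y_um=grp["y_um"].to_numpy(),
                intensity=(
                    grp["intensity"].to_numpy() if "intensity" in grp else None
                ),
                frame=(grp["frame"].to_numpy() if "frame" in grp else None),
                source=source,
            )
        )
    return tracks
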
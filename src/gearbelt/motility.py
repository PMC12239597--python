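"""Trajectory linking and gliding-motility statistics.

Per-frame detections are linked into trajectories by greedy nearest-neighbor
assignment (ascending link distance, bounded jump, bounded frame gap), and
each trajectory is summarized by mean speed on smoothed positions, farthest
displacement from the start point, path length, and run/turn structure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .track import Track

logger = logging.getLogger(__name__)


@dataclass
class TrackStats:
    """Kinematic summary of one trajectory."""

    mean_speed_um_s: float
    farthest_displacement_um: float
    path_length_um: float
    n_turn_events: int
    n_reversals: int
    duration_s: float


def link_tracks(
    detections,
    times_s,
    max_jump_um: float,
    max_gap_frames: int = 0,
) -> list[Track]:
    """Greedy nearest-neighbor linking of per-frame detections.

    Parameters
    ----------
    detections : sequence of (n_i, k) arrays
        One array per frame with columns ``x_um, y_um[, intensity]``.
    times_s : sequence of float
        Acquisition time of each frame.
    max_jump_um : float
        Links longer than this are rejected.
    max_gap_frames : int
        A track may skip up to this many frames (positions are not imputed).

    Candidate links are assigned in ascending distance order; ties are broken
    by (track id, detection x, detection y) so the result does not depend on
    the detection order within a frame.  Unmatched detections seed new
    tracks.
    """
    times_s = np.asarray(times_s, dtype=float)
    if len(detections) != times_s.size:
        raise ValueError("detections and times_s length mismatch")
    # active: list of dict(id, last_xy, last_frame, rows=[(t, x, y, inten)])
    active: list[dict] = []
    finished: list[dict] = []
    next_id = 0
    for f, dets in enumerate(detections):
        dets = np.atleast_2d(np.asarray(dets, dtype=float))
        if dets.size == 0:
            dets = dets.reshape(0, 2)
        has_intensity = dets.shape[1] >= 3
        # retire tracks that exceeded the allowed gap
        still = []
        for tr in active:
            if f - tr["last_frame"] > max_gap_frames + 1:
                finished.append(tr)
            else:
                still.append(tr)
        active = still
        candidates = []
        for tr in active:
            dx = dets[:, 0] - tr["last_xy"][0]
            dy = dets[:, 1] - tr["last_xy"][1]
            dist = np.hypot(dx, dy)
            for j in np.flatnonzero(dist <= max_jump_um):
                candidates.append(
                    (dist[j], tr["id"], dets[j, 0], dets[j, 1], tr, int(j))
                )
        candidates.sort(key=lambda c: (c[0], c[1], c[2], c[3]))
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for dist, tid, _x, _y, tr, j in candidates:
            if tid in used_tracks or j in used_dets:
                continue
            used_tracks.add(tid)
            used_dets.add(j)
            inten = dets[j, 2] if has_intensity else None
            tr["rows"].append((times_s[f], dets[j, 0], dets[j, 1], inten, f))
            tr["last_xy"] = (dets[j, 0], dets[j, 1])
            tr["last_frame"] = f
        # order new-track seeding by position for permutation invariance
        unmatched = sorted(
            (j for j in range(dets.shape[0]) if j not in used_dets),
            key=lambda j: (dets[j, 0], dets[j, 1]),
        )
        for j in unmatched:
            inten = dets[j, 2] if has_intensity else None
            active.append(
                {
                    "id": next_id,
                    "last_xy": (dets[j, 0], dets[j, 1]),
                    "last_frame": f,
                    "rows": [(times_s[f], dets[j, 0], dets[j, 1], inten, f)],
                }
            )
            next_id += 1
    finished.extend(active)
    finished.sort(key=lambda tr: tr["id"])
    tracks = []
    for tr in finished:
        rows = tr["rows"]
        inten = None
        if all(r[3] is not None for r in rows):
            inten = np.array([r[3] for r in rows])
        tracks.append(
            Track(
                track_id=tr["id"],
                t_s=np.array([r[0] for r in rows]),
                x_um=np.array([r[1] for r in rows]),
                y_um=np.array([r[2] for r in rows]),
                intensity=inten,
                frame=np.array([r[4] for r in rows]),
                source="cell",
            )
        )
    return tracks


def smooth_positions(track: Track, window_frames: int) -> np.ndarray:
    """Centered moving average of positions; edge windows shrink
    symmetrically so a linear trajectory is preserved exactly."""
    pos = track.positions
    n = len(track)
    if window_frames <= 1 or n <= window_frames:
        return pos.copy()
    half = (window_frames - 1) // 2
    out = np.empty_like(pos)
    csum = np.vstack([np.zeros(2), np.cumsum(pos, axis=0)])
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return out


def track_speed(track: Track, smooth_window_frames: int = 5) -> float:
    """Mean frame-to-frame speed on smoothed positions (µm/s).

    Positions are smoothed with a centered moving average (default window 5
    frames); speed is the mean of |Δr|/Δt over consecutive frames.  Steps
    across detection gaps (Δt > 1.5x the median frame interval) are excluded
    from the average.  Tracks shorter than the window fall back to
    unsmoothed positions with a logged warning.
    """
    if len(track) < 2:
        raise ValueError("track needs at least 2 samples")
    if len(track) < smooth_window_frames + 1:
        logger.warning(
            "track %d shorter than smoothing window; using raw positions",
            track.track_id,
        )
        pos = track.positions
    else:
        pos = smooth_positions(track, smooth_window_frames)
    dt = np.diff(track.t_s)
    step = np.hypot(*np.diff(pos, axis=0).T)
    keep = dt <= 1.5 * np.median(dt)
    if not keep.any():
        keep = np.ones_like(keep)
    return float(np.mean(step[keep] / dt[keep]))


def farthest_displacement(track: Track) -> float:
    """Maximum Euclidean distance from the first sample (µm)."""
    if len(track) < 2:
        raise ValueError("track needs at least 2 samples")
    pos = track.positions
    return float(np.max(np.hypot(pos[:, 0] - pos[0, 0], pos[:, 1] - pos[0, 1])))


def _wrap(a):
    return (a + np.pi) % (2 * np.pi) - np.pi


def _circmean(angles: np.ndarray) -> float:
    return float(np.arctan2(np.mean(np.sin(angles)), np.mean(np.cos(angles))))


def headings(track: Track, smooth_window_frames: int = 5,
             speed_floor_um: float = 1e-9) -> np.ndarray:
    """Per-step heading (rad) from smoothed velocity; stationary steps carry
    the last moving heading forward."""
    pos = smooth_positions(track, smooth_window_frames)
    d = np.diff(pos, axis=0)
    mag = np.hypot(d[:, 0], d[:, 1])
    h = np.zeros(len(d))
    moving = mag > speed_floor_um
    last = 0.0
    if moving.any():
        first = int(np.argmax(moving))
        last = math.atan2(d[first, 1], d[first, 0])
    for i in range(len(d)):
        if moving[i]:
            last = math.atan2(d[i, 1], d[i, 0])
        h[i] = last
    return h


def detect_turn_events(
    track: Track,
    angle_threshold_rad: float = math.pi / 2,
    window_frames: int = 5,
) -> tuple[int, int]:
    """Count turn events and reversals along a trajectory.

    A turn event is a change greater than ``angle_threshold_rad`` between the
    circular-mean heading of the ``window_frames`` steps before and after a
    frame; contiguous candidate frames (closer than ``window_frames``) merge
    into a single event.  A reversal is a turn whose heading change lies
    within pi ± pi/6.
    """
    if len(track) < 2 * window_frames:
        raise ValueError("track needs at least 2*window_frames samples")
    h = headings(track, window_frames)
    n = len(h)
    deltas = np.zeros(n)
    for i in range(window_frames, n - window_frames + 1):
        before = _circmean(h[i - window_frames : i])
        after = _circmean(h[i : i + window_frames])
        deltas[i] = _wrap(after - before)
    cand = np.flatnonzero(np.abs(deltas) > angle_threshold_rad)
    n_turns = 0
    n_reversals = 0
    i = 0
    while i < cand.size:
        j = i
        while j + 1 < cand.size and cand[j + 1] - cand[j] < window_frames:
            j += 1
        run = cand[i : j + 1]
        peak = run[int(np.argmax(np.abs(deltas[run])))]
        n_turns += 1
        if abs(abs(deltas[peak]) - math.pi) <= math.pi / 6:
            n_reversals += 1
        i = j + 1
    return n_turns, n_reversals


def compute_track_stats(
    track: Track,
    smooth_window_frames: int = 5,
    angle_threshold_rad: float = math.pi / 2,
    turn_window_frames: int = 5,
) -> TrackStats:
    """All per-track statistics in one pass."""
    if len(track) >= 2 * turn_window_frames:
        n_turns, n_rev = detect_turn_events(
            track, angle_threshold_rad, turn_window_frames
        )
    else:
        n_turns, n_rev = 0, 0
    return TrackStats(
        mean_speed_um_s=track_speed(track, smooth_window_frames),
        farthest_displacement_um=farthest_displacement(track),
        path_length_um=track.path_length_um(),
        n_turn_events=n_turns,
        n_reversals=n_rev,
        duration_s=track.duration_s,
    )


def population_summary(
    tracks: list[Track],
    smooth_window_frames: int = 5,
    angle_threshold_rad: float = math.pi / 2,
    turn_window_frames: int = 5,
) -> dict:
    """Arithmetic means of every :class:`TrackStats` field across tracks."""
    if not tracks:
        raise ValueError("population_summary needs at least one track")
    stats = [
        compute_track_stats(
            t, smooth_window_frames, angle_threshold_rad, turn_window_frames
        )
        for t in tracks
    ]
    out = {"n": len(stats)}
    for name in (
        "mean_speed_um_s",
        "farthest_displacement_um",
        "path_length_um",
        "n_turn_events",
        "n_reversals",
        "duration_s",
    ):
        out[name] = float(np.mean([getattr(s, name) for s in stats]))
    return out
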
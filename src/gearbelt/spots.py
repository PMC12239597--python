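"""Fluorescent spot detection, tracking and trajectory-shape classification.

Detection uses a difference-of-Gaussians band-pass (sigma and 3*sigma),
robust thresholding at median + snr_threshold * MAD of the filtered frame,
and subpixel localization by intensity-weighted centroid in a
(4*sigma + 1)-pixel window.  Speeds share the smoothed-velocity estimator of
:mod:`gearbelt.motility`; trajectory shapes are classified into looped,
oscillatory or extended.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .motility import link_tracks, smooth_positions, track_speed
from .track import Track

logger = logging.getLogger(__name__)

__all__ = [
    "SpotDetection",
    "ShapeClass",
    "detect_spots",
    "detect_spots_stack",
    "link_spot_tracks",
    "spot_speed",
    "classify_shape",
]


@dataclass
class SpotDetection:
    """One subpixel spot localization."""

    t_s: float
    x_um: float
    y_um: float
    intensity: float
    snr: float


@dataclass
class ShapeClass:
    """Trajectory shape label with its supporting metrics."""

    label: str  # "looped", "extended" or "oscillatory"
    confinement_ratio: float
    n_direction_reversals: int


def detect_spots(
    frame,
    pixel_size_um: float,
    psf_sigma_um: float,
    snr_threshold: float = 7.0,
    t_s: float = 0.0,
    image_rows: int | None = None,
) -> list[SpotDetection]:
    """Detect diffraction-limited spots in one frame.

    Returns positions in µm in the y-up analysis frame.  An empty list is a
    valid result for a blank frame.  Saturated frames are flagged with a
    warning but still processed.
    """
    img = np.asarray(frame, dtype=float)
    rows = image_rows if image_rows is not None else img.shape[0]
    if np.issubdtype(np.asarray(frame).dtype, np.integer):
        sat = np.iinfo(np.asarray(frame).dtype).max
        if (np.asarray(frame) == sat).any():
            logger.warning("saturated pixels in frame at t=%.3f s", t_s)
    sigma_px = psf_sigma_um / pixel_size_um
    dog = ndimage.gaussian_filter(img, sigma_px) - ndimage.gaussian_filter(
        img, 3.0 * sigma_px
    )
    med = float(np.median(dog))
    mad = float(np.median(np.abs(dog - med))) * 1.4826
    if mad <= 0:
        return []
    thr = med + snr_threshold * mad
    size = max(3, int(round(4 * sigma_px)) | 1)
    maxf = ndimage.maximum_filter(dog, size=size, mode="nearest")
    half = max(1, int(math.ceil(2.0 * sigma_px)))
    peaks = np.argwhere((dog == maxf) & (dog > thr))
    dets = []
    for r, c in peaks:
        r0, r1 = max(0, r - half), min(img.shape[0], r + half + 1)
        c0, c1 = max(0, c - half), min(img.shape[1], c + half + 1)
        w = np.clip(dog[r0:r1, c0:c1] - med, 0.0, None)
        tot = w.sum()
        if tot <= 0:
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        r_sub = float((rr * w).sum() / tot)
        c_sub = float((cc * w).sum() / tot)
        dets.append(
            SpotDetection(
                t_s=t_s,
                x_um=c_sub * pixel_size_um,
                y_um=(rows - 1 - r_sub) * pixel_size_um,
                intensity=float(tot),
                snr=(float(dog[r, c]) - med) / mad,
            )
        )
    return dets


def detect_spots_stack(video, psf_sigma_um: float,
                       snr_threshold: float = 7.0) -> list[list[SpotDetection]]:
    """Run :func:`detect_spots` on every frame of a stack."""
    meta = video.meta
    out = []
    for i in range(meta.n_frames):
        out.append(
            detect_spots(
                video.frames[i],
                pixel_size_um=meta.pixel_size_um,
                psf_sigma_um=psf_sigma_um,
                snr_threshold=snr_threshold,
                t_s=i * meta.frame_interval_s,
                image_rows=meta.shape_px[0],
            )
        )
    return out


def link_spot_tracks(
    detections: list[list[SpotDetection]],
    times_s,
    max_jump_um: float = 0.5,
    max_gap_frames: int = 2,
) -> list[Track]:
    """Link per-frame spot detections with the shared greedy linker."""
    arrays = [
        np.array([[d.x_um, d.y_um, d.intensity] for d in frame]).reshape(-1, 3)
        for frame in detections
    ]
    tracks = link_tracks(arrays, times_s, max_jump_um, max_gap_frames)
    for t in tracks:
        t.source = "spot"
    return tracks


def spot_speed(track: Track, smooth_window_frames: int = 5) -> float:
    """Mean spot speed (µm/s); same estimator as
    :func:`gearbelt.motility.track_speed` (shared implementation)."""
    return track_speed(track, smooth_window_frames)


def _direction_reversals(track: Track, smooth_window_frames: int = 3) -> int:
    """Count reversals of motion along the trajectory's dominant PCA axis."""
    pos = smooth_positions(track, smooth_window_frames)
    centered = pos - pos.mean(axis=0)
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, int(np.argmax(evals))]
    s = centered @ axis
    ds = np.diff(s)
    span = float(s.max() - s.min())
    eps = max(1e-9, 0.02 * span)
    signs = np.sign(ds[np.abs(ds) > eps])
    if signs.size < 2:
        return 0
    return int(np.sum(signs[1:] != signs[:-1]))


def classify_shape(
    track: Track,
    loop_closure_um: float = 0.5,
    reversal_count_threshold: int = 3,
    min_loop_path_um: float = 5.0,
) -> ShapeClass:
    """Classify a spot trajectory as looped, oscillatory or extended.

    * looped — the track returns within ``loop_closure_um`` of an earlier
      point after covering at least ``min_loop_path_um`` of path (about half
      a cell perimeter at the default cell size);
    * oscillatory — at least ``reversal_count_threshold`` direction reversals
      along the dominant axis and confinement ratio (net displacement / path
      length) below 0.2;
    * extended — otherwise.
    """
    if len(track) < 10:
        raise ValueError("classify_shape needs at least 10 samples")
    pos = track.positions
    steps = np.hypot(*np.diff(pos, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    path = float(cum[-1])
    net = float(np.hypot(pos[-1, 0] - pos[0, 0], pos[-1, 1] - pos[0, 1]))
    confinement = min(1.0, net / path) if path > 0 else 0.0
    n_rev = _direction_reversals(track)

    # looped = revisit after enough path AND with real spatial excursion in
    # between (distinguishes a closed loop from back-and-forth oscillation,
    # which also revisits points after accumulating path)
    looped = False
    min_excursion = 0.25 * min_loop_path_um
    for j in range(1, len(pos)):
        d = np.hypot(pos[:j, 0] - pos[j, 0], pos[:j, 1] - pos[j, 1])
        arc = cum[j] - cum[:j]
        for i in np.flatnonzero((d <= loop_closure_um) & (arc >= min_loop_path_um)):
            seg = pos[i : j + 1]
            excursion = np.max(np.hypot(seg[:, 0] - pos[i, 0], seg[:, 1] - pos[i, 1]))
            if excursion >= min_excursion:
                looped = True
                break
        if looped:
            break
    if looped:
        label = "looped"
    elif n_rev >= reversal_count_threshold and confinement < 0.2:
        label = "oscillatory"
    else:
        label = "extended"
    return ShapeClass(
        label=label, confinement_ratio=confinement, n_direction_reversals=n_rev
    )
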
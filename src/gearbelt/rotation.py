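"""Tethered-cell rotation analysis.

Extracts an unwrapped body angle trace from a phase-contrast video of a cell
rotating about a fixed tether, converts it to a signed rotational frequency
(+ = CCW in the analysis frame, which has y increasing upward), applies the
full-revolution inclusion filter, and summarizes populations of records into
a signed speed distribution.

Coordinate convention: image row r maps to y_um = (rows - 1 - r) * pixel_size
so that counterclockwise in the mathematical sense matches counterclockwise in
a conventionally displayed image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import AnalysisError

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi


@dataclass
class AngularTrace:
    """Unwrapped tether angle versus time.

    ``theta_rad`` is continuous (|step| < pi) and CCW-positive; ``center_xy_um``
    and ``radius_um`` describe the fitted rotation center and mean orbit
    radius of the body centroid.
    """

    times_s: np.ndarray
    theta_rad: np.ndarray
    center_xy_um: tuple[float, float] = (0.0, 0.0)
    radius_um: float = 0.0
    flagged_frames: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.theta_rad = np.asarray(self.theta_rad, dtype=float)
        if self.times_s.shape != self.theta_rad.shape:
            raise ValueError("times_s and theta_rad must have equal length")
        if self.times_s.size >= 2 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class RotationRecord:
    """Signed frequency and direction classification of one tethered motor."""

    frequency_hz: float
    direction: str  # "CCW", "CW" or "indeterminate"
    n_revolutions: float
    passes_filter: bool
    duration_s: float
    motor_id: int = 0


@dataclass
class SpeedDistribution:
    """Histogram summary of signed speeds over filter-passing records."""

    signed_speeds_hz: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    mean_dominant_hz: float
    dominant_direction: str
    fraction_dominant: float

    @classmethod
    def empty(cls) -> "SpeedDistribution":
        return cls(
            signed_speeds_hz=np.empty(0),
            bin_edges=np.empty(0),
            counts=np.empty(0, dtype=int),
            mean_dominant_hz=float("nan"),
            dominant_direction="indeterminate",
            fraction_dominant=float("nan"),
        )

    @property
    def is_empty(self) -> bool:
        return self.signed_speeds_hz.size == 0


def unwrap_angles(raw_theta) -> np.ndarray:
    """Unwrap a wrapped angle sequence into a continuous one.

    Each successive difference is mapped into (-pi, pi] (the boundary case of
    exactly pi is resolved toward +pi) and cumulatively summed onto the first
    raw angle.
    """
    raw = np.asarray(raw_theta, dtype=float)
    if raw.size == 0:
        return raw.copy()
    d = np.diff(raw)
    wrapped = np.pi - np.mod(np.pi - d, TWO_PI)
    return np.concatenate([[raw[0]], raw[0] + np.cumsum(wrapped)])


def _frame_centroid(frame: np.ndarray, min_area_px: int):
    """Weighted centroid (row, col) of the largest dark component, or None."""
    img = np.asarray(frame, dtype=float)
    try:
        th = threshold_otsu(img)
    except ValueError:  # constant image
        return None
    mask = img < th
    # a real dark cell occupies a small fraction of the frame; Otsu on an
    # object-free noise frame splits near the median and floods ~half of it
    if not mask.any() or mask.mean() > 0.25:
        return None
    labels, n = ndimage.label(mask)
    if n == 0:
        return None
    areas = ndimage.sum_labels(np.ones_like(img), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(areas)) + 1
    if areas[best - 1] < min_area_px:
        return None
    # tie-break equal-area components toward the lower row index
    ties = np.flatnonzero(areas == areas[best - 1]) + 1
    if ties.size > 1:
        min_rows = [np.min(np.nonzero(labels == lb)[0]) for lb in ties]
        best = int(ties[int(np.argmin(min_rows))])
    sel = labels == best
    w = np.where(sel, th - img, 0.0)
    w = np.clip(w, 0.0, None)
    total = w.sum()
    if total <= 0:
        return None
    rows, cols = np.nonzero(sel)
    r_c = float((rows * w[sel]).sum() / total)
    c_c = float((cols * w[sel]).sum() / total)
    return r_c, c_c


def extract_angle_trace(video, threshold_method: str = "otsu",
                        min_area_px: int = 50) -> AngularTrace:
    """Per-frame dark-object centroid -> unwrapped angle about the mean center.

    Frames where segmentation fails (no component of at least ``min_area_px``)
    are flagged and their centroids linearly interpolated from neighbors; if
    more than 10% of frames are flagged the analysis aborts.
    """
    if threshold_method != "otsu":
        raise ValueError("only the 'otsu' threshold method is implemented")
    meta = video.meta
    n = meta.n_frames
    rows = meta.shape_px[0]
    centroids = np.full((n, 2), np.nan)
    for t in range(n):
        c = _frame_centroid(video.frames[t], min_area_px)
        if c is not None:
            centroids[t] = c
    flagged = np.flatnonzero(np.isnan(centroids[:, 0]))
    if flagged.size > 0.10 * n:
        raise AnalysisError(
            f"segmentation failed on {flagged.size}/{n} frames (>10%)"
        )
    good = np.flatnonzero(~np.isnan(centroids[:, 0]))
    if good.size < 2:
        raise AnalysisError("fewer than two usable frames")
    if flagged.size:
        logger.warning("interpolating %d flagged frames", flagged.size)
        for k in range(2):
            centroids[flagged, k] = np.interp(flagged, good, centroids[good, k])
    # pixel -> um, y axis up
    px = meta.pixel_size_um
    x = centroids[:, 1] * px
    y = (rows - 1 - centroids[:, 0]) * px
    xc = float(np.mean(x[good]))
    yc = float(np.mean(y[good]))
    raw = np.arctan2(y - yc, x - xc)
    theta = unwrap_angles(raw)
    radius = float(np.mean(np.hypot(x[good] - xc, y[good] - yc)))
    times = np.arange(n) * meta.frame_interval_s
    return AngularTrace(
        times_s=times,
        theta_rad=theta,
        center_xy_um=(xc, yc),
        radius_um=radius,
        flagged_frames=flagged,
    )


def rotation_frequency(trace: AngularTrace, motor_id: int = 0) -> RotationRecord:
    """Signed mean frequency from the net unwrapped excursion.

    frequency = (theta_end - theta_start) / (2 pi * duration).  A record
    passes the inclusion filter only if the net excursion spans at least one
    full revolution; otherwise the direction is indeterminate (slow motion is
    not distinguishable from Brownian dithering).
    """
    t = trace.times_s
    if t.size < 2 or not np.all(np.diff(t) > 0):
        raise AnalysisError("angular trace times must be strictly increasing")
    duration = float(t[-1] - t[0])
    if duration < 1.0:
        raise AnalysisError("trace shorter than 1 s")
    net = float(trace.theta_rad[-1] - trace.theta_rad[0])
    freq = net / (TWO_PI * duration)
    n_rev = abs(net) / TWO_PI
    passes = n_rev >= 1.0
    if passes and freq > 0:
        direction = "CCW"
    elif passes and freq < 0:
        direction = "CW"
    else:
        direction = "indeterminate"
    return RotationRecord(
        frequency_hz=freq,
        direction=direction,
        n_revolutions=n_rev,
        passes_filter=passes,
        duration_s=duration,
        motor_id=motor_id,
    )


def speed_distribution(records: list[RotationRecord],
                       bin_width_hz: float = 0.2) -> SpeedDistribution:
    """Histogram of signed speeds over records passing the revolution filter.

    ``dominant_direction`` is the majority sign (ties resolved toward CCW),
    ``fraction_dominant`` the majority share, and ``mean_dominant_hz`` the
    mean absolute frequency of the dominant-direction subpopulation.
    """
    if bin_width_hz <= 0:
        raise ValueError("bin_width_hz must be > 0")
    speeds = np.array([r.frequency_hz for r in records if r.passes_filter])
    if speeds.size == 0:
        return SpeedDistribution.empty()
    n_ccw = int((speeds > 0).sum())
    n_cw = int((speeds < 0).sum())
    dominant = "CCW" if n_ccw >= n_cw else "CW"
    n_dom = max(n_ccw, n_cw) if n_ccw != n_cw else n_ccw
    fraction = n_dom / speeds.size
    dom_speeds = speeds[speeds > 0] if dominant == "CCW" else speeds[speeds < 0]
    mean_dom = float(np.mean(np.abs(dom_speeds))) if dom_speeds.size else float("nan")
    lo = np.floor(speeds.min() / bin_width_hz) * bin_width_hz
    hi = np.ceil(speeds.max() / bin_width_hz) * bin_width_hz
    if hi <= lo:
        hi = lo + bin_width_hz
    edges = np.arange(lo, hi + 0.5 * bin_width_hz, bin_width_hz)
    counts, edges = np.histogram(speeds, bins=edges)
    return SpeedDistribution(
        signed_speeds_hz=speeds,
        bin_edges=edges,
        counts=counts,
        mean_dominant_hz=mean_dom,
        dominant_direction=dominant,
        fraction_dominant=fraction,
    )
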
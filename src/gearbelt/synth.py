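"""Seeded synthetic video renderers with exact ground truth.

Three generators mirror the three assays quantified by the analysis modules:

* :func:`render_tethered_video` — a dark rod rotating rigidly about a fixed
  tether point (phase-contrast tethered-cell assay).
* :func:`render_gliding_video` — dark rods following supplied trajectories
  (phase-contrast gliding assay).
* :func:`render_spot_video` — a diffraction-limited fluorescent spot
  translocating along the closed stadium path of an elongated cell outline
  (TIRF conveyor-belt assay), with Poisson photon noise.

Phase contrast is approximated as dark-object-on-bright-background with
additive Gaussian noise; no halo is modeled.  All generators are
deterministic under a fixed seed and return the exact ground truth alongside
the rendered stack.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GenerationError, ParameterError
from .rotation import AngularTrace
from .track import Track

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VideoMeta:
    """Acquisition metadata of a (synthetic or real) video stack."""

    n_frames: int
    pixel_size_um: float = 0.1
    frame_interval_s: float = 1.0 / 15.0
    shape_px: tuple[int, int] = (512, 512)
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ParameterError("pixel_size_um and frame_interval_s must be > 0")
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        if self.bit_depth not in (8, 16):
            raise ParameterError("bit_depth must be 8 or 16")

    @property
    def dtype(self):
        return np.uint8 if self.bit_depth == 8 else np.uint16

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the field of view in µm."""
        return (
            (self.shape_px[1] - 1) * self.pixel_size_um,
            (self.shape_px[0] - 1) * self.pixel_size_um,
        )


@dataclass
class VideoStack:
    """Frames plus metadata; the raw observable for every assay."""

    meta: VideoMeta
    frames: np.ndarray  # (n_frames, rows, cols)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        expected = (self.meta.n_frames, *self.meta.shape_px)
        if self.frames.shape != expected:
            raise ValueError(f"frames shape {self.frames.shape} != {expected}")


@dataclass
class GroundTruth:
    """Exact generator output accompanying a synthetic stack."""

    kind: str  # "tethered", "gliding" or "spot"
    angle_trace: AngularTrace | None = None
    tracks: list[Track] | None = None
    params: dict = field(default_factory=dict)


def _um_grids(meta: VideoMeta):
    """Pixel-center coordinates in µm, y increasing upward."""
    rows, cols = meta.shape_px
    x = np.arange(cols) * meta.pixel_size_um
    y = (rows - 1 - np.arange(rows)) * meta.pixel_size_um
    return np.meshgrid(x, y)


def _capsule_profile(xg, yg, p0, p1, width_um, edge_um):
    """Soft-edged occupancy (0..1) of a capsule between endpoints p0, p1."""
    vx, vy = p1[0] - p0[0], p1[1] - p0[1]
    L2 = vx * vx + vy * vy
    if L2 == 0:
        d = np.hypot(xg - p0[0], yg - p0[1])
    else:
        t = np.clip(((xg - p0[0]) * vx + (yg - p0[1]) * vy) / L2, 0.0, 1.0)
        d = np.hypot(xg - (p0[0] + t * vx), yg - (p0[1] + t * vy))
    return np.clip((width_um / 2.0 + edge_um / 2.0 - d) / edge_um, 0.0, 1.0)


def _quantize(img, meta: VideoMeta):
    return np.clip(np.round(img), 0, meta.max_value).astype(meta.dtype)


def _check_in_view(points, meta: VideoMeta, margin_um, frame_idx):
    w, h = meta.extent_um
    for x, y in points:
        if not (margin_um <= x <= w - margin_um and margin_um <= y <= h - margin_um):
            raise GenerationError(
                f"object leaves the field of view at frame {frame_idx} "
                f"(point {x:.2f},{y:.2f} µm)"
            )


def render_tethered_video(
    signed_freq_hz: float,
    meta: VideoMeta,
    cell_length_um: float = 5.0,
    cell_width_um: float = 0.8,
    tether_offset_um: float = 1.0,
    noise_sd: float = 4.0,
    seed: int = 0,
    theta0_rad: float = 0.0,
    background: float | None = None,
    contrast: float | None = None,
    tether_xy_um: tuple[float, float] | None = None,
) -> tuple[VideoStack, GroundTruth]:
    """Render a rod rotating rigidly about a fixed tether point.

    At frame t the rod orientation is ``theta0 + 2*pi*signed_freq_hz*t``
    (positive = CCW with y up); the rod center sits ``tether_offset_um`` from
    the tether along the rod axis.  Gaussian pixel noise of sd ``noise_sd``
    (in intensity counts) is added.  The exact angles are returned as
    ``GroundTruth.angle_trace``.
    """
    nyquist = 0.25 / meta.frame_interval_s
    if abs(signed_freq_hz) > nyquist:
        raise ParameterError(
            f"|signed_freq_hz| = {abs(signed_freq_hz)} exceeds the quarter-turn "
            f"per frame margin ({nyquist:.3g} Hz at this frame interval)"
        )
    if background is None:
        background = 0.8 * meta.max_value
    if contrast is None:
        contrast = 0.5 * meta.max_value
    rng = np.random.default_rng(seed)
    xg, yg = _um_grids(meta)
    w, h = meta.extent_um
    tether = tether_xy_um if tether_xy_um is not None else (w / 2.0, h / 2.0)
    times = meta.times_s
    theta = theta0_rad + 2.0 * np.pi * signed_freq_hz * times
    half = max(0.0, (cell_length_um - cell_width_um) / 2.0)
    edge = meta.pixel_size_um
    frames = np.empty((meta.n_frames, *meta.shape_px), dtype=meta.dtype)
    for t in range(meta.n_frames):
        u = np.array([math.cos(theta[t]), math.sin(theta[t])])
        center = np.asarray(tether) + tether_offset_um * u
        p0 = center - half * u
        p1 = center + half * u
        margin = cell_width_um / 2.0 + 2.0 * edge
        _check_in_view([p0, p1], meta, margin, t)
        img = background - contrast * _capsule_profile(
            xg, yg, p0, p1, cell_width_um, edge
        )
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
        frames[t] = _quantize(img, meta)
    truth = GroundTruth(
        kind="tethered",
        angle_trace=AngularTrace(
            times_s=times,
            theta_rad=theta,
            center_xy_um=tuple(tether),
            radius_um=tether_offset_um,
        ),
        params={
            "signed_freq_hz": signed_freq_hz,
            "cell_length_um": cell_length_um,
            "cell_width_um": cell_width_um,
            "tether_offset_um": tether_offset_um,
            "noise_sd": noise_sd,
            "seed": seed,
            "theta0_rad": theta0_rad,
        },
    )
    return VideoStack(meta=meta, frames=frames), truth


def render_gliding_video(
    tracks: list[Track],
    meta: VideoMeta,
    cell_length_um: float = 5.0,
    cell_width_um: float = 0.8,
    noise_sd: float = 4.0,
    seed: int = 0,
    background: float | None = None,
    contrast: float | None = None,
) -> tuple[VideoStack, GroundTruth]:
    """Render moving dark rods along the supplied center trajectories.

    Each rod is oriented along its instantaneous velocity (orientation held
    through stationary stretches).  Overlapping cells are allowed; the ground
    truth simply echoes the input tracks.
    """
    if background is None:
        background = 0.8 * meta.max_value
    if contrast is None:
        contrast = 0.5 * meta.max_value
    rng = np.random.default_rng(seed)
    xg, yg = _um_grids(meta)
    times = meta.times_s
    half = max(0.0, (cell_length_um - cell_width_um) / 2.0)
    edge = meta.pixel_size_um

    centers = []
    orients = []
    for tr in tracks:
        cx = np.interp(times, tr.t_s, tr.x_um)
        cy = np.interp(times, tr.t_s, tr.y_um)
        dx = np.gradient(cx)
        dy = np.gradient(cy)
        ang = np.zeros_like(cx)
        last = 0.0
        moving = np.hypot(dx, dy) > 1e-9
        first = np.argmax(moving) if moving.any() else None
        if first is not None:
            last = math.atan2(dy[first], dx[first])
        for i in range(times.size):
            if moving[i]:
                last = math.atan2(dy[i], dx[i])
            ang[i] = last
        centers.append(np.column_stack([cx, cy]))
        orients.append(ang)

    frames = np.empty((meta.n_frames, *meta.shape_px), dtype=meta.dtype)
    for t in range(meta.n_frames):
        profile = np.zeros(meta.shape_px)
        for c, ang in zip(centers, orients):
            u = np.array([math.cos(ang[t]), math.sin(ang[t])])
            p0 = c[t] - half * u
            p1 = c[t] + half * u
            margin = cell_width_um / 2.0 + 2.0 * edge
            _check_in_view([p0, p1], meta, margin, t)
            profile = np.maximum(
                profile, _capsule_profile(xg, yg, p0, p1, cell_width_um, edge)
            )
        img = background - contrast * profile
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
        frames[t] = _quantize(img, meta)
    truth = GroundTruth(
        kind="gliding",
        tracks=tracks,
        params={
            "cell_length_um": cell_length_um,
            "cell_width_um": cell_width_um,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )
    return VideoStack(meta=meta, frames=frames), truth


def stadium_path(cell_length_um: float, cell_width_um: float):
    """Closed stadium (capsule midline) path centered at the origin.

    Returns ``(perimeter_um, position_fn)`` where ``position_fn(s)`` maps arc
    length (wrapped modulo the perimeter, counterclockwise from the bottom
    left corner) to (x, y).
    """
    if cell_length_um <= cell_width_um:
        raise ParameterError("cell_length_um must exceed cell_width_um")
    a = (cell_length_um - cell_width_um) / 2.0
    r = cell_width_um / 2.0
    perimeter = 4.0 * a + 2.0 * math.pi * r

    def position(s):
        s = np.mod(np.asarray(s, dtype=float), perimeter)
        x = np.empty_like(s)
        y = np.empty_like(s)
        # bottom edge, left -> right
        m = s < 2 * a
        x[m] = -a + s[m]
        y[m] = -r
        # right cap
        m = (s >= 2 * a) & (s < 2 * a + math.pi * r)
        phi = -math.pi / 2 + (s[m] - 2 * a) / r
        x[m] = a + r * np.cos(phi)
        y[m] = r * np.sin(phi)
        # top edge, right -> left
        m = (s >= 2 * a + math.pi * r) & (s < 4 * a + math.pi * r)
        x[m] = a - (s[m] - 2 * a - math.pi * r)
        y[m] = r
        # left cap
        m = s >= 4 * a + math.pi * r
        phi = math.pi / 2 + (s[m] - 4 * a - math.pi * r) / r
        x[m] = -a + r * np.cos(phi)
        y[m] = r * np.sin(phi)
        return x, y

    return perimeter, position


def render_spot_video(
    belt_speed_um_s: float,
    meta: VideoMeta,
    cell_length_um: float = 10.0,
    cell_width_um: float = 1.0,
    n_loops: int = 1,
    psf_sigma_um: float = 0.15,
    photon_level: float = 2000.0,
    background_photons: float = 20.0,
    seed: int = 0,
    mode: str = "loop",
    osc_span_um: float = 1.0,
    s0_um: float = 0.0,
) -> tuple[VideoStack, GroundTruth]:
    """Render diffraction-limited spots moving along the belt path.

    In ``mode='loop'`` each of the ``n_loops`` spots (evenly phase-offset)
    traverses the closed stadium path at constant ``belt_speed_um_s``,
    wrapping at the path end.  In ``mode='oscillate'`` the spot bounces back
    and forth within a segment of length ``osc_span_um`` — the short
    back-and-forth regime.  Poisson photon noise is applied with expected
    ``photon_level`` photons per spot per frame over ``background_photons``
    per pixel.
    """
    if mode not in ("loop", "oscillate"):
        raise ParameterError("mode must be 'loop' or 'oscillate'")
    if psf_sigma_um < meta.pixel_size_um / 2.0:
        logger.warning(
            "psf_sigma_um=%.3g is below half a pixel (%.3g µm): undersampled PSF",
            psf_sigma_um,
            meta.pixel_size_um / 2.0,
        )
    perimeter, position = stadium_path(cell_length_um, cell_width_um)
    w, h = meta.extent_um
    if cell_length_um + 4 * psf_sigma_um > w or cell_width_um + 4 * psf_sigma_um > h:
        raise GenerationError("belt path does not fit the field of view")
    rng = np.random.default_rng(seed)
    xg, yg = _um_grids(meta)
    times = meta.times_s
    cx, cy = w / 2.0, h / 2.0

    def arc_position(t):
        if mode == "loop":
            return s0_um + belt_speed_um_s * t
        u = belt_speed_um_s * t / osc_span_um if osc_span_um > 0 else 0.0 * t
        cyc = np.mod(u, 2.0)
        return s0_um + osc_span_um * np.where(cyc < 1.0, cyc, 2.0 - cyc)

    amp = photon_level * meta.pixel_size_um**2 / (2.0 * math.pi * psf_sigma_um**2)
    spot_tracks = []
    spot_xy = []
    for k in range(max(1, n_loops)):
        offset = k * perimeter / max(1, n_loops)
        s = arc_position(times) + offset
        sx, sy = position(s)
        sx, sy = sx + cx, sy + cy
        spot_xy.append((sx, sy))
        spot_tracks.append(
            Track(track_id=k, t_s=times, x_um=sx, y_um=sy, source="spot")
        )
    frames = np.empty((meta.n_frames, *meta.shape_px), dtype=meta.dtype)
    for t in range(meta.n_frames):
        img = np.full(meta.shape_px, float(background_photons))
        for sx, sy in spot_xy:
            img += amp * np.exp(
                -((xg - sx[t]) ** 2 + (yg - sy[t]) ** 2) / (2.0 * psf_sigma_um**2)
            )
        frames[t] = _quantize(rng.poisson(img), meta)
    truth = GroundTruth(
        kind="spot",
        tracks=spot_tracks,
        params={
            "belt_speed_um_s": belt_speed_um_s,
            "cell_length_um": cell_length_um,
            "cell_width_um": cell_width_um,
            "n_loops": n_loops,
            "psf_sigma_um": psf_sigma_um,
            "photon_level": photon_level,
            "background_photons": background_photons,
            "seed": seed,
            "mode": mode,
            "osc_span_um": osc_span_um,
            "perimeter_um": perimeter,
        },
    )
    return VideoStack(meta=meta, frames=frames), truth
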
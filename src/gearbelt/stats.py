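"""Statistics and rotor metrics shared across the pipeline.

Gaussian KDE with Silverman bandwidth, exact (full enumeration) two-tailed
Mann-Whitney U for small samples with a tie-corrected normal approximation
beyond, fraction-in-circle probability, the optimal in-plane rotation angle
about a fixed axis ("spin angle"), and cumulative work integration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "DensityEstimate",
    "RankTestResult",
    "SpinAngleResult",
    "WorkProfile",
    "gaussian_kde",
    "mann_whitney_u",
    "fraction_in_region",
    "spin_angle",
    "integrate_work",
    "EXACT_MAX_N",
]

#: Largest pooled sample size for which the Mann-Whitney p-value is computed
#: by full enumeration (C(14, 7) = 3432 assignments).
EXACT_MAX_N = 14


@dataclass
class DensityEstimate:
    """KDE evaluated on a regular grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass
class RankTestResult:
    """Two-tailed Mann-Whitney U test result."""

    u_statistic: float
    p_value_two_tailed: float
    method: str  # "exact" or "normal_approx"
    n1: int
    n2: int


@dataclass
class SpinAngleResult:
    """Optimal rotation angle about a given axis and residual misfit."""

    angle_rad: float
    residual: float


@dataclass
class WorkProfile:
    """Running work integral over steps."""

    cumulative_work: np.ndarray
    total: float


def silverman_bandwidth(samples: np.ndarray) -> float:
    """1.06 * min(sd, IQR/1.34) * n^(-1/5)."""
    x = np.asarray(samples, dtype=float)
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 1.06 * scale * x.size ** (-0.2)


def gaussian_kde(
    samples,
    bandwidth_rule: str = "silverman",
    bandwidth: float | None = None,
    grid_size: int = 512,
) -> DensityEstimate:
    """Gaussian-kernel density estimate on a grid spanning the data
    ± 4 bandwidths.

    ``bandwidth_rule`` is ``"silverman"`` (default) or ``"fixed"`` with an
    explicit ``bandwidth``.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: zero spread")
    if bandwidth_rule == "silverman":
        h = silverman_bandwidth(x)
    elif bandwidth_rule == "fixed":
        if bandwidth is None or bandwidth <= 0:
            raise ValueError("fixed rule requires bandwidth > 0")
        h = float(bandwidth)
    else:
        raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")
    grid = np.linspace(x.min() - 4 * h, x.max() + 4 * h, grid_size)
    z = (grid[:, None] - x[None, :]) / h
    density = np.exp(-0.5 * z * z).sum(axis=1) / (x.size * h * math.sqrt(2 * math.pi))
    return DensityEstimate(grid=grid, density=density, bandwidth=h)


def _u_from_ranks(rank_sum_1: float, n1: int) -> float:
    return rank_sum_1 - n1 * (n1 + 1) / 2.0


def mann_whitney_u(x, y) -> RankTestResult:
    """Two-tailed Mann-Whitney U with midranks for ties.

    For pooled sizes n1 + n2 <= 14 the p-value is exact: all C(n, n1) label
    assignments are enumerated and the smaller tail is doubled (capped at 1).
    Larger samples use the normal approximation with tie correction and a
    0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u1 = _u_from_ranks(float(ranks[:n1].sum()), n1)
    if np.ptp(pooled) == 0:
        return RankTestResult(u1, 1.0, "exact", n1, n2)
    n = n1 + n2
    if n <= EXACT_MAX_N:
        us = np.array(
            [
                _u_from_ranks(float(ranks[list(idx)].sum()), n1)
                for idx in combinations(range(n), n1)
            ]
        )
        eps = 1e-9
        p_le = np.mean(us <= u1 + eps)
        p_ge = np.mean(us >= u1 - eps)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return RankTestResult(u1, float(p), "exact", n1, n2)
    mean = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return RankTestResult(u1, 1.0, "normal_approx", n1, n2)
    # continuity correction toward the mean
    z = (u1 - mean - 0.5 * np.sign(u1 - mean)) / math.sqrt(var)
    p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return RankTestResult(u1, p, "normal_approx", n1, n2)


def fraction_in_region(points, center, radius: float) -> float:
    """Fraction of 2D points within (inclusive) a circle."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 1:
        raise ValueError("need at least one point")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    c = np.asarray(center, dtype=float)
    d = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])
    return float(np.mean(d <= radius))


def spin_angle(reference_coords, current_coords, axis) -> SpinAngleResult:
    """Optimal rotation angle about ``axis`` mapping reference onto current.

    Both point sets are projected onto the plane perpendicular to the axis
    and centered on their in-plane centroids; the closed-form optimal
    rotation is ``atan2(sum cross, sum dot)`` over matched pairs, and the
    residual is the RMS in-plane misfit after applying it.
    """
    ref = np.atleast_2d(np.asarray(reference_coords, dtype=float))
    cur = np.atleast_2d(np.asarray(current_coords, dtype=float))
    if ref.shape != cur.shape or ref.shape[0] < 2 or ref.shape[1] != 3:
        raise ValueError("need matched (n >= 2, 3) coordinate arrays")
    ax = np.asarray(axis, dtype=float)
    nrm = np.linalg.norm(ax)
    if nrm < 1e-12:
        raise ValueError("axis norm is ~0")
    ax = ax / nrm
    # orthonormal in-plane basis
    trial = np.array([1.0, 0.0, 0.0])
    if abs(ax @ trial) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(ax, trial)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(ax, e1)
    a = np.column_stack([ref @ e1, ref @ e2])
    b = np.column_stack([cur @ e1, cur @ e2])
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    if np.max(np.hypot(a[:, 0], a[:, 1])) < 1e-12:
        raise ValueError("all points lie on the axis; angle undefined")
    cross = float(np.sum(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]))
    dot = float(np.sum(a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1]))
    angle = math.atan2(cross, dot)
    c, s = math.cos(angle), math.sin(angle)
    rot = np.column_stack([a[:, 0] * c - a[:, 1] * s, a[:, 0] * s + a[:, 1] * c])
    residual = float(np.sqrt(np.mean(np.sum((rot - b) ** 2, axis=1))))
    return SpinAngleResult(angle_rad=angle, residual=residual)


def integrate_work(forces, displacements) -> WorkProfile:
    """Cumulative sum of per-step force x displacement products."""
    f = np.asarray(forces, dtype=float)
    d = np.asarray(displacements, dtype=float)
    if f.shape != d.shape or f.ndim != 1 or f.size == 0:
        raise ValueError("forces and displacements must be equal-length 1D arrays")
    cum = np.cumsum(f * d)
    return WorkProfile(cumulative_work=cum, total=float(cum[-1]))
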
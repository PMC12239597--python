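import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu, rankdata

from gearbelt import stats
from gearbelt.stats import (
    fraction_in_region,
    gaussian_kde,
    integrate_work,
    mann_whitney_u,
    spin_angle,
)


def mw_enumeration_oracle(x, y):
    """Independent oracle: U by pair counting, p by label enumeration."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)

    def u_stat(a, b):
        gt = sum(1 for ai in a for bj in b if ai > bj)
        ties = sum(1 for ai in a for bj in b if ai == bj)
        return gt + 0.5 * ties

    u_obs = u_stat(x, y)
    pooled = np.concatenate([x, y])
    us = [
        u_stat(pooled[list(idx)],
               pooled[[i for i in range(n1 + n2) if i not in idx]])
        for idx in itertools.combinations(range(n1 + n2), n1)
    ]
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs + 1e-9)
    p_ge = np.mean(us >= u_obs - 1e-9)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


class TestKDE:
    def test_standard_normal_density_at_zero(self):
        rng = np.random.default_rng(1)
        est = gaussian_kde(rng.normal(size=10_000))
        at0 = np.interp(0.0, est.grid, est.density)
        assert at0 == pytest.approx(1 / math.sqrt(2 * math.pi), abs=0.02)

    def test_two_point_closed_form(self):
        est = gaussian_kde([-1.0, 1.0], bandwidth_rule="fixed", bandwidth=1.0)
        at0 = np.interp(0.0, est.grid, est.density)
        # f(0) = mean of two unit-bandwidth kernels at distance 1
        expected = math.exp(-0.5) / math.sqrt(2 * math.pi)
        assert at0 == pytest.approx(expected, rel=1e-3)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        a = gaussian_kde(x, bandwidth_rule="fixed", bandwidth=0.3)
        b = gaussian_kde(x + 5.0, bandwidth_rule="fixed", bandwidth=0.3)
        assert np.allclose(b.grid, a.grid + 5.0)
        assert np.allclose(b.density, a.density)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            gaussian_kde([3.0, 3.0, 3.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_integral_is_one(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.gamma(2.0, 1.5, size=rng.integers(10, 500))
        est = gaussian_kde(x)
        assert est.integral() == pytest.approx(1.0, abs=0.01)

    def test_silverman_bandwidth_formula(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        est = gaussian_kde(x)
        sd = np.std(x, ddof=1)
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        expected = 1.06 * min(sd, iqr / 1.34) * 100 ** (-0.2)
        assert est.bandwidth == pytest.approx(expected)


class TestMannWhitney:
    def test_identical_samples(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value_two_tailed == 1.0

    def test_fully_separated_three_three(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0.0
        assert res.method == "exact"
        assert res.p_value_two_tailed == pytest.approx(0.1)  # 2/C(6,3)

    def test_fully_separated_six_six(self):
        res = mann_whitney_u(np.arange(6) + 100.0, np.arange(6.0))
        assert res.method == "exact"
        assert res.p_value_two_tailed == pytest.approx(2 / 924)

    def test_all_constant(self):
        res = mann_whitney_u([5.0] * 4, [5.0] * 9)
        assert res.p_value_two_tailed == 1.0
        assert res.method == "exact"

    def test_u_range_invariant(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=8), rng.normal(size=5)
        res = mann_whitney_u(x, y)
        assert 0 <= res.u_statistic <= res.n1 * res.n2

    @given(
        st.lists(st.integers(0, 5), min_size=1, max_size=6),
        st.lists(st.integers(0, 5), min_size=1, max_size=6),
    )
    @settings(max_examples=60, deadline=None)
    def test_exact_matches_enumeration_oracle(self, x, y):
        if len(x) + len(y) > 10:
            return
        res = mann_whitney_u(x, y)
        u_or, p_or = mw_enumeration_oracle(x, y)
        assert res.method == "exact"
        assert res.u_statistic == pytest.approx(u_or)
        assert res.p_value_two_tailed == pytest.approx(p_or)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_exact_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=6)
        y = rng.normal(1.0, 1.0, size=7)
        res = mann_whitney_u(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.u_statistic == pytest.approx(ref.statistic)
        assert res.p_value_two_tailed == pytest.approx(ref.pvalue)

    def test_large_sample_normal_approx(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=40)
        y = rng.normal(0.8, 1.0, size=45)
        res = mann_whitney_u(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.method == "normal_approx"
        assert res.p_value_two_tailed == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestFractionInRegion:
    def test_all_at_center(self):
        pts = np.zeros((10, 2))
        assert fraction_in_region(pts, (0, 0), 1.0) == 1.0

    def test_uniform_square_quarter_pi(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(-1, 1, size=(10_000, 2))
        frac = fraction_in_region(pts, (0.0, 0.0), 1.0)
        assert frac == pytest.approx(math.pi / 4, abs=0.02)

    def test_mixture_mass_recovery(self):
        # 82% of mass inside the circle by construction
        rng = np.random.default_rng(7)
        n = 10_000
        inside = rng.random(n) < 0.82
        r = np.where(inside, rng.random(n) * 0.9, 1.1 + rng.random(n))
        phi = rng.uniform(0, 2 * np.pi, n)
        pts = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
        assert fraction_in_region(pts, (0, 0), 1.0) == pytest.approx(0.82,
                                                                     abs=0.02)

    def test_boundary_inclusive(self):
        assert fraction_in_region([[1.0, 0.0]], (0, 0), 1.0) == 1.0

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            fraction_in_region([[0, 0]], (0, 0), 0.0)


def _rotate_z(coords, angle):
    c, s = math.cos(angle), math.sin(angle)
    rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    return coords @ rot.T


class TestSpinAngle:
    def _cloud(self, seed=0, n=30):
        return np.random.default_rng(seed).normal(size=(n, 3))

    def test_recovers_36_degrees(self):
        ref = self._cloud()
        cur = _rotate_z(ref, math.radians(36.0))
        res = spin_angle(ref, cur, [0, 0, 1])
        assert res.angle_rad == pytest.approx(math.radians(36.0), abs=1e-9)
        assert res.residual < 1e-9

    def test_identity_zero(self):
        ref = self._cloud(1)
        res = spin_angle(ref, ref, [0, 0, 1])
        assert res.angle_rad == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry(self):
        ref = self._cloud(2)
        cur = _rotate_z(ref, 0.8)
        fwd = spin_angle(ref, cur, [0, 0, 1])
        bwd = spin_angle(cur, ref, [0, 0, 1])
        assert fwd.angle_rad == pytest.approx(-bwd.angle_rad)

    def test_jittered_matches_grid_search_oracle(self):
        rng = np.random.default_rng(3)
        ref = self._cloud(3)
        theta = 0.9
        cur = _rotate_z(ref, theta) + rng.normal(0, 0.02, ref.shape)
        res = spin_angle(ref, cur, [0, 0, 1])
        # brute-force 0.01-degree grid over the misfit objective
        grid = np.deg2rad(np.arange(-18000, 18001) * 0.01)
        best, best_cost = None, np.inf
        a = ref[:, :2] - ref[:, :2].mean(0)
        b = cur[:, :2] - cur[:, :2].mean(0)
        cross = np.sum(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])
        dot = np.sum(a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1])
        cost = -(np.cos(grid) * dot + np.sin(grid) * cross)
        best = grid[int(np.argmin(cost))]
        assert res.angle_rad == pytest.approx(best, abs=np.deg2rad(0.01))
        assert res.angle_rad == pytest.approx(theta, abs=0.02)

    def test_arbitrary_axis(self):
        axis = np.array([1.0, 2.0, 2.0]) / 3.0
        ref = self._cloud(4)
        angle = -0.5
        k = axis
        # Rodrigues rotation about the axis
        def rot(v):
            return (v * math.cos(angle)
                    + np.cross(k, v) * math.sin(angle)
                    + k * (k @ v) * (1 - math.cos(angle)))
        cur = np.array([rot(v) for v in ref])
        res = spin_angle(ref, cur, axis)
        assert res.angle_rad == pytest.approx(angle, abs=1e-9)

    def test_zero_axis_rejected(self):
        with pytest.raises(ValueError):
            spin_angle(self._cloud(), self._cloud(), [0, 0, 0])

    def test_points_on_axis_rejected(self):
        pts = np.column_stack([np.zeros(5), np.zeros(5), np.arange(5.0)])
        with pytest.raises(ValueError):
            spin_angle(pts, pts, [0, 0, 1])


class TestIntegrateWork:
    def test_constant_torque_full_turn(self):
        n = 100
        torque = np.full(n, 3.0)
        dtheta = np.full(n, 2 * math.pi / n)
        prof = integrate_work(torque, dtheta)
        assert prof.total == pytest.approx(6 * math.pi)
        assert prof.cumulative_work[0] == pytest.approx(torque[0] * dtheta[0])

    def test_opposite_passes_negate(self):
        rng = np.random.default_rng(8)
        torque = rng.normal(size=50)
        dtheta = np.full(50, 0.1)
        fwd = integrate_work(torque, dtheta)
        bwd = integrate_work(torque, -dtheta)
        assert bwd.total == pytest.approx(-fwd.total)

    def test_tilted_periodic_profile_favors_cw(self):
        # torque landscape with a constant CW-favoring tilt: the work to
        # rotate a full turn CW is lower than CCW by 2*pi*tilt, analytically
        n = 3600
        dtheta = 2 * math.pi / n
        theta = np.arange(n) * dtheta
        tilt = 0.5
        torque = lambda th: np.sin(3 * th) + tilt  # noqa: E731
        w_ccw = integrate_work(torque(theta), np.full(n, dtheta)).total
        w_cw = integrate_work(torque(theta[::-1]), np.full(n, -dtheta)).total
        assert w_cw < w_ccw
        assert w_ccw - w_cw == pytest.approx(2 * 2 * math.pi * tilt, rel=1e-3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            integrate_work([1.0, 2.0], [0.1])
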
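"""Correlation functions and change-of-support covariances against
independent quadrature / Monte-Carlo oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate
from scipy.spatial.distance import cdist
from shapely.geometry import box

from cosstack import (
    BlockSupport,
    GeometryCache,
    KernelParams,
    PointSupport,
    PredPoint,
    TimeInterval,
    build_cov_blocks,
    build_cov_cross,
    build_cov_points,
    build_cov_pred,
    matern_correlation,
    polygon_mc_average,
    temporal_block_integral,
    temporal_point_integral,
)
from cosstack.supports import PolygonSampleCache


def quad_block_oracle(I1, I2, phi2):
    """Adaptive 2-D quadrature of the exponential temporal kernel.

    The inner integral is split at the |t - t'| kink so the adaptive rule
    reaches full precision.
    """

    def inner(tp):
        pts = [tp] if I1.a < tp < I1.b else None
        val, _ = integrate.quad(
            lambda t: np.exp(-phi2 * abs(t - tp)),
            I1.a, I1.b, points=pts, epsabs=1e-13, epsrel=1e-13, limit=200,
        )
        return val

    val, _ = integrate.quad(inner, I2.a, I2.b, epsabs=1e-12, epsrel=1e-12, limit=200)
    return val


class TestMatern:
    def test_zero_distance_is_one(self):
        for nu in (0.5, 1.0, 1.5, 2.7):
            assert matern_correlation(0.0, 3.0, nu) == pytest.approx(1.0)

    def test_half_smoothness_is_exponential(self):
        assert matern_correlation(0.5, 4.0, 0.5) == pytest.approx(np.exp(-2.0), rel=1e-12)

    def test_bessel_form_matches_three_halves_closed_form(self):
        # generic Bessel evaluation vs the nu = 3/2 closed form (1+x)e^{-x}
        d = np.linspace(1e-4, 3.0, 50)
        via_bessel = matern_correlation(d, 1.0, 1.5000000001)
        closed = (1 + d) * np.exp(-d)
        assert np.allclose(via_bessel, closed, atol=1e-6)
        assert matern_correlation(1.0, 1.0, 1.5) == pytest.approx(2 * np.exp(-1.0), rel=1e-12)

    @given(
        d=st.floats(0.01, 10.0),
        phi=st.floats(0.1, 10.0),
        nu=st.sampled_from([0.5, 1.0, 1.5, 2.5]),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_decreasing_in_distance_and_decay(self, d, phi, nu):
        eps = 1e-4
        assert matern_correlation(d + eps, phi, nu) <= matern_correlation(d, phi, nu)
        assert matern_correlation(d, phi + eps, nu) <= matern_correlation(d, phi, nu) + 1e-15

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            matern_correlation(-0.1, 1.0, 0.5)
        with pytest.raises(ValueError):
            matern_correlation(1.0, -1.0, 0.5)
        with pytest.raises(ValueError):
            matern_correlation(1.0, 1.0, 0.0)

    def test_underflow_floors_at_zero(self):
        assert matern_correlation(1e6, 10.0, 0.5) == 0.0
        assert matern_correlation(1e6, 10.0, 2.2) == 0.0


class TestTemporalBlockIntegral:
    def test_same_interval_closed_form(self):
        # (2/phi^2)(phi T - 1 + e^{-phi T}) for I1 = I2 = (0, T)
        I = TimeInterval(0.0, 1.0)
        expected = 2.0 * (1.0 - 1.0 + np.exp(-1.0))
        got = temporal_block_integral(I, I, 1.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(quad_block_oracle(I, I, 1.0), rel=1e-9)

    def test_disjoint_intervals(self):
        I1, I2 = TimeInterval(0.0, 1.0), TimeInterval(2.0, 3.0)
        expected = np.exp(-3.0) + np.exp(-1.0) - 2.0 * np.exp(-2.0)
        assert temporal_block_integral(I1, I2, 1.0) == pytest.approx(expected, rel=1e-12)

    def test_nested_interval_matches_quadrature(self):
        I1, I2 = TimeInterval(0.0, 2.0), TimeInterval(0.5, 1.5)
        got = temporal_block_integral(I1, I2, 0.6)
        assert got == pytest.approx(quad_block_oracle(I1, I2, 0.6), rel=1e-8)

    @given(
        pts=st.lists(st.floats(0.0, 12.0), min_size=4, max_size=4, unique=True),
        phi2=st.floats(0.05, 5.0),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_symmetry_and_quadrature_agreement(self, pts, phi2):
        a, b, c, d = sorted(pts)
        # exercise all configurations by pairing endpoints three ways
        for (lo1, hi1), (lo2, hi2) in [
            ((a, b), (c, d)),   # disjoint
            ((a, c), (b, d)),   # overlapping
            ((a, d), (b, c)),   # nested
        ]:
            if hi1 - lo1 < 1e-9 or hi2 - lo2 < 1e-9:
                continue
            I1, I2 = TimeInterval(lo1, hi1), TimeInterval(lo2, hi2)
            v12 = temporal_block_integral(I1, I2, phi2)
            v21 = temporal_block_integral(I2, I1, phi2)
            assert v12 == v21  # exact symmetry after canonical ordering
            oracle = quad_block_oracle(I1, I2, phi2)
            assert v12 == pytest.approx(oracle, rel=1e-8, abs=1e-12)


class TestTemporalPointIntegral:
    @pytest.mark.parametrize(
        "t0, I, expected",
        [
            (0.0, (0.0, 1.0), 1.0 - np.exp(-1.0)),
            (1.0, (0.0, 2.0), 2.0 - 2.0 * np.exp(-1.0)),
            (3.0, (0.0, 1.0), np.exp(-2.0) - np.exp(-3.0)),
        ],
    )
    def test_closed_forms(self, t0, I, expected):
        got = temporal_point_integral(t0, TimeInterval(*I), 1.0)
        assert got == pytest.approx(expected, rel=1e-12)
        oracle, _ = integrate.quad(
            lambda t: np.exp(-abs(t0 - t)), I[0], I[1], epsabs=1e-13
        )
        assert got == pytest.approx(oracle, rel=1e-9)

    def test_small_decay_limit_is_interval_length(self):
        got = temporal_point_integral(0.3, TimeInterval(0.0, 2.5), 1e-9)
        assert got == pytest.approx(2.5, rel=1e-6)


class TestPolygonAveraging:
    def test_constant_kernel_averages_to_one(self):
        assert polygon_mc_average(lambda p: np.ones(len(p)), box(0, 0, 1, 1), 200, 3) == 1.0

    def test_coordinate_mean_over_unit_square(self):
        val = polygon_mc_average(lambda p: p[:, 0], box(0, 0, 1, 1), n_mc=100_000, seed=5)
        mc_se = np.sqrt(1.0 / 12.0 / 100_000)
        assert abs(val - 0.5) < 3 * mc_se

    def test_exponential_kernel_matches_grid_quadrature(self):
        centre = np.array([0.3, 0.7])

        def f(p):
            return np.exp(-np.linalg.norm(p - centre, axis=1))

        n_mc = 20_000
        val = polygon_mc_average(f, box(0, 0, 1, 1), n_mc=n_mc, seed=11)
        g = (np.arange(200) + 0.5) / 200.0
        gx, gy = np.meshgrid(g, g)
        grid = np.column_stack([gx.ravel(), gy.ravel()])
        oracle = f(grid).mean()
        # MC standard error of the mean of f
        se = f(PolygonSampleCache(box(0, 0, 1, 1), 11, n_mc).points).std() / np.sqrt(n_mc)
        assert abs(val - oracle) < 3 * se

    def test_sample_cache_reproducible_and_inside(self):
        poly = box(0.2, 0.2, 0.8, 0.9)
        c1 = PolygonSampleCache(poly, seed=7, n_mc=500)
        c2 = PolygonSampleCache(poly, seed=7, n_mc=500)
        assert np.array_equal(c1.points, c2.points)
        import shapely

        assert shapely.contains_xy(poly, c1.points[:, 0], c1.points[:, 1]).all()

    def test_degenerate_polygon_rejected(self):
        from shapely.geometry import Polygon

        line_like = Polygon([(0, 0), (1, 0), (0, 0)])
        with pytest.raises(ValueError):
            polygon_mc_average(lambda p: np.ones(len(p)), line_like, 10, 0)


class TestCovBuilders:
    def test_single_support_variance(self, kp):
        T = 2.0
        sup = [PointSupport(site=(0.1, 0.2), interval=TimeInterval(0.0, T))]
        C = build_cov_points(sup, kp)
        phi = kp.phi2
        expected = 2.0 / (phi**2 * T**2) * (phi * T - 1.0 + np.exp(-phi * T))
        assert C[0, 0] == pytest.approx(expected, rel=1e-10)
        assert C[0, 0] < 1.0  # averaging strictly reduces variance

    def test_points_matrix_properties(self, small_supports, kp):
        C = build_cov_points(small_supports, kp)
        assert np.allclose(C, C.T)
        w = np.linalg.eigvalsh(C)
        assert w[0] >= -1e-8 * abs(w[-1])
        assert np.all(np.diag(C) < 1.0)

    def test_shrinking_intervals_approach_separable_kernel(self, kp):
        eps = 1e-6
        sites = [(0.1, 0.1), (0.6, 0.4), (0.3, 0.8)]
        times = [1.0, 2.0, 3.5]
        sup = [
            PointSupport(site=s, interval=TimeInterval(t, t + eps))
            for s, t in zip(sites, times)
        ]
        C = build_cov_points(sup, kp)
        D = cdist(np.array(sites), np.array(sites))
        point_kernel = matern_correlation(D, kp.phi1, kp.nu) * np.exp(
            -kp.phi2 * np.abs(np.subtract.outer(times, times))
        )
        assert np.allclose(C, point_kernel, atol=1e-4)

    def test_cross_matches_dense_quadrature(self, kp):
        sup = [
            PointSupport(site=(0.25, 0.25), interval=TimeInterval(0.0, 1.0)),
            PointSupport(site=(0.75, 0.5), interval=TimeInterval(1.0, 2.0)),
            PointSupport(site=(0.5, 0.9), interval=TimeInterval(2.0, 3.0)),
        ]
        blocks = [
            BlockSupport(polygon=box(0, 0, 0.5, 0.5), interval=TimeInterval(0.0, 3.0)),
            BlockSupport(polygon=box(0.5, 0.5, 1, 1), interval=TimeInterval(0.0, 3.0)),
        ]
        n_mc = 4000
        got = build_cov_cross(sup, blocks, kp, n_mc=n_mc, seed=3)
        # brute force: 50x50 spatial grid per polygon, closed-form in time
        for j, s in enumerate(sup):
            for k, blk in enumerate(blocks):
                minx, miny, maxx, maxy = blk.polygon.bounds
                gx = np.linspace(minx, maxx, 51)[:-1] + (maxx - minx) / 100
                gy = np.linspace(miny, maxy, 51)[:-1] + (maxy - miny) / 100
                gxx, gyy = np.meshgrid(gx, gy)
                pts = np.column_stack([gxx.ravel(), gyy.ravel()])
                dvals = matern_correlation(
                    np.linalg.norm(pts - np.array(s.site), axis=1), kp.phi1, kp.nu
                )
                spatial = dvals.mean()
                tint = temporal_block_integral(s.interval, blk.interval, kp.phi2)
                expected = spatial * tint / (
                    s.interval.length() * blk.interval.length()
                )
                se = dvals.std() / np.sqrt(n_mc) * tint / 3.0 + 1e-6
                assert abs(got[j, k] - expected) < 3 * se

    def test_tiny_block_matches_point_diagonal(self, kp):
        s = (0.4, 0.6)
        I = TimeInterval(0.0, 1.0)
        sup = [PointSupport(site=s, interval=I)]
        side = 1e-4
        tiny = BlockSupport(
            polygon=box(s[0] - side / 2, s[1] - side / 2, s[0] + side / 2, s[1] + side / 2),
            interval=I,
        )
        got = build_cov_cross(sup, [tiny], kp, n_mc=200, seed=1)[0, 0]
        diag = build_cov_points(sup, kp)[0, 0]
        assert got == pytest.approx(diag, abs=1e-3)

    def test_constant_spatial_kernel_limit(self):
        kp0 = KernelParams(phi1=1e-8, nu=0.5, phi2=0.6, delta2=1.0)
        sup = [PointSupport(site=(0.2, 0.2), interval=TimeInterval(0.0, 1.0))]
        blk = [BlockSupport(polygon=box(0, 0, 1, 1), interval=TimeInterval(1.0, 2.0))]
        got = build_cov_cross(sup, blk, kp0, n_mc=100, seed=2)[0, 0]
        expected = temporal_block_integral(sup[0].interval, blk[0].interval, 0.6)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_blocks_matrix_properties(self, small_blocks, kp):
        C = build_cov_blocks(small_blocks, kp, n_mc=300, seed=5)
        assert np.allclose(C, C.T)
        w = np.linalg.eigvalsh(C)
        assert w[0] >= -1e-8 * abs(w[-1])
        assert np.all((np.diag(C) > 0) & (np.diag(C) < 1))

    def test_duplicate_blocks_rank_one(self, kp):
        blk = BlockSupport(polygon=box(0, 0, 1, 1), interval=TimeInterval(0.0, 1.0))
        C = build_cov_blocks([blk, blk], kp, n_mc=200, seed=9)
        assert np.allclose(C, C[0, 0])

    def test_blocks_match_dense_quadrature(self, kp):
        blocks = [
            BlockSupport(polygon=box(0, 0, 0.5, 1), interval=TimeInterval(0.0, 1.0)),
            BlockSupport(polygon=box(0.5, 0, 1, 1), interval=TimeInterval(0.0, 1.0)),
            BlockSupport(polygon=box(0, 0, 1, 0.5), interval=TimeInterval(1.0, 2.0)),
        ]
        n_mc = 3000
        got = build_cov_blocks(blocks, kp, n_mc=n_mc, seed=3)
        for k1 in range(3):
            for k2 in range(k1, 3):

                def grid(blk, n=40):
                    minx, miny, maxx, maxy = blk.polygon.bounds
                    gx = np.linspace(minx, maxx, n + 1)[:-1] + (maxx - minx) / (2 * n)
                    gy = np.linspace(miny, maxy, n + 1)[:-1] + (maxy - miny) / (2 * n)
                    gxx, gyy = np.meshgrid(gx, gy)
                    return np.column_stack([gxx.ravel(), gyy.ravel()])

                p1, p2 = grid(blocks[k1]), grid(blocks[k2])
                vals = matern_correlation(cdist(p1, p2), kp.phi1, kp.nu)
                spatial = vals.mean()
                tint = temporal_block_integral(
                    blocks[k1].interval, blocks[k2].interval, kp.phi2
                )
                expected = spatial * tint / (
                    blocks[k1].interval.length() * blocks[k2].interval.length()
                )
                se = vals.std() / np.sqrt(n_mc) + 1e-6
                assert abs(got[k1, k2] - expected) < 3 * se

    def test_pred_matrices(self, small_supports, kp):
        pred = [PredPoint(site=(0.2, 0.3), time=0.5), PredPoint(site=(0.9, 0.1), time=2.2)]
        cross, C_pred = build_cov_pred(pred, small_supports, kp)
        assert np.allclose(np.diag(C_pred), 1.0)
        assert np.allclose(C_pred, C_pred.T)
        # cross entries against 1-D quadrature
        for i, p in enumerate(pred):
            for j, s in enumerate(small_supports[:4]):
                spatial = matern_correlation(
                    float(np.hypot(p.site[0] - s.site[0], p.site[1] - s.site[1])),
                    kp.phi1, kp.nu,
                )
                tq, _ = integrate.quad(
                    lambda t: np.exp(-kp.phi2 * abs(p.time - t)),
                    s.interval.a, s.interval.b, epsabs=1e-13,
                )
                assert cross[i, j] == pytest.approx(
                    spatial * tq / s.interval.length(), rel=1e-8, abs=1e-12
                )

    def test_pred_point_at_support_with_shrunken_interval(self, kp):
        eps = 1e-7
        sup = [PointSupport(site=(0.5, 0.5), interval=TimeInterval(1.0, 1.0 + eps))]
        pred = [PredPoint(site=(0.5, 0.5), time=1.0)]
        cross, _ = build_cov_pred(pred, sup, kp)
        assert cross[0, 0] == pytest.approx(1.0, abs=1e-6)
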
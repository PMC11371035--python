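"""Projections, hull baselines, Gaussian fits and top-half centroids."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fiberfold.exceptions import GeometryError
from fiberfold.trace1d import (
    Box,
    Trace,
    centroid_top_half,
    convex_hull_baseline,
    fit_peaks_gaussian,
    measure_distance,
    project_box,
)


def lower_hull_oracle(x, y):
    """Brute-force lower convex envelope: a point is a hull vertex unless
    some chord between points on either side passes strictly below it."""
    n = len(x)
    verts = []
    for i in range(n):
        left = [j for j in range(n) if x[j] < x[i]]
        right = [k for k in range(n) if x[k] > x[i]]
        is_vertex = True
        for j in left:
            for k in right:
                line = y[j] + (y[k] - y[j]) * (x[i] - x[j]) / (x[k] - x[j])
                if line < y[i] - 1e-12:
                    is_vertex = False
                    break
            if not is_vertex:
                break
        if is_vertex:
            verts.append(i)
    return np.interp(x, x[verts], y[verts])


class TestProjectBox:
    def test_uniform_field(self):
        img = np.full((64, 64), 3.0)
        box = Box("equator_axial", anchor=(32.0, 32.0), length=40, width=5)
        trace = project_box(img, box)
        np.testing.assert_allclose(trace.intensity, 15.0)
        assert len(trace.coordinate) == 40

    def test_gaussian_ridge_area(self):
        # vertical ridge A*exp(-(x-x0)^2 / 2 sigma^2): projected area = A w sigma sqrt(2 pi)
        A, sigma, x0, w = 50.0, 3.0, 60.0, 7
        xx = np.arange(128, dtype=float)
        img = np.tile(A * np.exp(-0.5 * ((xx - x0) / sigma) ** 2), (64, 1))
        box = Box("equator_axial", anchor=(64.0, 32.0), length=120, width=w)
        trace = project_box(img, box)
        area = np.trapezoid(trace.intensity, trace.coordinate)
        assert area == pytest.approx(A * w * sigma * math.sqrt(2 * math.pi), rel=0.01)

    def test_meridian_box(self):
        img = np.zeros((64, 64))
        img[40, :] = 2.0
        box = Box("meridian_axial", anchor=(32.0, 32.0), length=60, width=9)
        trace = project_box(img, box)
        j = int(np.argmax(trace.intensity))
        assert trace.coordinate[j] == pytest.approx(8.0)  # row 40 - anchor 32
        assert trace.intensity[j] == pytest.approx(18.0)

    def test_oriented_matches_axial_on_isotropic(self):
        yy, xx = np.indices((128, 128), dtype=float)
        img = 100.0 * np.exp(-np.hypot(xx - 63.5, yy - 63.5) / 20.0)
        ax = Box("equator_axial", anchor=(63.5, 63.5), length=80, width=9)
        ori = Box("oriented", anchor=(63.5, 63.5), length=80, width=9, angle=45.0)
        t_ax = project_box(img, ax)
        t_ori = project_box(img, ori)
        # compare on the common coordinate grid
        interp = np.interp(t_ax.coordinate, t_ori.coordinate, t_ori.intensity)
        np.testing.assert_allclose(interp, t_ax.intensity, rtol=0.02)

    def test_sentinel_pixels_renormalized(self):
        img = np.full((32, 32), 4.0)
        img[10, :] = -100.0  # a gap row inside the box
        box = Box("equator_axial", anchor=(16.0, 11.0), length=20, width=5)
        trace = project_box(img, box, sentinel_threshold=0.0)
        np.testing.assert_allclose(trace.intensity, 20.0)  # renormalized to width 5

    def test_box_outside_raises(self):
        with pytest.raises(GeometryError):
            project_box(np.ones((16, 16)), Box("oriented", (100.0, 100.0), 10, 3))


class TestConvexHull:
    def test_worked_example(self):
        trace = Trace(np.arange(5.0), np.array([4.0, 3.0, 5.0, 2.0, 6.0]))
        baseline = convex_hull_baseline(trace)
        np.testing.assert_allclose(baseline, [4.0, 3.0, 2.5, 2.0, 6.0])
        np.testing.assert_allclose(trace.intensity - baseline, [0.0, 0.0, 2.5, 0.0, 0.0])

    def test_convex_input_is_its_own_baseline(self):
        x = np.linspace(-5, 5, 21)
        trace = Trace(x, x**2)
        np.testing.assert_allclose(convex_hull_baseline(trace), x**2, atol=1e-12)

    def test_translation_equivariance(self, rng):
        x = np.arange(30.0)
        y = rng.uniform(0, 10, size=30)
        t0 = Trace(x, y)
        t1 = Trace(x, y + 7.5)
        np.testing.assert_allclose(
            convex_hull_baseline(t1), convex_hull_baseline(t0) + 7.5, atol=1e-9
        )

    def test_baseline_below_trace_and_touching(self, rng):
        x = np.arange(50.0)
        y = rng.uniform(0, 100, size=50)
        baseline = convex_hull_baseline(Trace(x, y))
        assert np.all(baseline <= y + 1e-9)
        assert np.sum(np.isclose(baseline, y)) >= 2

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(min_value=0, max_value=100), min_size=3, max_size=50)
    )
    def test_matches_brute_force_oracle(self, ys):
        x = np.arange(len(ys), dtype=float)
        y = np.array(ys, dtype=float)
        baseline = convex_hull_baseline(Trace(x, y))
        np.testing.assert_allclose(baseline, lower_hull_oracle(x, y), atol=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            convex_hull_baseline(Trace(np.arange(2.0), np.zeros(2)))


class TestGaussianFits:
    def test_single_noise_free_gaussian(self):
        x = np.arange(256.0)
        area, c, s = 5000.0, 120.0, 4.0
        y = area * np.exp(-0.5 * ((x - c) / s) ** 2) / (s * math.sqrt(2 * math.pi))
        fits = fit_peaks_gaussian(Trace(x, y), [118.0], background="gaussians",
                                  n_background_gaussians=0)
        assert fits[0].center == pytest.approx(c, rel=1e-3)
        assert fits[0].area == pytest.approx(area, rel=1e-3)
        assert fits[0].sigma == pytest.approx(s, rel=1e-3)
        assert not fits[0].flagged

    def test_two_separated_gaussians(self):
        x = np.arange(300.0)
        def g(a, c, s):
            return a * np.exp(-0.5 * ((x - c) / s) ** 2) / (s * math.sqrt(2 * math.pi))
        y = g(4000.0, 100.0, 4.0) + g(2500.0, 124.0, 4.0)  # 6 sigma apart
        fits = fit_peaks_gaussian(Trace(x, y), [98.0, 126.0], background="gaussians",
                                  n_background_gaussians=0)
        assert fits[0].area == pytest.approx(4000.0, rel=0.005)
        assert fits[1].area == pytest.approx(2500.0, rel=0.005)
        assert fits[0].center == pytest.approx(100.0, abs=0.1)
        assert fits[1].center == pytest.approx(124.0, abs=0.1)

    def test_zero_trace_flagged(self):
        x = np.arange(100.0)
        fits = fit_peaks_gaussian(Trace(x, np.zeros(100)), [50.0],
                                  background="gaussians", n_background_gaussians=0)
        assert fits[0].flagged


class TestCentroidTopHalf:
    def test_worked_symmetric_example(self):
        trace = Trace(np.arange(7.0), np.array([0, 1, 3, 4, 3, 1, 0], dtype=float))
        m = centroid_top_half(trace, (0, 6))
        assert m.centroid == pytest.approx(3.0, abs=1e-12)
        assert m.height == 4.0

    def test_worked_asymmetric_example(self):
        trace = Trace(np.arange(7.0), np.array([0, 1, 3, 4, 2, 1, 0], dtype=float))
        m = centroid_top_half(trace, (0, 6))
        assert m.centroid == pytest.approx(8.0 / 3.0, abs=1e-12)

    def test_symmetric_peak_centroid_is_axis(self):
        x = np.linspace(-10, 10, 201)
        y = 50.0 * np.exp(-0.5 * ((x - 1.25) / 2.0) ** 2)
        m = centroid_top_half(Trace(x, y), (-10, 10))
        assert m.centroid == pytest.approx(1.25, abs=1e-9)

    def test_scale_invariance(self):
        x = np.arange(7.0)
        y = np.array([0, 1, 3, 4, 2, 1, 0], dtype=float)
        m1 = centroid_top_half(Trace(x, y), (0, 6))
        m2 = centroid_top_half(Trace(x, 10.0 * y), (0, 6))
        assert m1.centroid == pytest.approx(m2.centroid, abs=1e-12)

    def test_halfwidth_interpolated(self):
        x = np.arange(7.0)
        y = np.array([0, 1, 3, 4, 3, 1, 0], dtype=float)
        m = centroid_top_half(Trace(x, y), (0, 6))
        # level 2: crossings at x = 1.5 and 4.5
        assert m.halfwidth == pytest.approx(3.0)
        assert m.triangular_area == pytest.approx(12.0)

    def test_flat_window_flagged(self):
        m = centroid_top_half(Trace(np.arange(5.0), np.full(5, 2.0)), (0, 4))
        assert m.flagged

    def test_triangular_over_gauss_ratio_closed_form(self):
        # height * FWHM over the Gaussian area tends to
        # sqrt(8 ln 2) / sqrt(2 pi) ~ 0.9394 for a pure Gaussian
        x = np.linspace(-40, 40, 4001)
        area, s = 1000.0, 5.0
        y = area * np.exp(-0.5 * (x / s) ** 2) / (s * math.sqrt(2 * math.pi))
        m = centroid_top_half(Trace(x, y), (-40, 40))
        expected = math.sqrt(8 * math.log(2)) / math.sqrt(2 * math.pi)
        assert m.triangular_area / area == pytest.approx(expected, rel=1e-3)

    def test_centroid_noise_variance_sane(self, rng):
        # under 5% multiplicative noise the centroid stays unbiased and its
        # spread remains of the same order as the Gaussian-fit center spread
        # (within 3x in variance; the half-height level itself jitters with
        # the noisy peak maximum, which costs the centroid some efficiency)
        x = np.arange(120.0)
        area, c, s = 1.0e4, 60.0, 4.0
        clean = area * np.exp(-0.5 * ((x - c) / s) ** 2) / (s * math.sqrt(2 * math.pi))
        cents, gauss = [], []
        for _ in range(60):
            y = clean * rng.normal(1.0, 0.05, size=x.size)
            t = Trace(x, y)
            cents.append(centroid_top_half(t, (40, 80)).centroid)
            gauss.append(
                fit_peaks_gaussian(t, [59.0], background="gaussians",
                                   n_background_gaussians=0)[0].center
            )
        assert np.mean(cents) == pytest.approx(c, abs=0.05)
        assert np.var(cents) <= 3.0 * np.var(gauss) + 1e-6


def test_measure_distance():
    assert measure_distance((0, 0), (3, 4)) == 5.0
    assert measure_distance((2, 7), (2, 7)) == 0.0
    assert measure_distance((10, 10), (13, 14)) == 5.0  # translation invariant
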
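"""Polar-mask geometry: construction, membership, IoU and area."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peakcloud.polarmask import (PolarMask, mask_area, mask_from_points,
                                 point_in_mask, polar_iou, rays_about_points,
                                 rays_from_points)


def unit_circle_points(n=36, r=1.0):
    ang = 2 * np.pi * np.arange(n) / n
    return np.column_stack([r * np.cos(ang), r * np.sin(ang)])


def smooth_random_rays(rng, n=36, base=1.0):
    """Random star-convex contour smooth at the bin scale, as elution
    features produce (low-order Fourier modulation of a circle)."""
    theta = 2 * np.pi * np.arange(n) / n
    r = base * (1.0 + 0.25 * np.sin(2 * theta + rng.uniform(0, 2 * np.pi))
                + 0.15 * np.cos(3 * theta + rng.uniform(0, 2 * np.pi)))
    return r


class TestMaskFromPoints:
    def test_exact_cover_gives_constant_rays(self):
        m = mask_from_points((0, 0), unit_circle_points())
        np.testing.assert_allclose(m.rays, 1.0, atol=1e-12)

    def test_single_point_fills_all_sectors(self):
        m = mask_from_points((0, 0), [(2.0, 0.0)])
        np.testing.assert_allclose(m.rays, 2.0)

    def test_empty_member_set_raises(self):
        with pytest.raises(ValueError):
            mask_from_points((0, 0), [])

    def test_dense_star_polygon_reconstruction(self):
        # sampling oracle: a densely sampled smooth star-convex region is
        # recovered to within one angular bin's chord error
        rng = np.random.default_rng(3)
        true_rays = smooth_random_rays(rng, base=1.2)

        def radius(theta):
            k = theta / (2 * np.pi / 36)
            k0 = np.floor(k).astype(int) % 36
            frac = k - np.floor(k)
            return (1 - frac) * true_rays[k0] + frac * true_rays[(k0 + 1) % 36]

        theta = rng.uniform(0, 2 * np.pi, 20000)
        r = radius(theta) * np.sqrt(rng.uniform(0, 1, 20000))
        # force boundary support in every sector
        bt = 2 * np.pi * np.arange(36) / 36
        theta = np.concatenate([theta, bt])
        r = np.concatenate([r, radius(bt)])
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        rec = rays_from_points((0, 0), pts)
        chord = 2 * np.pi / 36 * true_rays.max()
        assert np.abs(rec - true_rays).max() <= chord
        # and the reconstruction never loses a sample point
        assert point_in_mask(pts, PolarMask((0, 0), rec)).all()

    def test_members_always_inside_own_mask(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(200, 2))
        center = pts.mean(axis=0)
        m = mask_from_points(center, pts)
        assert point_in_mask(pts, m).all()

    def test_rays_about_points_matches_per_point_construction(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(40, 2))
        all_rays = rays_about_points(pts)
        for i in (0, 7, 39):
            np.testing.assert_allclose(
                all_rays[i], rays_from_points(pts[i], pts), atol=1e-12)


class TestPointInMask:
    def test_center_is_inside(self):
        m = PolarMask((1.0, -2.0), np.full(36, 0.5))
        assert point_in_mask((1.0, -2.0), m)

    def test_beyond_max_ray_is_outside(self):
        m = PolarMask((0, 0), np.linspace(0.1, 1.0, 36))
        assert not point_in_mask((1.5, 0.0), m)

    def test_monte_carlo_polygon_agreement(self):
        # oracle: matplotlib's independent point-in-polygon rasterization of
        # the mask boundary (densely subdivided along the interpolated
        # radius), compared on 1e5 random points
        from matplotlib.path import Path

        from peakcloud.polarmask import radius_at

        rng = np.random.default_rng(0)
        rays = smooth_random_rays(rng)
        m = PolarMask((0.2, -0.1), rays)
        fine = np.linspace(0, 2 * np.pi, 3600, endpoint=False)
        rf = radius_at(rays, fine)
        poly = Path(np.column_stack([0.2 + rf * np.cos(fine),
                                     -0.1 + rf * np.sin(fine)]))
        pts = np.column_stack([rng.uniform(-1.5, 2.0, 100_000),
                               rng.uniform(-1.8, 1.7, 100_000)])
        ours = point_in_mask(pts, m)
        theirs = poly.contains_points(pts)
        assert np.mean(ours == theirs) >= 0.999

        # against the coarse straight-edge 36-gon, any disagreement sits
        # within one interpolation chord of the boundary
        ang = 2 * np.pi * np.arange(36) / 36
        coarse = Path(np.column_stack([0.2 + rays * np.cos(ang),
                                       -0.1 + rays * np.sin(ang)]))
        bad = pts[ours != coarse.contains_points(pts)]
        theta = np.mod(np.arctan2(bad[:, 1] + 0.1, bad[:, 0] - 0.2), 2 * np.pi)
        dist = np.hypot(bad[:, 0] - 0.2, bad[:, 1] + 0.1)
        # chord radius in polar form: r(θ) = r0·r1·sinΔ / (r0·sin(θ−θ0) + r1·sin(θ1−θ))
        step = 2 * np.pi / 36
        k = np.floor(theta / step).astype(int) % 36
        r0, r1 = rays[k], rays[(k + 1) % 36]
        t0 = k * step
        chord_r = (r0 * r1 * np.sin(step)
                   / (r0 * np.sin(theta - t0) + r1 * np.sin(t0 + step - theta)))
        gap = np.abs(radius_at(rays, theta) - chord_r).max() + 1e-9
        assert np.abs(dist - radius_at(rays, theta)).max() <= gap


class TestPolarIoU:
    def test_identity_is_one(self):
        r = np.random.default_rng(1).uniform(0, 2, 36)
        assert polar_iou(r, r) == 1.0

    def test_zero_versus_nonzero_is_zero(self):
        assert polar_iou(np.zeros(36), np.ones(36)) == 0.0

    def test_double_rays_is_half(self):
        assert polar_iou(np.ones(36), np.full(36, 2.0)) == pytest.approx(0.5)

    def test_both_empty_defined_as_one(self):
        assert polar_iou(np.zeros(36), np.zeros(36)) == 1.0

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError):
            polar_iou(np.ones(36), np.ones(18))

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.01, 10.0), min_size=36, max_size=36),
           st.lists(st.floats(0.01, 10.0), min_size=36, max_size=36))
    def test_symmetric_bounded_and_scale_property(self, a, b):
        a, b = np.array(a), np.array(b)
        v = polar_iou(a, b)
        assert 0.0 <= v <= 1.0
        assert v == polar_iou(b, a)
        assert polar_iou(a, 2 * a) == pytest.approx(0.5)


class TestMaskArea:
    def test_zero_rays_zero_area(self):
        assert mask_area(PolarMask((0, 0), np.zeros(36))) == 0.0

    def test_regular_36gon_closed_form(self):
        area = mask_area(PolarMask((0, 0), np.ones(36)))
        assert area == pytest.approx(36 * 0.5 * np.sin(np.deg2rad(10.0)))
        assert area < np.pi  # inscribed polygon is smaller than the disc

    def test_doubling_rays_quadruples_area(self):
        r = np.random.default_rng(2).uniform(0.1, 1, 36)
        assert mask_area(PolarMask((0, 0), 2 * r)) == pytest.approx(
            4 * mask_area(PolarMask((0, 0), r)))
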
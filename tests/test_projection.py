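"""Hammer projection: closed-form examples, round-trip identity, and the
equal-area property that motivates auditing on the reprojected raster."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from panoscape.projection import (
    equirect_to_hammer,
    hammer_contains,
    hammer_forward,
    hammer_inverse,
    masked_class_proportions,
    naive_proportions,
    solid_angle_proportions,
)
from panoscape.rasters import EQUIRECTANGULAR, MASK_LABEL, SphericalRaster, lat_centers


def interior_grid(n=100):
    lons = np.linspace(-np.pi, np.pi, n + 2)[1:-1]
    lats = np.linspace(-np.pi / 2, np.pi / 2, n + 2)[1:-1]
    return np.meshgrid(lons, lats)


def sky_band_raster(width=2048, lat_deg=30.0):
    """Two-band sphere: class 1 (sky) above lat_deg, class 0 below."""
    h = width // 2
    labels = np.zeros((h, width), dtype=np.int64)
    labels[lat_centers(h) >= np.radians(lat_deg), :] = 1
    return SphericalRaster(labels, EQUIRECTANGULAR)


class TestForward:
    def test_projection_center_maps_to_origin(self):
        assert hammer_forward(0.0, 0.0) == (0.0, 0.0)

    def test_quarter_turn_on_equator(self):
        x, y = hammer_forward(np.pi / 2, 0.0)
        assert x == pytest.approx(1.5307337294603592, abs=1e-12)
        assert y == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(
        lon=st.floats(1e-6, np.pi - 1e-6),
        lat=st.floats(-np.pi / 2 + 1e-6, np.pi / 2 - 1e-6),
    )
    def test_mirror_symmetry_in_longitude(self, lon, lat):
        x, y = hammer_forward(lon, lat)
        xm, ym = hammer_forward(-lon, lat)
        assert xm == pytest.approx(-x, abs=1e-14)
        assert ym == pytest.approx(y, abs=1e-14)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            hammer_forward(4.0, 0.0)
        with pytest.raises(ValueError):
            hammer_forward(0.0, 2.0)

    def test_image_satisfies_ellipse_bound(self):
        lo, la = interior_grid(50)
        x, y = hammer_forward(lo, la)
        assert hammer_contains(x, y).all()


class TestInverse:
    def test_origin(self):
        assert hammer_inverse(0.0, 0.0) == (0.0, 0.0)

    def test_inverse_of_equatorial_quarter_turn(self):
        lon, lat = hammer_inverse(1.5307337294603592, 0.0)
        assert lon == pytest.approx(np.pi / 2, abs=1e-6)
        assert lat == pytest.approx(0.0, abs=1e-6)

    def test_exterior_point_signals(self):
        with pytest.raises(ValueError, match="exterior"):
            hammer_inverse(2.9, 1.0)
        lon, lat = hammer_inverse(2.9, 1.0, strict=False)
        assert np.isnan(lon) and np.isnan(lat)

    def test_round_trip_identity_on_grid(self):
        lo, la = interior_grid(100)
        x, y = hammer_forward(lo, la)
        lo2, la2 = hammer_inverse(x, y)
        assert np.max(np.abs(lo2 - lo)) < 1e-10
        assert np.max(np.abs(la2 - la)) < 1e-10

    def test_scalar_round_trip(self):
        x, y = hammer_forward(0.7, -0.3)
        lon, lat = hammer_inverse(x, y)
        assert lon == pytest.approx(0.7, abs=1e-10)
        assert lat == pytest.approx(-0.3, abs=1e-10)


def test_uniform_sphere_points_fill_ellipse_uniformly():
    """Equal-area property: uniformly distributed solid angle maps to
    uniform areal density inside the ellipse (chi-square GOF over a 10x10
    partition of the bounding box, expected counts from the ellipse's
    analytic cell coverage)."""
    rng = np.random.default_rng(20)
    n = 100_000
    lon = rng.uniform(-np.pi, np.pi, n)
    lat = np.arcsin(rng.uniform(-1.0, 1.0, n))
    x, y = hammer_forward(lon, lat)
    a, b = 2 * np.sqrt(2), np.sqrt(2)
    counts, xe, ye = np.histogram2d(x, y, bins=10, range=[[-a, a], [-b, b]])
    # expected cell probabilities: fine-grid coverage of the ellipse
    fx = np.linspace(-a, a, 4000)
    fy = np.linspace(-b, b, 2000)
    inside = hammer_contains(fx[:, None], fy[None, :])
    ix = np.clip(np.searchsorted(xe, fx, "right") - 1, 0, 9)
    iy = np.clip(np.searchsorted(ye, fy, "right") - 1, 0, 9)
    expected = np.zeros((10, 10))
    np.add.at(expected, (ix[:, None], iy[None, :]), inside)
    p_cell = (expected / expected.sum()).ravel()
    keep = p_cell > 0
    stat, p = sps.chisquare(
        counts.ravel()[keep], f_exp=n * p_cell[keep] / p_cell[keep].sum()
    )
    assert p > 0.01


class TestReprojection:
    def test_constant_raster_stays_constant(self):
        src = SphericalRaster(np.full((64, 128), 7, dtype=np.int64), EQUIRECTANGULAR)
        out = equirect_to_hammer(src, 256)
        assert out.geometry == "hammer"
        assert set(np.unique(out.values[out.mask])) == {7}
        assert set(np.unique(out.values[~out.mask])) == {MASK_LABEL}

    def test_sky_band_proportion_corrected(self):
        """A sky band above 30 deg covers (sin 90 - sin 30)/2 = 25 % of the
        sphere; the Hammer count recovers that while the naive
        equirectangular count returns the biased 60/180 = 33.3 %."""
        src = sky_band_raster(1024)
        naive = naive_proportions(src)[1]
        assert naive == pytest.approx(1 / 3, abs=0.01)
        ham = equirect_to_hammer(src, 1024)
        sky = masked_class_proportions(ham)[1]
        assert sky == pytest.approx(0.25, abs=0.01)
        assert abs(sky - naive) > 0.05

    def test_bilinear_on_labels_rejected(self):
        src = SphericalRaster(np.zeros((8, 16), dtype=np.int64), EQUIRECTANGULAR)
        with pytest.raises(ValueError, match="nearest"):
            equirect_to_hammer(src, 32, "bilinear")

    def test_rgb_bilinear_smoke(self):
        rng = np.random.default_rng(0)
        src = SphericalRaster(
            rng.integers(0, 256, (32, 64, 3), dtype=np.uint8), EQUIRECTANGULAR
        )
        out = equirect_to_hammer(src, 128, "bilinear")
        assert out.values.shape == (64, 128, 3)
        assert out.mask.any() and not out.mask.all()

    def test_labels_preserved_no_invention(self):
        rng = np.random.default_rng(1)
        src = SphericalRaster(
            rng.choice([3, 9, 11], size=(64, 128)), EQUIRECTANGULAR
        )
        out = equirect_to_hammer(src, 256)
        assert set(np.unique(out.values[out.mask])) <= {3, 9, 11}

    def test_mask_area_fraction_approaches_ellipse_ratio(self):
        src = SphericalRaster(np.zeros((64, 128), dtype=np.int64), EQUIRECTANGULAR)
        out = equirect_to_hammer(src, 1024)
        assert out.mask.mean() == pytest.approx(np.pi / 4, abs=2e-3)


class TestSolidAngleOracle:
    def test_single_class_normalization(self):
        src = SphericalRaster(np.full((16, 32), 5, dtype=np.int64), EQUIRECTANGULAR)
        assert solid_angle_proportions(src) == {5: 1.0}

    def test_band_closed_form(self):
        src = sky_band_raster(720)
        assert solid_angle_proportions(src)[1] == pytest.approx(0.25, abs=0.005)

    def test_empty_raster_rejected(self):
        src = SphericalRaster(np.zeros((0, 0), dtype=np.int64), EQUIRECTANGULAR)
        with pytest.raises(ValueError):
            solid_angle_proportions(src)

    def test_cross_oracle_agreement_random_labels(self):
        """Cosine-weighted counting on the equirectangular grid and plain
        counting on the Hammer grid measure the same solid angles."""
        rng = np.random.default_rng(7)
        src = SphericalRaster(rng.integers(0, 4, (512, 1024)), EQUIRECTANGULAR)
        weighted = solid_angle_proportions(src)
        ham = masked_class_proportions(equirect_to_hammer(src, 1024))
        for cls in weighted:
            assert ham[cls] == pytest.approx(weighted[cls], abs=0.01)
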
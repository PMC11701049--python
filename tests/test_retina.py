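"""Profile widths, peaks, contour classification, retinal regions."""

import numpy as np
import pytest

from octi.geometry import EyeModelParams
from octi.retina import (ProfileCurve, RetinalSampleGrid, angular_distance,
                         central_peak, classify_region, contour_80,
                         extract_profile, profile_points, retinal_point,
                         width_at_fraction)


def gaussian_curve(sigma=5.0, center=0.0, extent=80.0, step=0.25):
    t = np.arange(-extent, extent + step / 2, step)
    return ProfileCurve("horizontal", t,
                        np.exp(-0.5 * ((t - center) / sigma) ** 2))


class TestWidths:
    def test_gaussian_fwhm_closed_form(self):
        """FWHM of a Gaussian is 2*sigma*sqrt(2 ln 2) = 11.774 deg for
        sigma = 5 deg."""
        w = width_at_fraction(gaussian_curve(sigma=5.0), 0.5)
        assert not w.censored
        assert w.width == pytest.approx(2 * 5.0 * np.sqrt(2 * np.log(2)),
                                        abs=0.26)

    def test_triangular_80_width(self):
        """Triangular peak of base half-width 10 deg: 80% width = 4 deg."""
        t = np.arange(-80.0, 80.25, 0.25)
        v = np.maximum(0.0, 1.0 - np.abs(t) / 10.0)
        w = width_at_fraction(ProfileCurve("horizontal", t, v), 0.8)
        assert w.width == pytest.approx(4.0, abs=1e-9)

    def test_width80_le_fwhm(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            sigma = rng.uniform(2, 20)
            c = gaussian_curve(sigma=sigma, center=rng.uniform(-30, 30))
            w80 = width_at_fraction(c, 0.8)
            w50 = width_at_fraction(c, 0.5)
            assert w80.width <= w50.width

    def test_normalization_invariance(self):
        """Widths and offsets are unchanged by affine (min-max) rescaling."""
        c = gaussian_curve(sigma=7.0, center=4.0)
        v2 = 0.2 + 0.6 * c.values
        c2 = ProfileCurve(c.direction, c.abscissa, v2)
        assert width_at_fraction(c2, 0.5).width == pytest.approx(
            width_at_fraction(c, 0.5).width)
        assert central_peak(c2)[1] == central_peak(c)[1]

    def test_boundary_peak_is_censored(self):
        t = np.arange(-80.0, 80.25, 0.25)
        v = np.exp(0.05 * t)               # peak at the right boundary
        w = width_at_fraction(ProfileCurve("horizontal", t, v), 0.5)
        assert w.right_censored and not w.left_censored

    def test_constant_curve_rejected(self):
        t = np.arange(-80.0, 80.25, 0.25)
        with pytest.raises(ValueError):
            width_at_fraction(ProfileCurve("horizontal", t, np.ones_like(t)),
                              0.5)


class TestCentralPeak:
    def test_symmetric_peak_at_zero(self):
        v, off, tie = central_peak(gaussian_curve())
        assert off == 0.0 and not tie

    def test_shifted_peak(self):
        _v, off, _tie = central_peak(gaussian_curve(center=5.0))
        assert off == pytest.approx(5.0, abs=0.26)

    def test_tie_resolved_toward_center(self):
        t = np.arange(-10.0, 10.5, 0.5)
        v = np.zeros_like(t)
        v[np.argmin(np.abs(t - 3.0))] = 1.0
        v[np.argmin(np.abs(t + 7.0))] = 1.0
        _v, off, tie = central_peak(ProfileCurve("horizontal", t, v))
        assert off == pytest.approx(3.0)
        assert tie


@pytest.fixture(scope="module")
def grid():
    return RetinalSampleGrid.build(EyeModelParams(), ecc_step=1.0,
                                   meridian_step=2.0, extent=80.0)


def bump(grid, center_ecc, center_mer, sigma):
    E, M = np.meshgrid(grid.ecc, grid.meridian, indexing="ij")
    d = angular_distance(E, M, center_ecc, center_mer)
    v = np.exp(-0.5 * (d / sigma) ** 2)
    return (v - v.min()) / (v.max() - v.min())


class TestContour:
    def test_interior_gaussian_closed_no_overlap(self, grid):
        closed, overlap, comp = contour_80(grid, bump(grid, 0, 0, 8.0))
        assert closed and overlap == "none" and comp.any()

    def test_peak_on_nerve_disc_full_overlap(self, grid):
        v = bump(grid, grid.nerve_center[0], grid.nerve_center[1], 18.0)
        closed, overlap, _ = contour_80(grid, v)
        assert overlap == "full"

    def test_narrow_peak_near_disc_partial_overlap(self, grid):
        v = bump(grid, grid.nerve_center[0] + grid.nerve_radius,
                 grid.nerve_center[1], 6.0)
        _closed, overlap, _ = contour_80(grid, v)
        assert overlap == "partial"

    def test_boundary_peak_unclosed(self, grid):
        closed, _overlap, _ = contour_80(grid, bump(grid, 80.0, 200.0, 10.0))
        assert not closed

    def test_closure_invariant_to_meridian_origin(self, grid):
        """Rotating the meridian origin must not change the closure call
        (the super-level region is meridian-periodic)."""
        v = bump(grid, 20.0, 1.0, 12.0)    # straddles the meridian seam
        closed, overlap, comp = contour_80(grid, v)
        roll = len(grid.meridian) // 2
        closed_r, _o, comp_r = contour_80(grid, np.roll(v, roll, axis=1))
        assert closed == closed_r
        assert comp.sum() == comp_r.sum()


class TestRegions:
    @pytest.mark.parametrize("ecc,mer,region", [
        (0.0, 0.0, "fovea"),
        (2.0, 123.0, "fovea"),
        (4.0, 200.0, "parafovea"),
        (10.0, 90.0, "perifovea"),
        (50.0, 10.0, "peripheral"),
        (22.5, 0.0, "nerve_disc"),         # nerve-tilt eccentricity, nasal
    ])
    def test_classification(self, ecc, mer, region):
        assert classify_region(ecc, mer) == region

    def test_nerve_disc_overrides_annulus(self):
        # a point nasal at the nerve eccentricity but large disc radius
        assert classify_region(13.0, 0.0, nerve_radius=12.0) == "nerve_disc"


class TestProfilesAndGrid:
    def test_profile_points_conventions(self):
        """Positive horizontal abscissa is temporal (-x); positive vertical
        is superior (+y)."""
        t, pts = profile_points("horizontal", 11.165, extent=80, step=1.0)
        i = np.argmin(np.abs(t - 30.0))
        assert pts[i, 0] < 0                # temporal = -x
        j = np.argmin(np.abs(t + 30.0))
        assert pts[j, 0] > 0                # nasal = +x
        t, pts = profile_points("vertical", 11.165, extent=80, step=1.0)
        assert pts[np.argmin(np.abs(t - 30.0)), 1] > 0

    def test_grid_points_on_mid_surface(self, grid):
        pts = grid.points()
        assert np.allclose(np.linalg.norm(pts, axis=1), grid.radius)

    def test_extract_profile_matches_separable_field(self, grid):
        v = bump(grid, 0, 0, 10.0)
        prof = extract_profile(grid, v, "horizontal", step=0.5)
        _pv, off, _ = central_peak(prof)
        assert off == 0.0
        assert np.all(np.diff(prof.abscissa) > 0)

    def test_nasal_shifted_peak_stays_centered_vertically(self, grid):
        v = bump(grid, 10.0, 0.0, 12.0)     # peak 10 deg nasal
        ph = extract_profile(grid, v, "horizontal", step=0.5)
        pv = extract_profile(grid, v, "vertical", step=0.5)
        assert central_peak(ph)[1] == pytest.approx(-10.0, abs=0.6)
        assert central_peak(pv)[1] == pytest.approx(0.0, abs=0.6)

    def test_horizontal_profile_crosses_nerve_disc_nasally(self, grid):
        """The nerve-disc center sits at abscissa ~ -22.5 deg (nasal) on the
        horizontal profile."""
        ecc_n, mer_n = grid.nerve_center
        p_nerve = retinal_point(ecc_n, mer_n, grid.radius)
        t, pts = profile_points("horizontal", grid.radius, step=0.25)
        d = np.linalg.norm(pts - p_nerve, axis=1)
        assert t[np.argmin(d)] == pytest.approx(-22.5, abs=0.26)
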
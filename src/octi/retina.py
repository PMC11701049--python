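"""Retinal-surface sampling, MMEA profiles, and focality/steerability metrics.

Retinal coordinates are (eccentricity, meridian): eccentricity is the angle
in degrees from the posterior pole (the retinal center, fovea), meridian the
rotational position around it, measured from the nasal horizontal semi-axis
(+x) toward superior (+y).  The optic-nerve cross-section sits on the nasal
horizontal meridian at the nerve-tilt eccentricity (22.5 deg by default).

Profile sign conventions: horizontal profiles are positive toward temporal,
vertical profiles positive toward superior, diagonal profiles positive
toward temporal-superior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .geometry import EyeModelParams

#: meridian (deg) of the positive semi-axis per profile direction
PROFILE_MERIDIANS = {"horizontal": 180.0, "vertical": 90.0, "diagonal": 135.0}

#: macular annulus outer radii, deg of eccentricity (configurable)
DEFAULT_REGION_RADII = {"fovea": 2.6, "parafovea": 6.2, "perifovea": 13.7}


def retinal_point(ecc_deg, meridian_deg, radius: float) -> np.ndarray:
    """3D point(s) on the retinal mid-surface sphere."""
    e = np.deg2rad(np.asarray(ecc_deg, dtype=float))
    m = np.deg2rad(np.asarray(meridian_deg, dtype=float))
    return radius * np.stack(
        [np.sin(e) * np.cos(m), np.sin(e) * np.sin(m), np.cos(e)], axis=-1)


def angular_distance(ecc1, mer1, ecc2, mer2) -> np.ndarray:
    """Great-circle angle (deg) between two retinal coordinates."""
    e1, e2 = np.deg2rad(ecc1), np.deg2rad(ecc2)
    dm = np.deg2rad(np.asarray(mer1) - np.asarray(mer2))
    c = np.cos(e1) * np.cos(e2) + np.sin(e1) * np.sin(e2) * np.cos(dm)
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


@dataclass
class RetinalSampleGrid:
    """Regular (eccentricity x meridian) grid on the retinal mid-surface."""

    ecc: np.ndarray                  # (Ne,) deg, starting at 0
    meridian: np.ndarray             # (Nm,) deg in [0, 360)
    radius: float                    # mid-surface radius, mm
    extent: float                    # max eccentricity, deg
    nerve_center: Tuple[float, float] = (22.5, 0.0)   # (ecc, meridian) deg
    nerve_radius: float = 9.1                          # angular radius, deg

    @classmethod
    def build(cls, params: EyeModelParams, ecc_step: float = 1.0,
              meridian_step: float = 2.0, extent: float = 80.0
              ) -> "RetinalSampleGrid":
        ecc = np.arange(0.0, extent + 0.5 * ecc_step, ecc_step)
        mer = np.arange(0.0, 360.0, meridian_step)
        return cls(ecc=ecc, meridian=mer, radius=params.retina_mid_radius,
                   extent=extent,
                   nerve_center=(params.nerve_tilt, 0.0),
                   nerve_radius=params.nerve_disc_angular_radius)

    def points(self) -> np.ndarray:
        """(Ne*Nm, 3) sample points, ecc-major ordering."""
        E, M = np.meshgrid(self.ecc, self.meridian, indexing="ij")
        return retinal_point(E.ravel(), M.ravel(), self.radius)

    def shape(self) -> Tuple[int, int]:
        return (len(self.ecc), len(self.meridian))

    def nerve_mask(self) -> np.ndarray:
        """Boolean (Ne, Nm) mask of the optic-nerve cross-section."""
        E, M = np.meshgrid(self.ecc, self.meridian, indexing="ij")
        d = angular_distance(E, M, self.nerve_center[0], self.nerve_center[1])
        return d <= self.nerve_radius


@dataclass
class ProfileCurve:
    """1-D MMEA profile along a great-circle arc through the retinal center."""

    direction: str
    abscissa: np.ndarray            # signed eccentricity, deg, increasing
    values: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.abscissa) <= 0):
            raise ValueError("profile abscissa must be strictly increasing")


@dataclass
class Width:
    """Full width of a profile at a fraction of its peak."""

    width: float
    left_censored: bool = False
    right_censored: bool = False

    @property
    def censored(self) -> bool:
        return self.left_censored or self.right_censored

    def __float__(self) -> float:
        return self.width


@dataclass
class FocalityStats:
    """Focality metrics of one MMEA map / profile set."""

    fwhm: Dict[str, Width] = field(default_factory=dict)
    width80: Dict[str, Width] = field(default_factory=dict)
    # chord of the map's 80% iso-intensity region along each profile line
    # (None-valued directions are simply absent from the dict)
    chord80: Dict[str, Width] = field(default_factory=dict)
    central_peak_value: Dict[str, float] = field(default_factory=dict)
    central_peak_offset: Dict[str, float] = field(default_factory=dict)
    contour_closed: bool = True
    nerve_overlap: str = "none"        # none | partial | full


def profile_points(direction: str, radius: float, extent: float = 80.0,
                   step: float = 0.25
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """(abscissa deg, (N, 3) points) along a signed profile direction."""
    if direction not in PROFILE_MERIDIANS:
        raise ValueError(f"unknown profile direction {direction!r}")
    m_pos = PROFILE_MERIDIANS[direction]
    t = np.arange(-extent, extent + 0.5 * step, step)
    mer = np.where(t >= 0, m_pos, (m_pos + 180.0) % 360.0)
    pts = retinal_point(np.abs(t), mer, radius)
    return t, pts


def extract_profile(grid: RetinalSampleGrid, values: np.ndarray,
                    direction: str, step: Optional[float] = None
                    ) -> ProfileCurve:
    """Profile along a great-circle arc, interpolated from the grid.

    ``values`` is (Ne, Nm).  The profile passes through the posterior pole
    in the plane of the stated direction.
    """
    if direction not in PROFILE_MERIDIANS:
        raise ValueError(f"unknown profile direction {direction!r}")
    values = np.asarray(values, dtype=float).reshape(grid.shape())
    step = step or float(grid.ecc[1] - grid.ecc[0])
    m_pos = PROFILE_MERIDIANS[direction]
    t = np.arange(-grid.extent, grid.extent + 0.5 * step, step)
    mer = np.where(t >= 0, m_pos, (m_pos + 180.0) % 360.0)
    out = _bilinear(grid, values, np.abs(t), mer)
    return ProfileCurve(direction=direction, abscissa=t, values=out)


def _bilinear(grid: RetinalSampleGrid, values: np.ndarray,
              ecc, mer) -> np.ndarray:
    ecc = np.asarray(ecc, dtype=float)
    mer = np.asarray(mer, dtype=float) % 360.0
    de = grid.ecc[1] - grid.ecc[0]
    dm = grid.meridian[1] - grid.meridian[0]
    fi = np.clip(ecc / de, 0, len(grid.ecc) - 1 - 1e-9)
    fj = (mer / dm) % len(grid.meridian)
    i0 = fi.astype(int)
    j0 = fj.astype(int)
    wi = fi - i0
    wj = fj - j0
    i1 = np.minimum(i0 + 1, len(grid.ecc) - 1)
    j1 = (j0 + 1) % len(grid.meridian)
    return ((1 - wi) * (1 - wj) * values[i0, j0]
            + wi * (1 - wj) * values[i1, j0]
            + (1 - wi) * wj * values[i0, j1]
            + wi * wj * values[i1, j1])


def central_peak(curve: ProfileCurve) -> Tuple[float, float, bool]:
    """(peak value, signed offset deg, tie flag) of the global maximum.

    Equal maxima are resolved toward the abscissa closest to zero.
    """
    v = np.asarray(curve.values, dtype=float)
    if np.ptp(v) <= 1e-15 * max(1.0, abs(float(v.max()))):
        raise ValueError("constant profile has no defined peak")
    peak = v.max()
    cand = np.nonzero(v >= peak * (1.0 - 1e-12))[0]
    tie = len(cand) > 1
    best = cand[np.argmin(np.abs(curve.abscissa[cand]))]
    return float(peak), float(curve.abscissa[best]), tie


def width_at_fraction(curve: ProfileCurve, fraction: float) -> Width:
    """Width of the contiguous super-level interval around the global peak.

    The interval endpoints are located by linear interpolation between
    samples.  If the profile never drops below ``fraction * peak`` before
    the domain boundary on one side, that side is censored at the boundary.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    peak, _off, _tie = central_peak(curve)      # raises on constant curve
    v = np.asarray(curve.values, dtype=float)
    t = curve.abscissa
    # threshold between the curve's own floor and peak, so widths are
    # invariant to the affine constants of min-max normalization
    thr = float(v.min()) + fraction * (peak - float(v.min()))
    ip = int(np.argmax(v))
    # walk left
    left, left_cens = t[0], True
    for i in range(ip, 0, -1):
        if v[i - 1] < thr:
            f = (v[i] - thr) / (v[i] - v[i - 1])
            left, left_cens = t[i] - f * (t[i] - t[i - 1]), False
            break
    # walk right
    right, right_cens = t[-1], True
    for i in range(ip, len(v) - 1):
        if v[i + 1] < thr:
            f = (v[i] - thr) / (v[i] - v[i + 1])
            right, right_cens = t[i] + f * (t[i + 1] - t[i]), False
            break
    return Width(width=float(right - left), left_censored=left_cens,
                 right_censored=right_cens)


#: en-face unit axes per profile direction (temporal-positive a,
#: superior-positive b)
DIRECTION_AXES = {
    "horizontal": (1.0, 0.0),
    "vertical": (0.0, 1.0),
    "diagonal": (np.sqrt(0.5), np.sqrt(0.5)),
}


def enface_coords(ecc, meridian):
    """Azimuthal-equidistant chart of the retina: a positive toward
    temporal, b positive toward superior (both in deg of eccentricity)."""
    m = np.deg2rad(np.asarray(meridian, dtype=float))
    e = np.asarray(ecc, dtype=float)
    return -e * np.cos(m), e * np.sin(m)


def polar_coords(a, b):
    """Inverse of :func:`enface_coords`: (eccentricity, meridian) deg."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ecc = np.hypot(a, b)
    meridian = np.degrees(np.arctan2(b, -a)) % 360.0
    return ecc, meridian


def profile_through_point(grid: RetinalSampleGrid, values: np.ndarray,
                          direction: str,
                          point_ab: Tuple[float, float] = (0.0, 0.0),
                          step: float = 0.25) -> ProfileCurve:
    """Profile along the stated direction through an arbitrary retinal
    point (en-face chart), interpolated from the grid.

    With ``point_ab`` at the map's global peak this yields the curves whose
    widths characterize the convergent area and whose peak position is the
    central-peak offset relative to the retinal center.
    """
    if direction not in DIRECTION_AXES:
        raise ValueError(f"unknown profile direction {direction!r}")
    values = np.asarray(values, dtype=float).reshape(grid.shape())
    ax = np.array(DIRECTION_AXES[direction])
    p = np.asarray(point_ab, dtype=float)
    foot = p - (p @ ax) * ax            # perpendicular offset of the line
    t = np.arange(-grid.extent, grid.extent + 0.5 * step, step)
    pts = foot[None, :] + t[:, None] * ax[None, :]
    inside = np.hypot(pts[:, 0], pts[:, 1]) <= grid.extent
    t = t[inside]
    ecc, mer = polar_coords(pts[inside, 0], pts[inside, 1])
    vals = _bilinear(grid, values, ecc, mer)
    return ProfileCurve(direction=direction, abscissa=t, values=vals)


def peak_enface(grid: RetinalSampleGrid, values: np.ndarray
                ) -> Tuple[float, float]:
    """En-face coordinates (a, b) of the map's global maximum."""
    values = np.asarray(values, dtype=float).reshape(grid.shape())
    i, j = np.unravel_index(int(np.argmax(values)), values.shape)
    a, b = enface_coords(grid.ecc[i], grid.meridian[j])
    return float(a), float(b)


def chord_width(curve: ProfileCurve, level: float = 0.8) -> Optional[Width]:
    """Chord of the iso-intensity super-level region along the profile.

    ``curve.values`` must be normalized over the full retinal map, so
    ``level`` is an absolute intensity (0.8 = the 80% iso-intensity level of
    the map).  Returns the contiguous interval around the curve's global
    maximum where values >= level, or None when the profile never reaches
    the level (the iso-intensity region does not intersect this line).
    """
    v = np.asarray(curve.values, dtype=float)
    t = curve.abscissa
    ip = int(np.argmax(v))
    if v[ip] < level:
        return None
    left, left_cens = t[0], True
    for i in range(ip, 0, -1):
        if v[i - 1] < level:
            f = (v[i] - level) / (v[i] - v[i - 1])
            left, left_cens = t[i] - f * (t[i] - t[i - 1]), False
            break
    right, right_cens = t[-1], True
    for i in range(ip, len(v) - 1):
        if v[i + 1] < level:
            f = (v[i] - level) / (v[i] - v[i + 1])
            right, right_cens = t[i] + f * (t[i + 1] - t[i]), False
            break
    return Width(width=float(right - left), left_censored=left_cens,
                 right_censored=right_cens)


def contour_80(grid: RetinalSampleGrid, values: np.ndarray,
               level: float = 0.8
               ) -> Tuple[bool, str, np.ndarray]:
    """Classify the iso-level super-level region around the global peak.

    ``values`` (Ne, Nm) are min-max normalized over the grid.  Returns
    (contour_closed, nerve_overlap, peak component mask).  The region is
    "closed" iff its connected component (meridian-periodic) does not touch
    the eccentricity extent boundary; nerve overlap is none/partial/full by
    pixel intersection with the optic-nerve cross-section disc
    (full = the disc is entirely inside the region).
    """
    values = np.asarray(values, dtype=float).reshape(grid.shape())
    vmax = values.max()
    if level >= vmax + 1e-12 and vmax < level:
        return True, "none", np.zeros(grid.shape(), dtype=bool)
    mask = values >= level
    lab, n = ndimage.label(mask)
    # merge components across the periodic meridian seam
    for i in range(lab.shape[0]):
        a, b = lab[i, 0], lab[i, -1]
        if a > 0 and b > 0 and a != b:
            lab[lab == b] = a
    peak_idx = np.unravel_index(np.argmax(values), values.shape)
    comp = lab == lab[peak_idx]
    closed = not bool(comp[-1, :].any())
    disc = grid.nerve_mask()
    inter = comp & disc
    if not inter.any():
        overlap = "none"
    elif np.array_equal(inter, disc):
        overlap = "full"
    else:
        overlap = "partial"
    return closed, overlap, comp


def classify_region(ecc: float, meridian: float,
                    radii: Optional[Dict[str, float]] = None,
                    nerve_center: Tuple[float, float] = (22.5, 0.0),
                    nerve_radius: float = 9.1) -> str:
    """Macular annulus / nerve-disc classification of a retinal point."""
    radii = radii or DEFAULT_REGION_RADII
    if angular_distance(ecc, meridian, *nerve_center) <= nerve_radius:
        return "nerve_disc"
    if ecc <= radii["fovea"]:
        return "fovea"
    if ecc <= radii["parafovea"]:
        return "parafovea"
    if ecc <= radii["perifovea"]:
        return "perifovea"
    return "peripheral"


def sample_retina(mesh, lead, currents: Dict[int, float], montage_kind: str,
                  ecc_step: float = 1.0, meridian_step: float = 2.0,
                  extent: float = 80.0):
    """MMEA on a regular retinal grid for given channel currents.

    Convenience wrapper used by the experiment drivers; returns
    (RetinalSampleGrid, EnvelopeField with (Ne, Nm)-shaped values).
    """
    from .envelope import envelope_field
    from .fem import FieldSampler, superpose

    grid = RetinalSampleGrid.build(mesh.params, ecc_step, meridian_step,
                                   extent)
    pts = grid.points()
    sampler = FieldSampler(mesh)
    scaled = superpose(lead, currents)
    fields = {ch: sampler.sample(E, pts) for ch, E in scaled.items()}
    env = envelope_field(fields, montage_kind, points=pts)
    return grid, env
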
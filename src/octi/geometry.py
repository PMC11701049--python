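"""Parametric eye + orbit + optic-nerve volume-conductor geometry and meshing.

Coordinate convention
---------------------
Origin at the eye center O.  +z points posterior along the central (optical)
axis, so the anterior corneal pole sits at z = -R and the posterior retinal
pole at z = +R.  +x points nasal, +y superior.  Electrode polar angles theta
are measured from the *anterior* pole, so theta -> 180 deg moves an electrode
toward the retinal center.

The mesh is a graded rectilinear grid (fine near the posterior pole where the
retinal metrics live, geometrically coarsened elsewhere) whose boxes are split
into six tetrahedra sharing the main diagonal (Kuhn subdivision, conforming by
construction).  Every tetrahedron is labeled by classifying its centroid
against the analytic tissue geometry, so the mesh build is fully deterministic.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

# ---------------------------------------------------------------------------
# Tissue vocabulary
# ---------------------------------------------------------------------------

TISSUES: Tuple[str, ...] = (
    "cornea",
    "atria",
    "lens",
    "vitreous",
    "retina",
    "choroid",
    "sclera",
    "muscle",
    "fat",
    "optic_nerve",
    "csf",
    "sheath",
)

LABEL_OF: Dict[str, int] = {name: i for i, name in enumerate(TISSUES)}
NAME_OF: Dict[int, str] = {i: name for i, name in enumerate(TISSUES)}
OUTSIDE = -1


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EyeModelParams:
    """Geometric parameters of the eye model (all lengths in mm, angles deg).

    Shell thicknesses follow the printed tissue table: the vitreous chamber
    diameter (22 mm) plus retina/choroid/sclera shells fixes the outer scleral
    radius at 12.41 mm, giving a ~24.8 mm axial globe and a retinal
    mid-surface radius of ~11.17 mm (2.6 deg of eccentricity ~ 0.51 mm of
    retinal arc).
    """

    vitreous_diameter: float = 22.0
    retina_thickness: float = 0.33
    choroid_thickness: float = 0.45
    sclera_thickness: float = 0.63
    cornea_thickness: float = 0.5
    cornea_cap_angle: float = 27.0      # half-angle of the corneal cap, deg
    atria_depth: float = 2.8            # axial depth cornea -> lens front
    lens_axial_thickness: float = 4.0
    lens_equatorial_radius: float = 4.5
    shell_extent: float = 95.0          # retina/choroid extent, deg eccentricity

    nerve_tilt: float = 22.5            # deg from central axis, toward nasal
    nerve_diameter: float = 3.55        # retrobulbar cylinder diameter
    nerve_head_diameter: float = 1.8    # optic-disc diameter at the retina
    csf_annulus: float = 0.58
    sheath_annulus: float = 0.73
    nerve_length: float = 14.0          # cylinder length beyond the globe

    muscle_thickness: float = 1.42      # posterior shell over the globe
    fat_extent: float = 14.5            # radial extent of orbital fat region

    # -- derived radii ------------------------------------------------------
    @property
    def vitreous_radius(self) -> float:
        return self.vitreous_diameter / 2.0

    @property
    def retina_outer_radius(self) -> float:
        return self.vitreous_radius + self.retina_thickness

    @property
    def choroid_outer_radius(self) -> float:
        return self.retina_outer_radius + self.choroid_thickness

    @property
    def globe_outer_radius(self) -> float:
        return self.choroid_outer_radius + self.sclera_thickness

    @property
    def retina_mid_radius(self) -> float:
        return self.vitreous_radius + self.retina_thickness / 2.0

    @property
    def domain_radius(self) -> float:
        return self.globe_outer_radius + self.fat_extent

    @property
    def lens_front_z(self) -> float:
        return -self.globe_outer_radius + self.cornea_thickness + self.atria_depth

    @property
    def nerve_axis(self) -> np.ndarray:
        t = np.deg2rad(self.nerve_tilt)
        return np.array([np.sin(t), 0.0, np.cos(t)])

    @property
    def nerve_disc_angular_radius(self) -> float:
        """Angular radius (deg) of the nerve cross-section on the retina."""
        return float(np.rad2deg(np.arcsin(
            min(1.0, (self.nerve_diameter / 2.0) / self.retina_mid_radius))))

    def validate(self) -> None:
        lengths = [
            self.vitreous_diameter, self.retina_thickness,
            self.choroid_thickness, self.sclera_thickness,
            self.cornea_thickness, self.atria_depth,
            self.lens_axial_thickness, self.nerve_diameter,
            self.csf_annulus, self.sheath_annulus, self.nerve_length,
            self.muscle_thickness, self.fat_extent,
        ]
        if any(x <= 0 for x in lengths):
            raise ValueError("all lengths must be positive")
        if not (0.0 <= self.nerve_tilt <= 45.0):
            raise ValueError("nerve_tilt must lie in [0, 45] degrees")
        shells = (self.retina_thickness + self.choroid_thickness
                  + self.sclera_thickness)
        if shells >= self.globe_outer_radius:
            raise ValueError("posterior shell stack exceeds the globe radius")
        # nested shells keep positive clearance at the poles by construction
        if self.vitreous_radius <= self.lens_axial_thickness:
            raise ValueError("lens does not fit inside the vitreous chamber")


@dataclass(frozen=True)
class ElectrodeSpec:
    """A disc electrode on the outer scleral/corneal surface."""

    theta: float                 # deg from anterior pole
    plane: str                   # "horizontal" | "vertical"
    side: str                    # "nasal" | "temporal" | "superior" | "inferior"
    role: str                    # "stimulating" | "return"
    channel_id: int
    diameter_um: float = 500.0
    thickness_um: float = 50.0

    def validate(self) -> None:
        if not (0.0 <= self.theta < 180.0):
            raise ValueError("theta must lie in [0, 180) degrees")
        if self.plane not in ("horizontal", "vertical"):
            raise ValueError(f"unknown plane {self.plane!r}")
        if self.side not in ("nasal", "temporal", "superior", "inferior"):
            raise ValueError(f"unknown side {self.side!r}")
        if self.role not in ("stimulating", "return"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.diameter_um <= 0 or self.thickness_um <= 0:
            raise ValueError("electrode dimensions must be positive")


def electrode_center(theta: float, plane: str, side: str,
                     surface_radius: float) -> np.ndarray:
    """Center of an electrode on the sphere of ``surface_radius``.

    theta is measured from the anterior pole (0, 0, -R) toward the stated
    side in the stated plane.
    """
    if not (0.0 <= theta < 180.0):
        raise ValueError("theta must lie in [0, 180) degrees")
    t = np.deg2rad(theta)
    s, c = np.sin(t), np.cos(t)
    R = surface_radius
    if plane == "horizontal":
        sign = {"nasal": 1.0, "temporal": -1.0}[side]
        return np.array([sign * R * s, 0.0, -R * c])
    if plane == "vertical":
        sign = {"superior": 1.0, "inferior": -1.0}[side]
        return np.array([0.0, sign * R * s, -R * c])
    raise ValueError(f"unknown plane {plane!r}")


def montage_2d(theta1: float, theta2: float, **kw) -> List[ElectrodeSpec]:
    """Two horizontal channels: nasal (1) and temporal (2) stim/return pairs."""
    return [
        ElectrodeSpec(theta1, "horizontal", "nasal", "stimulating", 1, **kw),
        ElectrodeSpec(theta2, "horizontal", "nasal", "return", 1, **kw),
        ElectrodeSpec(theta1, "horizontal", "temporal", "stimulating", 2, **kw),
        ElectrodeSpec(theta2, "horizontal", "temporal", "return", 2, **kw),
    ]


def montage_3d(theta1H: float, theta2H: float,
               theta1V: Optional[float] = None,
               theta2V: Optional[float] = None, **kw) -> List[ElectrodeSpec]:
    """Four channels: nasal (1), temporal (2), superior (3), inferior (4)."""
    theta1V = theta1H if theta1V is None else theta1V
    theta2V = theta2H if theta2V is None else theta2V
    out = montage_2d(theta1H, theta2H, **kw)
    out += [
        ElectrodeSpec(theta1V, "vertical", "superior", "stimulating", 3, **kw),
        ElectrodeSpec(theta2V, "vertical", "superior", "return", 3, **kw),
        ElectrodeSpec(theta1V, "vertical", "inferior", "stimulating", 4, **kw),
        ElectrodeSpec(theta2V, "vertical", "inferior", "return", 4, **kw),
    ]
    return out


# ---------------------------------------------------------------------------
# Tissue classifier
# ---------------------------------------------------------------------------

def classify_points(pts: np.ndarray, params: EyeModelParams,
                    include_nerve: bool = True) -> np.ndarray:
    """Label points (N, 3) with tissue codes; OUTSIDE beyond the domain.

    The classifier is the analytic ground truth for the geometry: meshes are
    labeled by evaluating it at element centroids, and tests probe it
    directly.
    """
    p = params
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    r = np.sqrt(x * x + y * y + z * z)

    R_out = p.globe_outer_radius
    R_dom = p.domain_radius

    labels = np.full(len(pts), OUTSIDE, dtype=np.int32)
    inside_dom = r <= R_dom
    labels[inside_dom] = LABEL_OF["fat"]

    # posterior extra-ocular muscle shell
    musc = inside_dom & (r > R_out) & (r <= R_out + p.muscle_thickness) & (z >= 0)
    labels[musc] = LABEL_OF["muscle"]

    globe = r <= R_out
    if np.any(globe):
        rg = r[globe]
        zg = z[globe]
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_ecc = np.where(rg > 0, zg / np.maximum(rg, 1e-300), 1.0)
        ecc = np.degrees(np.arccos(np.clip(cos_ecc, -1.0, 1.0)))
        theta_ant = 180.0 - ecc

        sub = np.empty(globe.sum(), dtype=np.int32)
        sub[:] = LABEL_OF["vitreous"]

        interior = rg <= R_out - p.sclera_thickness
        # anterior chamber: everything anterior to the lens front plane
        sub[interior & (zg <= p.lens_front_z)] = LABEL_OF["atria"]
        # lens ellipsoid on the central axis
        zc = p.lens_front_z + p.lens_axial_thickness / 2.0
        a, b = p.lens_equatorial_radius, p.lens_axial_thickness / 2.0
        in_lens = ((x[globe] ** 2 + y[globe] ** 2) / a ** 2
                   + (zg - zc) ** 2 / b ** 2) <= 1.0
        sub[interior & in_lens] = LABEL_OF["lens"]
        # posterior shells (retina/choroid) within shell_extent
        shells = ecc <= p.shell_extent
        in_ret = (rg > p.vitreous_radius) & (rg <= p.retina_outer_radius)
        in_cho = (rg > p.retina_outer_radius) & (rg <= p.choroid_outer_radius)
        sub[shells & in_ret & interior] = LABEL_OF["retina"]
        sub[shells & in_cho & interior] = LABEL_OF["choroid"]
        # outermost shell: sclera everywhere except the corneal cap
        outer = rg > R_out - p.sclera_thickness
        sub[outer] = LABEL_OF["sclera"]
        cap = (theta_ant <= p.cornea_cap_angle) & (rg > R_out - p.cornea_thickness)
        sub[cap] = LABEL_OF["cornea"]
        sub[(theta_ant <= p.cornea_cap_angle) & (rg <= R_out - p.cornea_thickness)
            & outer] = LABEL_OF["atria"]
        labels[globe] = sub

    if include_nerve:
        d = p.nerve_axis
        s = pts @ d
        rho = np.sqrt(np.maximum(np.sum(pts * pts, axis=1) - s * s, 0.0))
        r_cyl = p.nerve_diameter / 2.0
        s_j = R_out                       # scleral junction along the axis
        s_end = s_j + p.nerve_length

        post = inside_dom & (s > s_j) & (s <= s_end)
        labels[post & (rho <= r_cyl + p.csf_annulus + p.sheath_annulus)] = \
            LABEL_OF["sheath"]
        labels[post & (rho <= r_cyl + p.csf_annulus)] = LABEL_OF["csf"]
        labels[post & (rho <= r_cyl)] = LABEL_OF["optic_nerve"]

        # intraocular truncated cone: optic-disc radius at the inner retinal
        # surface widening to the cylinder radius at the scleral junction
        s_disc = p.vitreous_radius
        r_head = p.nerve_head_diameter / 2.0
        cone = globe & (s > s_disc) & (s <= s_j)
        frac = np.clip((s - s_disc) / max(s_j - s_disc, 1e-9), 0.0, 1.0)
        r_cone = r_head + (r_cyl - r_head) * frac
        labels[cone & (rho <= r_cone)] = LABEL_OF["optic_nerve"]

    return labels


# ---------------------------------------------------------------------------
# Mesh
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeshSpec:
    """Graded rectilinear mesh specification (all lengths mm).

    A fine box around the posterior pole (where retinal metrics and the
    posterior return electrodes live) at ``h_fine``; geometric coarsening by
    ``ratio`` up to ``h_coarse`` elsewhere.
    """

    h_fine: float = 0.45
    h_coarse: float = 3.0
    ratio: float = 1.45
    fine_xy: float = 6.0            # fine half-extent in x and y
    fine_z: Tuple[float, float] = (9.4, 12.9)

    @classmethod
    def preset(cls, name: str) -> "MeshSpec":
        presets = {
            "test": cls(h_fine=0.6, h_coarse=3.2, ratio=1.5, fine_xy=6.0,
                        fine_z=(9.4, 12.9)),
            "coarse": cls(),
            # sub-0.2 mm elements around the posterior pole: required to
            # resolve macular envelope peaks a few tenths of a mm wide
            "macular": cls(h_fine=0.18, h_coarse=3.0, ratio=1.45,
                           fine_xy=2.5, fine_z=(10.9, 12.9)),
            # posterior cap out to ~25 deg eccentricity at 0.3 mm: resolves
            # convergent areas steered across the central retina
            "posterior": cls(h_fine=0.3, h_coarse=3.0, ratio=1.45,
                             fine_xy=5.0, fine_z=(10.0, 12.9)),
            # uniform resolution over the whole globe: unbiased comparisons
            # between central and peripheral retinal samples
            "globe": cls(h_fine=1.0, h_coarse=2.8, ratio=1.5,
                         fine_xy=13.5, fine_z=(-13.5, 13.5)),
            "reference": cls(h_fine=0.25, h_coarse=2.0, ratio=1.3,
                             fine_xy=7.5, fine_z=(9.0, 13.0)),
        }
        try:
            return presets[name]
        except KeyError:
            raise ValueError(
                f"unknown mesh preset {name!r}; choose from {sorted(presets)}")


def _graded_axis(lo: float, hi: float, fine_lo: float, fine_hi: float,
                 h_fine: float, h_coarse: float, ratio: float) -> np.ndarray:
    """Strictly increasing coordinates over [lo, hi], fine in [fine_lo, fine_hi]."""
    fine_lo = max(fine_lo, lo)
    fine_hi = min(fine_hi, hi)
    n_fine = max(1, int(round((fine_hi - fine_lo) / h_fine)))
    core = np.linspace(fine_lo, fine_hi, n_fine + 1)

    def grow(start: float, stop: float, direction: float) -> List[float]:
        out: List[float] = []
        h = h_fine
        pos = start
        while (stop - pos) * direction > 1e-9:
            h = min(h * ratio, h_coarse)
            remaining = (stop - pos) * direction
            if remaining <= h * 1.5:
                out.append(stop)
                break
            pos = pos + direction * h
            out.append(pos)
        return out

    left = grow(fine_lo, lo, -1.0)[::-1]
    right = grow(fine_hi, hi, +1.0)
    return np.array(left + list(core) + right)


_KUHN = np.array([
    [0, 1, 3, 7], [0, 1, 5, 7], [0, 2, 3, 7],
    [0, 2, 6, 7], [0, 4, 5, 7], [0, 4, 6, 7],
])
# vertex k of a box has offsets (k&1, (k>>1)&1, (k>>2)&1); every tet shares
# the main diagonal 0-7, so faces of neighboring boxes triangulate identically


@dataclass
class LabeledMesh:
    """Tetrahedral mesh with per-cell tissue labels and electrode patches."""

    nodes: np.ndarray                       # (N, 3) mm
    tets: np.ndarray                        # (M, 4) int
    labels: np.ndarray                      # (M,) int tissue codes
    params: EyeModelParams
    electrodes: List[ElectrodeSpec] = field(default_factory=list)
    # per electrode: (node indices, weights summing to 1)
    patches: Dict[Tuple[int, str], Tuple[np.ndarray, np.ndarray]] = \
        field(default_factory=dict)
    axes: Optional[Tuple[np.ndarray, np.ndarray, np.ndarray]] = None
    _volumes: Optional[np.ndarray] = None

    # -- basic derived quantities ------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_cells(self) -> int:
        return len(self.tets)

    def cell_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def cell_volumes(self) -> np.ndarray:
        if self._volumes is None:
            p = self.nodes[self.tets]
            a = p[:, 1] - p[:, 0]
            b = p[:, 2] - p[:, 0]
            c = p[:, 3] - p[:, 0]
            self._volumes = np.abs(np.einsum("ij,ij->i", a, np.cross(b, c))) / 6.0
        return self._volumes

    def tissue_volume(self, tissue: str) -> float:
        return float(self.cell_volumes()[self.labels == LABEL_OF[tissue]].sum())

    def present_tissues(self) -> List[str]:
        return [NAME_OF[i] for i in sorted(set(self.labels.tolist()))]

    def node_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.nodes).tobytes())
        h.update(np.ascontiguousarray(self.tets).tobytes())
        h.update(np.ascontiguousarray(self.labels).tobytes())
        return h.hexdigest()

    # -- point location -----------------------------------------------------
    def locate(self, points: np.ndarray) -> np.ndarray:
        """Containing-cell index for each point (-1 if outside the mesh).

        Uses the rectilinear box structure: searchsorted per axis, then a
        barycentric test over the six candidate tets of the box.
        """
        if self.axes is None:
            raise RuntimeError("mesh has no rectilinear axis metadata")
        xs, ys, zs = self.axes
        points = np.atleast_2d(points)
        ix = np.clip(np.searchsorted(xs, points[:, 0]) - 1, 0, len(xs) - 2)
        iy = np.clip(np.searchsorted(ys, points[:, 1]) - 1, 0, len(ys) - 2)
        iz = np.clip(np.searchsorted(zs, points[:, 2]) - 1, 0, len(zs) - 2)
        box_key = (ix * (len(ys) - 1) + iy) * (len(zs) - 1) + iz
        out = np.full(len(points), -1, dtype=np.int64)
        order = np.argsort(box_key, kind="stable")
        keys = box_key[order]
        starts = np.searchsorted(self._box_keys, keys)
        for rank, (pi, st) in enumerate(zip(order, starts)):
            if st >= len(self._box_keys) or self._box_keys[st] != keys[rank]:
                continue
            pt = points[pi]
            for ci in range(st, min(st + 6, len(self._box_keys))):
                if self._box_keys[ci] != keys[rank]:
                    break
                t = self._box_tets[ci]
                if self._point_in_tet(pt, t):
                    out[pi] = t
                    break
        return out

    def interpolate(self, node_values: np.ndarray, points: np.ndarray
                    ) -> np.ndarray:
        """P1 (barycentric) interpolation of a nodal field at points.

        Exact for finite-element solutions; points outside the mesh get NaN.
        """
        points = np.atleast_2d(points)
        cells = self.locate(points)
        out = np.full(len(points), np.nan)
        for i, (p, c) in enumerate(zip(points, cells)):
            if c < 0:
                continue
            v = self.nodes[self.tets[c]]
            T = (v[1:] - v[0]).T
            lam123 = np.linalg.solve(T, p - v[0])
            lam = np.concatenate([[1.0 - lam123.sum()], lam123])
            out[i] = lam @ node_values[self.tets[c]]
        return out

    def _point_in_tet(self, pt: np.ndarray, t: int, tol: float = 1e-9) -> bool:
        v = self.nodes[self.tets[t]]
        T = (v[1:] - v[0]).T
        try:
            lam = np.linalg.solve(T, pt - v[0])
        except np.linalg.LinAlgError:
            return False
        return bool(lam.min() >= -tol and lam.sum() <= 1.0 + tol)

    def finalize_locator(self, box_keys: np.ndarray) -> None:
        order = np.argsort(box_keys, kind="stable")
        self._box_keys = box_keys[order]
        self._box_tets = order


def _build_mesh(params: EyeModelParams, spec: MeshSpec,
                classify) -> LabeledMesh:
    R = params.domain_radius
    xs = _graded_axis(-R, R, -spec.fine_xy, spec.fine_xy,
                      spec.h_fine, spec.h_coarse, spec.ratio)
    ys = _graded_axis(-R, R, -spec.fine_xy, spec.fine_xy,
                      spec.h_fine, spec.h_coarse, spec.ratio)
    zs = _graded_axis(-R, R, spec.fine_z[0], spec.fine_z[1],
                      spec.h_fine, spec.h_coarse, spec.ratio)

    nx, ny, nz = len(xs) - 1, len(ys) - 1, len(zs) - 1
    # box centroids -> quick domain trim before splitting into tets
    cx = 0.5 * (xs[:-1] + xs[1:])
    cy = 0.5 * (ys[:-1] + ys[1:])
    cz = 0.5 * (zs[:-1] + zs[1:])
    CX, CY, CZ = np.meshgrid(cx, cy, cz, indexing="ij")
    centers = np.column_stack([CX.ravel(), CY.ravel(), CZ.ravel()])
    # keep a box if its centroid is within the domain plus one diagonal
    pad = np.sqrt(3) * spec.h_coarse
    keep_box = np.linalg.norm(centers, axis=1) <= R + pad
    box_ids = np.nonzero(keep_box)[0]

    bi = box_ids // (ny * nz)
    bj = (box_ids // nz) % ny
    bk = box_ids % nz

    # global node ids on the (nx+1, ny+1, nz+1) lattice
    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    corner = np.empty((len(box_ids), 8), dtype=np.int64)
    for v in range(8):
        di, dj, dk = v & 1, (v >> 1) & 1, (v >> 2) & 1
        corner[:, v] = nid(bi + di, bj + dj, bk + dk)

    tets_global = corner[:, _KUHN].reshape(-1, 4)          # (nbox*6, 4)
    tet_box = np.repeat(box_ids, 6)

    # label tets at centroids
    lat_x = np.concatenate([xs])
    lat_y = np.concatenate([ys])
    lat_z = np.concatenate([zs])

    def node_xyz(gids):
        k = gids % (nz + 1)
        j = (gids // (nz + 1)) % (ny + 1)
        i = gids // ((ny + 1) * (nz + 1))
        return np.column_stack([lat_x[i], lat_y[j], lat_z[k]])

    cent = node_xyz(tets_global.ravel()).reshape(-1, 4, 3).mean(axis=1)
    lab = classify(cent)
    keep = lab >= 0
    tets_global = tets_global[keep]
    lab = lab[keep]
    tet_box = tet_box[keep]

    used, inv = np.unique(tets_global.ravel(), return_inverse=True)
    tets = inv.reshape(-1, 4).astype(np.int64)
    nodes = node_xyz(used)

    mesh = LabeledMesh(nodes=nodes, tets=tets, labels=lab.astype(np.int32),
                       params=params, axes=(xs, ys, zs))
    mesh.finalize_locator(tet_box)
    return mesh


def _select_patch(mesh: LabeledMesh, c: np.ndarray, surface_radius: float,
                  disc_radius_mm: float) -> Tuple[np.ndarray, np.ndarray]:
    """Nodal injection patch for a disc electrode centered at ``c``.

    Nodes within ~one local cell of the spherical surface radially and
    within max(disc radius, one local cell) laterally get Gaussian
    (lateral-distance) weights; falls back to the single nearest node.
    """
    h_loc = _local_h(mesh, c)
    r_eff = max(disc_radius_mm, 1.0 * h_loc)
    r_node = np.linalg.norm(mesh.nodes, axis=1)
    radial = np.abs(r_node - surface_radius)
    d = np.linalg.norm(mesh.nodes - c, axis=1)
    lateral = np.sqrt(np.maximum(d * d - (r_node - surface_radius) ** 2, 0.0))
    idx = np.nonzero((radial <= 0.8 * h_loc) & (lateral <= r_eff))[0]
    if len(idx) == 0:
        idx = np.array([int(np.argmin(d))])
    w = np.exp(-(lateral[idx] / max(r_eff, 1e-9)) ** 2)
    w /= w.sum()
    return idx, w


def _attach_electrodes(mesh: LabeledMesh, montage: Sequence[ElectrodeSpec],
                       spec: MeshSpec) -> None:
    """Select compact nodal injection patches for every electrode.

    Electrode footprints must not overlap one another.
    """
    p = mesh.params
    centers = {}
    for el in montage:
        el.validate()
        c = electrode_center(el.theta, el.plane, el.side, p.globe_outer_radius)
        centers[(el.channel_id, el.role)] = (el, c)
    keys = list(centers)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            ei, ci = centers[keys[i]]
            ej, cj = centers[keys[j]]
            min_sep = (ei.diameter_um + ej.diameter_um) / 2000.0
            if np.linalg.norm(ci - cj) < min_sep:
                raise ValueError(
                    f"electrode footprints overlap: channel {ei.channel_id} "
                    f"{ei.role} and channel {ej.channel_id} {ej.role}")

    for key, (el, c) in centers.items():
        mesh.patches[key] = _select_patch(mesh, c, p.globe_outer_radius,
                                          el.diameter_um / 2000.0)
    mesh.electrodes = list(montage)


def build_eye_model(params: Optional[EyeModelParams] = None,
                    montage: Sequence[ElectrodeSpec] = (),
                    mesh: Optional[MeshSpec] = None,
                    include_nerve: bool = True) -> LabeledMesh:
    """Build the labeled eye/orbit/nerve mesh with electrodes attached."""
    params = params or EyeModelParams()
    params.validate()
    spec = mesh or MeshSpec()
    out = _build_mesh(params, spec,
                      lambda pts: classify_points(pts, params, include_nerve))
    if montage:
        _attach_electrodes(out, montage, spec)
    return out


def build_phantom(kind: str,
                  params: Optional[EyeModelParams] = None,
                  montage: Sequence[ElectrodeSpec] = (),
                  mesh: Optional[MeshSpec] = None,
                  radius: float = 12.0) -> LabeledMesh:
    """Simplified phantoms for verification.

    ``homogeneous_sphere``: a single-tissue ball (labeled vitreous) of the
    given radius.  ``nerve_free_eye``: the full eye model with the optic
    nerve assembly removed (those regions classify as orbital fat).
    """
    if kind == "homogeneous_sphere":
        spec = mesh or MeshSpec(h_fine=1.0, h_coarse=1.0, fine_xy=radius,
                                fine_z=(-radius, radius))

        def classify(pts):
            pts = np.atleast_2d(pts)
            lab = np.full(len(pts), OUTSIDE, dtype=np.int32)
            lab[np.linalg.norm(pts, axis=1) <= radius] = LABEL_OF["vitreous"]
            return lab

        params = params or EyeModelParams()
        out = _build_mesh(params, spec, classify)
        if montage:
            # electrode centers on the phantom surface
            _attach_phantom_electrodes(out, montage, radius)
        return out
    if kind == "nerve_free_eye":
        return build_eye_model(params, montage, mesh, include_nerve=False)
    raise ValueError(f"unknown phantom kind {kind!r}")


def _attach_phantom_electrodes(mesh: LabeledMesh,
                               montage: Sequence[ElectrodeSpec],
                               radius: float) -> None:
    for el in montage:
        el.validate()
        c = electrode_center(el.theta, el.plane, el.side, radius)
        mesh.patches[(el.channel_id, el.role)] = _select_patch(
            mesh, c, radius, el.diameter_um / 2000.0)
    mesh.electrodes = list(montage)


def _local_h(mesh: LabeledMesh, c: np.ndarray) -> float:
    xs, ys, zs = mesh.axes
    hx = np.diff(xs)[np.clip(np.searchsorted(xs, c[0]) - 1, 0, len(xs) - 2)]
    hz = np.diff(zs)[np.clip(np.searchsorted(zs, c[2]) - 1, 0, len(zs) - 2)]
    return float(max(hx, hz))
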
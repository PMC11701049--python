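"""Conduction solver verification on phantoms.

The homogeneous-sphere phantom admits an analytic solution: for a point
current source I on the surface of an insulated conducting sphere of radius
a and conductivity sigma, the interior potential is the Legendre series

    phi(r, gamma) = I / (4 pi sigma a) * sum_n (2n+1)/n (r/a)^n P_n(cos gamma)

with gamma the angle from the source axis.  Two electrodes superpose a
source (+I) and sink (-I).  The series is evaluated here independently of
the finite-element machinery and acts as the oracle.
"""

import numpy as np
import pytest
from numpy.polynomial import legendre

from octi.envelope import envelope_field
from octi.fem import (FieldSampler, LeadFieldSolver, plane_flux,
                      superpose)
from octi.geometry import (ElectrodeSpec, MeshSpec, build_phantom,
                           electrode_center, montage_2d)

RADIUS = 10.0
SIGMA = 1.5        # phantom is labeled vitreous


def sphere_point_source_potential(points, src, current, radius, sigma,
                                  n_terms=120):
    """Analytic interior potential of a surface point source, insulated
    sphere; independent Legendre-series oracle."""
    pts = np.atleast_2d(points)
    r = np.linalg.norm(pts, axis=1)
    cosg = (pts @ src) / np.maximum(r * np.linalg.norm(src), 1e-300)
    cosg = np.clip(cosg, -1.0, 1.0)
    a_m = radius * 1e-3
    x = r / radius
    out = np.zeros(len(pts))
    for n in range(1, n_terms):
        cn = np.zeros(n + 1)
        cn[n] = 1.0
        Pn = legendre.legval(cosg, cn)
        out += (2 * n + 1) / n * x ** n * Pn
    return current / (4 * np.pi * sigma * a_m) * out


@pytest.fixture(scope="module")
def antipodal_phantom():
    """Sphere with one channel: contacts at the two poles of the z axis."""
    montage = [
        ElectrodeSpec(170.0, "horizontal", "nasal", "stimulating", 1),
        ElectrodeSpec(10.0, "horizontal", "nasal", "return", 1),
    ]
    mesh = build_phantom(
        "homogeneous_sphere", montage=montage, radius=RADIUS,
        mesh=MeshSpec(h_fine=0.9, h_coarse=0.9, fine_xy=RADIUS,
                      fine_z=(-RADIUS, RADIUS)))
    return mesh


@pytest.fixture(scope="module")
def solved(antipodal_phantom):
    solver = LeadFieldSolver(antipodal_phantom)
    phi, E = solver.solve_channel(1)
    return solver, phi, E


def test_potential_matches_legendre_series(antipodal_phantom, solved):
    """FEM potential within 2% of the analytic two-point-source series at
    probe points away from the contacts."""
    _solver, phi, _E = solved
    mesh = antipodal_phantom
    src = electrode_center(170.0, "horizontal", "nasal", RADIUS)
    snk = electrode_center(10.0, "horizontal", "nasal", RADIUS)
    rng = np.random.default_rng(42)
    pts = rng.normal(size=(300, 3))
    pts = pts / np.linalg.norm(pts, axis=1, keepdims=True) \
        * rng.uniform(0.0, 0.7 * RADIUS, (300, 1))
    # keep probes > 4 mm from both contacts
    ok = (np.linalg.norm(pts - src, axis=1) > 4.0) \
        & (np.linalg.norm(pts - snk, axis=1) > 4.0)
    pts = pts[ok]
    exact = (sphere_point_source_potential(pts, src, 1e-3, RADIUS, SIGMA)
             - sphere_point_source_potential(pts, snk, 1e-3, RADIUS, SIGMA))
    exact -= exact.mean()
    fem = mesh.interpolate(phi, pts)
    assert np.all(np.isfinite(fem))
    fem -= fem.mean()
    scale = np.abs(exact).max()
    assert np.max(np.abs(fem - exact)) / scale < 0.02


def test_current_conservation_through_equator(antipodal_phantom, solved):
    """Net current through the equatorial cutting plane equals the injected
    1 mA within 1%."""
    _solver, _phi, E = solved
    mesh = antipodal_phantom
    J = SIGMA * E                       # A/m^2, homogeneous conductivity
    flux = plane_flux(mesh, J, z0=0.0)
    assert abs(abs(flux) - 1e-3) / 1e-3 < 0.01


def test_reciprocity():
    """Potential difference across pair B from unit current through pair A
    equals that across A from unit current through B, within 1%."""
    montage = montage_2d(40.0, 140.0)      # two separate electrode pairs
    mesh = build_phantom(
        "homogeneous_sphere", montage=montage, radius=RADIUS,
        mesh=MeshSpec(h_fine=0.9, h_coarse=0.9, fine_xy=RADIUS,
                      fine_z=(-RADIUS, RADIUS)))
    solver = LeadFieldSolver(mesh)
    phi1, _ = solver.solve_channel(1)
    phi2, _ = solver.solve_channel(2)
    i1s, w1s = mesh.patches[(1, "stimulating")]
    i1r, w1r = mesh.patches[(1, "return")]
    i2s, w2s = mesh.patches[(2, "stimulating")]
    i2r, w2r = mesh.patches[(2, "return")]
    u_2_from_1 = w2s @ phi1[i2s] - w2r @ phi1[i2r]
    u_1_from_2 = w1s @ phi2[i1s] - w1r @ phi2[i1r]
    assert u_2_from_1 == pytest.approx(u_1_from_2, rel=0.01)


def test_superpose_identity_and_linearity(antipodal_phantom):
    solver = LeadFieldSolver(antipodal_phantom)
    lead = solver.solve_all([1])
    out = superpose(lead, {1: 1.0})
    assert np.array_equal(out[1], lead.cell_E[1])
    doubled = superpose(lead, {1: 2.0})
    assert np.allclose(doubled[1], 2.0 * lead.cell_E[1])
    with pytest.raises(KeyError):
        superpose(lead, {9: 1.0})


def test_solver_determinism(antipodal_phantom):
    s1 = LeadFieldSolver(antipodal_phantom)
    s2 = LeadFieldSolver(antipodal_phantom)
    phi1, _ = s1.solve_channel(1)
    phi2, _ = s2.solve_channel(1)
    assert np.array_equal(phi1, phi2)


def test_mesh_refinement_consistency():
    """Envelope magnitude at fixed probes changes by <5% when the phantom
    edge length is reduced 1.5x (two-channel montage)."""
    montage = montage_2d(30.0, 150.0)
    probes = np.array([[0, 0, 6.0], [2, 0, 5.0], [-2, 1, 5.5],
                       [0, -2, 6.5], [1, 1, 6.0]])
    vals = {}
    for h in (1.35, 0.9):
        mesh = build_phantom(
            "homogeneous_sphere", montage=montage, radius=RADIUS,
            mesh=MeshSpec(h_fine=h, h_coarse=h, fine_xy=RADIUS,
                          fine_z=(-RADIUS, RADIUS)))
        solver = LeadFieldSolver(mesh)
        lead = solver.solve_all()
        sampler = FieldSampler(mesh, "vitreous")
        fields = {ch: sampler.sample(E, probes)
                  for ch, E in superpose(lead, {1: 1.0, 2: 1.0}).items()}
        env = envelope_field(fields, "2D", points=probes)
        vals[h] = env.mmea_raw
    rel = np.abs(vals[0.9] - vals[1.35]) / np.abs(vals[0.9])
    assert rel.max() < 0.05
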
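"""Eye-model geometry: classifier, electrode placement, mesh invariants."""

import numpy as np
import pytest

from octi.geometry import (LABEL_OF, NAME_OF, EyeModelParams, MeshSpec,
                           build_eye_model, build_phantom, classify_points,
                           electrode_center, montage_2d, montage_3d)


@pytest.fixture(scope="module")
def params():
    return EyeModelParams()


@pytest.fixture(scope="module")
def tiny_mesh(params):
    return build_eye_model(params, montage_3d(30, 170),
                           MeshSpec.preset("test"))


class TestElectrodeCenter:
    def test_anterior_pole(self):
        c = electrode_center(0.0, "horizontal", "nasal", 12.0)
        assert np.allclose(c, [0, 0, -12.0])

    def test_30deg_nasal_closed_form(self):
        c = electrode_center(30.0, "horizontal", "nasal", 12.0)
        assert np.allclose(c, [6.0, 0.0, -10.392304845], atol=1e-8)

    def test_quarter_turn_superior(self):
        c = electrode_center(90.0, "vertical", "superior", 12.0)
        assert np.allclose(c, [0.0, 12.0, 0.0])

    def test_theta_domain(self):
        with pytest.raises(ValueError):
            electrode_center(180.0, "horizontal", "nasal", 12.0)


class TestClassifier:
    def test_posterior_shell_thicknesses(self, params):
        """Retina 0.33, choroid 0.45, sclera 0.63 mm along the posterior
        pole normal, resolved by dense radial probing."""
        r = np.linspace(10.8, 12.5, 3500)
        pts = np.column_stack([np.zeros_like(r), np.zeros_like(r), r])
        lab = classify_points(pts, params)
        for tissue, thickness in (("retina", 0.33), ("choroid", 0.45),
                                  ("sclera", 0.63)):
            sel = r[lab == LABEL_OF[tissue]]
            measured = sel.max() - sel.min() + (r[1] - r[0])
            assert measured == pytest.approx(thickness, abs=0.01)

    def test_nerve_axis_angle(self, params):
        """Cells along the nerve axis classify as optic nerve; the axis is
        tilted 22.5 deg from the central axis toward nasal."""
        d = params.nerve_axis
        assert np.degrees(np.arccos(d @ [0, 0, 1])) == pytest.approx(22.5)
        s = np.linspace(13.0, 20.0, 40)
        pts = s[:, None] * d
        lab = classify_points(pts, params)
        assert np.all(lab == LABEL_OF["optic_nerve"])
        # CSF then sheath annuli around the cylinder
        perp = np.array([d[2], 0, -d[0]])
        lab_csf = classify_points(pts + 2.0 * perp, params)
        lab_sheath = classify_points(pts + 2.7 * perp, params)
        assert np.all(lab_csf == LABEL_OF["csf"])
        assert np.all(lab_sheath == LABEL_OF["sheath"])

    def test_nerve_free_classifier_mirror_symmetric(self, params):
        rng = np.random.default_rng(11)
        pts = rng.uniform(-15, 15, size=(4000, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        lab = classify_points(pts, params, include_nerve=False)
        lab_m = classify_points(mirrored, params, include_nerve=False)
        assert np.array_equal(lab, lab_m)


class TestMesh:
    def test_all_tissues_present(self, tiny_mesh):
        assert set(tiny_mesh.present_tissues()) == set(NAME_OF.values())

    def test_vitreous_volume_conservation(self, tiny_mesh, params):
        """Vitreous mesh volume within 5% of the analytic chamber volume
        (sphere minus lens cap and anterior chamber)."""
        analytic = 4.0 / 3.0 * np.pi * params.vitreous_radius ** 3
        assert tiny_mesh.tissue_volume("vitreous") == \
            pytest.approx(analytic, rel=0.05)

    def test_deterministic_hash(self, params, tiny_mesh):
        again = build_eye_model(params, montage_3d(30, 170),
                                MeshSpec.preset("test"))
        assert again.node_hash() == tiny_mesh.node_hash()

    def test_electrode_patches_attached_and_compact(self, tiny_mesh, params):
        """Each contact is a compact node patch near the scleral surface at
        the electrode center, with weights summing to one."""
        assert len(tiny_mesh.patches) == 8
        spec = MeshSpec.preset("test")
        for el in tiny_mesh.electrodes:
            idx, w = tiny_mesh.patches[(el.channel_id, el.role)]
            assert w.sum() == pytest.approx(1.0)
            c = electrode_center(el.theta, el.plane, el.side,
                                 params.globe_outer_radius)
            d = np.linalg.norm(tiny_mesh.nodes[idx] - c, axis=1)
            # patch nodes stay within ~2 local cells of the disc center
            assert d.max() <= 2.0 * spec.h_coarse
            # radially hugging the scleral surface
            rn = np.linalg.norm(tiny_mesh.nodes[idx], axis=1)
            assert np.all(np.abs(rn - params.globe_outer_radius)
                          <= spec.h_coarse)

    def test_overlapping_electrodes_rejected(self, params):
        montage = montage_2d(30, 30.001)
        with pytest.raises(ValueError, match="overlap"):
            build_eye_model(params, montage, MeshSpec.preset("test"))

    def test_locate_finds_containing_cells(self, tiny_mesh):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-8, 8, size=(50, 3))
        cells = tiny_mesh.locate(pts)
        assert np.all(cells >= 0)
        # located cell's vertices surround the point
        for p, c in zip(pts, cells):
            v = tiny_mesh.nodes[tiny_mesh.tets[c]]
            assert np.all(p >= v.min(axis=0) - 1e-9)
            assert np.all(p <= v.max(axis=0) + 1e-9)


class TestPhantoms:
    def test_homogeneous_sphere_single_label(self):
        ph = build_phantom("homogeneous_sphere", radius=10.0,
                           mesh=MeshSpec(h_fine=1.5, h_coarse=1.5,
                                         fine_xy=10, fine_z=(-10, 10)))
        assert ph.present_tissues() == ["vitreous"]

    def test_nerve_free_eye_has_no_nerve_labels(self):
        ph = build_phantom("nerve_free_eye", mesh=MeshSpec.preset("test"))
        present = set(ph.present_tissues())
        assert not present & {"optic_nerve", "csf", "sheath"}

    def test_nerve_free_labels_mirror_symmetric(self):
        """Mirror-paired sample points get identical labels when the nerve
        assembly is absent (construction symmetry)."""
        ph = build_phantom("nerve_free_eye", mesh=MeshSpec.preset("test"))
        rng = np.random.default_rng(5)
        pts = rng.uniform(-12, 12, (500, 3))
        lab = classify_points(pts, ph.params, include_nerve=False)
        lab_m = classify_points(pts * [-1, 1, 1], ph.params,
                                include_nerve=False)
        assert np.array_equal(lab, lab_m)

    def test_unknown_phantom_kind(self):
        with pytest.raises(ValueError):
            build_phantom("cube_of_jelly")


class TestParamValidation:
    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            EyeModelParams(retina_thickness=-0.1).validate()

    def test_tilt_bounds(self):
        with pytest.raises(ValueError):
            EyeModelParams(nerve_tilt=60.0).validate()
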
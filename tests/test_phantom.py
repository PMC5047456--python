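"""Head phantom: geometry, virtual surgery, tensors, electrodes."""

import numpy as np
import pytest

import craniofield as cf
from craniofield.constants import Tissue
from craniofield.phantom import (SkullDefectSpec, TensorParams,
                                 defect_patch_area, distance_to_surface)


def sphere_volume(r):
    return 4.0 / 3.0 * np.pi * r ** 3


class TestBuildPhantom:
    def test_compartment_volumes_match_analytic_within_5pct(self, phantom,
                                                            default_spec):
        r = default_spec.layer_radii
        a = default_spec.tumor_semiaxes
        tumor = 4.0 / 3.0 * np.pi * a[0] * a[1] * a[2]
        expected = {
            Tissue.SCALP: sphere_volume(r[0]) - sphere_volume(r[1]),
            Tissue.SKULL: sphere_volume(r[1]) - sphere_volume(r[2]),
            Tissue.CSF: sphere_volume(r[2]) - sphere_volume(r[3]),
            Tissue.GM: sphere_volume(r[3]) - sphere_volume(r[4]),
            Tissue.WM: sphere_volume(r[4]) - tumor,
            Tissue.TUMOR: tumor,
        }
        for tissue, vol in expected.items():
            assert phantom.compartment_volume(tissue) == pytest.approx(
                vol, rel=0.05), tissue

    def test_tumor_volume_matches_ellipsoid_formula(self, phantom):
        # 25 x 17.5 x 25.5 mm semiaxes -> 46.7 cm^3
        assert phantom.compartment_volume(Tissue.TUMOR) / 1000.0 == \
            pytest.approx(46.7, rel=0.05)

    def test_tumor_depth_below_cortex_about_20mm(self, phantom, default_spec):
        faces, _ = phantom.boundary_faces(phantom.labels == Tissue.TUMOR)
        surf = phantom.nodes[np.unique(faces)]
        depth = default_spec.layer_radii[3] - np.linalg.norm(surf, axis=1).max()
        assert depth == pytest.approx(20.0, abs=2.5)

    def test_zero_measure_tumor_rejected(self):
        spec = cf.HeadPhantomSpec(tumor_semiaxes=(0.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="infeasible"):
            cf.build_head_phantom(spec)

    def test_tumor_outside_brain_rejected(self):
        spec = cf.HeadPhantomSpec(tumor_center=(60.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="infeasible"):
            cf.build_head_phantom(spec)

    def test_volume_errors_shrink_with_resolution(self):
        errors = []
        for h in (16.0, 10.0, 6.0):
            mesh = cf.build_head_phantom(
                cf.HeadPhantomSpec(target_edge_length=h))
            got = mesh.compartment_volume(Tissue.TUMOR)
            want = 4.0 / 3.0 * np.pi * 25.0 * 17.5 * 25.5
            errors.append(abs(got - want) / want)
        assert errors[2] < errors[0]
        assert max(errors[1], errors[2]) < 0.05


class TestPeritumoralShell:
    def test_flag_respects_strict_margin(self, phantom):
        peri = phantom.get_flag("peritumoral")
        assert peri.sum() > 0
        faces, _ = phantom.boundary_faces(phantom.labels == Tissue.TUMOR)
        brain = np.isin(phantom.labels, (Tissue.GM, Tissue.WM))
        near = brain & (np.linalg.norm(
            phantom.centroids - np.array([31.0, 0, 0]), axis=1) < 50.0)
        d = distance_to_surface(phantom.centroids[near], phantom.nodes, faces)
        flagged = peri[near]
        assert np.all(flagged == (d < 10.0))

    def test_tumor_elements_never_flagged(self, phantom):
        assert not np.any(phantom.get_flag("peritumoral")
                          & (phantom.labels == Tissue.TUMOR))

    def test_monotone_in_margin(self, phantom):
        m5 = cf.flag_peritumoral(phantom.copy(), 5.0).get_flag("peritumoral")
        m10 = phantom.get_flag("peritumoral")  # built with 10 mm
        assert np.all(~m5 | m10)               # m5 subset of m10
        assert m5.sum() < m10.sum()

    def test_nonpositive_margin_rejected(self, phantom):
        with pytest.raises(ValueError):
            cf.flag_peritumoral(phantom.copy(), 0.0)


class TestSkullDefect:
    def test_circle_relabels_disc_of_matching_area(self, phantom):
        mesh = phantom.copy()
        cf.apply_skull_defect(mesh, SkullDefectSpec(kind="circle",
                                                    diameter=30.0))
        area = defect_patch_area(mesh)
        assert area == pytest.approx(np.pi * 15.0 ** 2, rel=0.10)
        # relabeled elements became scalp
        assert np.all(mesh.labels[mesh.get_flag("defect_relabeled")]
                      == Tissue.SCALP)

    def test_burr_holes_total_area(self, phantom):
        mesh = phantom.copy()
        cf.apply_skull_defect(mesh, SkullDefectSpec.four_burr_holes())
        area = defect_patch_area(mesh)
        assert area == pytest.approx(707.0, rel=0.10)

    def test_zero_diameter_is_identity(self, phantom):
        mesh = phantom.copy()
        out = cf.apply_skull_defect(mesh, SkullDefectSpec(kind="circle",
                                                          diameter=0.0))
        assert np.array_equal(out.labels, phantom.labels)

    def test_relabeling_preserves_geometry_and_total_volume(self, phantom):
        mesh = phantom.copy()
        cf.apply_skull_defect(mesh, SkullDefectSpec(kind="circle",
                                                    diameter=50.0))
        assert mesh.geometry_hash() == phantom.geometry_hash()
        assert mesh.total_volume() == pytest.approx(phantom.total_volume())

    def test_missing_skull_rejected(self, phantom):
        mesh = phantom.copy()
        with pytest.raises(ValueError, match="misses the skull"):
            cf.apply_skull_defect(mesh, SkullDefectSpec(
                kind="burr_holes", hole_diameter=1.0,
                hole_centers=((500.0, 500.0),)))

    def test_oval_flap_area(self, phantom):
        mesh = phantom.copy()
        spec = SkullDefectSpec(kind="oval_flap",
                               principal_diameters=(50.0, 67.0))
        cf.apply_skull_defect(mesh, spec)
        assert defect_patch_area(mesh) == pytest.approx(
            spec.footprint_area(), rel=0.10)


class TestResection:
    def test_resection_relabels_tumor_to_csf(self, phantom):
        mesh = phantom.copy()
        tumor_vol = mesh.compartment_volume(Tissue.TUMOR)
        csf_before = mesh.compartment_volume(Tissue.CSF)
        cf.apply_resection(mesh)
        assert mesh.compartment_volume(Tissue.TUMOR) == 0.0
        assert mesh.compartment_volume(Tissue.CSF) == pytest.approx(
            csf_before + tumor_vol)

    def test_peritumoral_flags_survive_resection(self, phantom):
        mesh = phantom.copy()
        before = mesh.get_flag("peritumoral").copy()
        cf.apply_resection(mesh)
        assert np.array_equal(mesh.get_flag("peritumoral"), before)

    def test_double_resection_warns_and_noops(self, phantom):
        mesh = phantom.copy()
        cf.apply_resection(mesh)
        labels = mesh.labels.copy()
        with pytest.warns(UserWarning, match="no tumor"):
            cf.apply_resection(mesh)
        assert np.array_equal(mesh.labels, labels)


class TestDiffusionTensors:
    def test_zero_noise_isotropic_gives_scaled_identity(self, phantom):
        params = TensorParams(fa={Tissue.GM: 0.0, Tissue.WM: 0.0,
                                  Tissue.TUMOR: 0.0}, noise_sigma=0.0)
        field = cf.generate_diffusion_tensors(phantom, params, seed=0)
        gm = phantom.labels == Tissue.GM
        d = params.md[Tissue.GM]
        assert np.allclose(field.tensors[gm], d * np.eye(3))

    def test_fixed_seed_reproducible_bitwise(self, phantom):
        f1 = cf.generate_diffusion_tensors(phantom, seed=42)
        f2 = cf.generate_diffusion_tensors(phantom, seed=42)
        assert np.array_equal(f1.tensors, f2.tensors)
        f3 = cf.generate_diffusion_tensors(phantom, seed=43)
        assert not np.array_equal(f1.tensors, f3.tensors)

    def test_tensors_spd_with_requested_fa(self, phantom):
        field = cf.generate_diffusion_tensors(phantom, seed=1)
        wm = phantom.labels == Tissue.WM
        lam = np.linalg.eigvalsh(field.tensors[wm])
        assert np.all(lam > 0)
        md = lam.mean(axis=1)
        fa = np.sqrt(1.5 * ((lam - md[:, None]) ** 2).sum(axis=1)
                     / (lam ** 2).sum(axis=1))
        assert np.allclose(fa, 0.70, atol=1e-10)

    def test_wm_principal_axis_radial(self, phantom):
        field = cf.generate_diffusion_tensors(phantom, seed=1)
        wm = np.flatnonzero(phantom.labels == Tissue.WM)
        lam, vec = np.linalg.eigh(field.tensors[wm])
        e1 = vec[:, :, 2]                       # largest eigenvalue last
        c = phantom.centroids[wm]
        rad = c / np.linalg.norm(c, axis=1, keepdims=True)
        cosang = np.abs(np.einsum("ij,ij->i", e1, rad))
        frac = np.mean(cosang > np.cos(np.deg2rad(5.0)))
        assert frac >= 0.99

    def test_invalid_anisotropy_rejected(self, phantom):
        params = TensorParams(fa={Tissue.GM: 1.0, Tissue.WM: 0.7,
                                  Tissue.TUMOR: 0.1})
        with pytest.raises(ValueError, match="anisotropy"):
            cf.generate_diffusion_tensors(phantom, params, seed=0)


class TestElectrodes:
    def test_patch_areas_near_requested_footprint(self, phantom):
        lr, ap = cf.place_electrode_pairs(phantom)
        for pair in (lr, ap):
            for area in pair.patch_areas(phantom):
                assert area == pytest.approx(70.0 * 50.0, rel=0.10)

    def test_lr_patch_aligned_with_defect_direction(self, phantom):
        lr, _ = cf.place_electrode_pairs(phantom)
        fc = phantom.nodes[lr.faces_a].mean(axis=(0, 1))
        d = fc / np.linalg.norm(fc)
        # defect over the superficial tumor points along +x
        assert np.degrees(np.arccos(d @ np.array([1.0, 0, 0]))) < 15.0

    def test_zero_patch_dimension_rejected(self, phantom):
        layout = cf.phantom.default_layout(patch_size=(0.0, 50.0))
        with pytest.raises(ValueError):
            cf.place_electrode_pairs(phantom, layout)

    def test_overlapping_patches_rejected(self, phantom):
        layout = {
            "LR": ((1.0, 0.0, 0.0), (1.0, 0.2, 0.0)),
            "AP": ((0.0, 1.0, 0.0), (0.0, -1.0, 0.0)),
            "patch_size": (70.0, 50.0),
        }
        with pytest.raises(ValueError, match="overlap"):
            cf.place_electrode_pairs(phantom, layout)
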
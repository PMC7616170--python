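"""Labeled tetrahedral meshing and interface surface areas."""

import numpy as np
import pytest

import scarshape as ss
from scarshape.mesh_interface import (
    build_labeled_mesh,
    build_labeled_mesh_from_layers,
    interface_area,
    interface_report,
)

from conftest import make_label_field, sphere_core_field


class TestBuildLabeledMesh:
    def test_single_voxel_splits_into_five_tets_conserving_volume(self):
        labels = np.full((3, 3, 3), -1)
        labels[1, 1, 1] = ss.BZ
        mesh = build_labeled_mesh(make_label_field(labels))
        assert len(mesh.elements) == 5
        vox_mm3 = 1.3 * 1.3 * 5.0
        assert mesh.total_volume_mm3() == pytest.approx(vox_mm3, abs=1e-6)
        assert np.all(mesh.element_volumes_mm3() > 0)

    def test_all_healthy_field_is_single_label(self):
        labels = np.full((5, 5, 5), -1)
        labels[1:4, 1:4, 1:4] = ss.HEALTHY
        mesh = build_labeled_mesh(make_label_field(labels))
        assert set(np.unique(mesh.element_label)) == {ss.HEALTHY}

    def test_spherical_shell_mesh_volume_within_2pct_of_analytic(
        self, spherical_spec, spherical_stack
    ):
        psi = ss.compute_psi(spherical_stack, mode="global_max")
        field = ss.classify_psi(psi, ss.DEFAULT_CONFIGS[1])
        mesh = build_labeled_mesh(field)
        analytic = spherical_spec.analytic_shell_volume_mm3()
        assert abs(mesh.total_volume_mm3() - analytic) / analytic < 0.02

    def test_mesh_volume_equals_voxel_count_times_volume(self):
        rng = np.random.default_rng(0)
        labels = np.where(rng.random((6, 6, 6)) < 0.5, rng.integers(0, 3, (6, 6, 6)), -1)
        if not (labels >= 0).any():
            labels[0, 0, 0] = 0
        field = make_label_field(labels)
        mesh = build_labeled_mesh(field)
        expect = (labels >= 0).sum() * field.voxel_volume_mm3
        assert mesh.total_volume_mm3() == pytest.approx(expect, rel=1e-12)


class TestInterfaceArea:
    def test_no_core_means_zero_bz_core_area(self):
        labels = np.full((5, 5, 5), -1)
        labels[1:4, 1:4, 1:4] = ss.BZ
        mesh = build_labeled_mesh(make_label_field(labels))
        assert interface_area(mesh, "BZ_vs_core") == 0.0

    def test_cuboid_core_area_exact_facet_arithmetic(self):
        # core block of 4 x 5 x 6 voxels inside BZ, spacing (1.3, 1.3, 5)
        labels = np.full((14, 15, 16), -1)
        labels[2:12, 2:13, 2:14] = ss.BZ
        labels[4:8, 5:10, 5:11] = ss.CORE
        mesh = build_labeled_mesh(make_label_field(labels))
        a, b, c = 4 * 1.3, 5 * 1.3, 6 * 5.0
        exact_cm2 = 2 * (a * b + b * c + a * c) / 100.0
        assert interface_area(mesh, "BZ_vs_core") == pytest.approx(exact_cm2, abs=1e-9)

    def test_sphere_core_area_within_5pct_of_4_pi_r2(self):
        field = sphere_core_field(radius_mm=10.0, spacing=(1.3, 1.3, 1.3))
        mesh = build_labeled_mesh(field)
        truth_cm2 = 4.0 * np.pi * 10.0**2 / 100.0
        corrected = interface_area(mesh, "BZ_vs_core", correction="normal")
        assert abs(corrected - truth_cm2) / truth_cm2 < 0.05
        # uncorrected staircase area overestimates a curved surface by ~3/2
        raw = interface_area(mesh, "BZ_vs_core", correction="none")
        assert 1.3 < raw / truth_cm2 < 1.6

    def test_sphere_core_area_at_clinical_slice_thickness(self):
        field = sphere_core_field(radius_mm=10.0, spacing=(1.3, 1.3, 5.0))
        mesh = build_labeled_mesh(field)
        truth_cm2 = 4.0 * np.pi * 10.0**2 / 100.0
        corrected = interface_area(mesh, "BZ_vs_core", correction="normal")
        assert abs(corrected - truth_cm2) / truth_cm2 < 0.05

    def test_healthy_he_invariant_under_bz_core_swap(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 3, size=(8, 8, 8)).astype(np.int8)
        field = make_label_field(labels)
        mesh = build_labeled_mesh(field)
        area = interface_area(mesh, "healthy_vs_HE")
        swapped = labels.copy()
        swapped[labels == ss.BZ] = ss.CORE
        swapped[labels == ss.CORE] = ss.BZ
        mesh2 = build_labeled_mesh(make_label_field(swapped))
        area2 = interface_area(mesh2, "healthy_vs_HE")
        assert area == pytest.approx(area2, rel=1e-12)

    def test_area_independent_of_element_order(self):
        rng = np.random.default_rng(9)
        labels = rng.integers(0, 3, size=(6, 6, 6)).astype(np.int8)
        mesh = build_labeled_mesh(make_label_field(labels))
        perm = rng.permutation(len(mesh.elements))
        shuffled = ss.LabeledVolumeMesh(
            vertices=mesh.vertices,
            elements=mesh.elements[perm],
            element_label=mesh.element_label[perm],
        )
        for pair in ("healthy_vs_HE", "BZ_vs_core"):
            assert interface_area(mesh, pair) == pytest.approx(
                interface_area(shuffled, pair), rel=1e-12
            )

    def test_refinement_keeps_corrected_sphere_area_in_band(self):
        coarse = sphere_core_field(radius_mm=10.0, spacing=(2.0, 2.0, 2.0))
        fine = sphere_core_field(radius_mm=10.0, spacing=(1.0, 1.0, 1.0))
        truth = 4.0 * np.pi * 10.0**2 / 100.0
        for field in (coarse, fine):
            a = interface_area(build_labeled_mesh(field), "BZ_vs_core", correction="normal")
            assert abs(a - truth) / truth < 0.05

    def test_unknown_pair_rejected(self):
        labels = np.full((3, 3, 3), ss.BZ)
        mesh = build_labeled_mesh(make_label_field(labels))
        with pytest.raises(ValueError):
            interface_area(mesh, "scar_vs_blood")


class TestLayerPathMesh:
    def test_layer_mesh_volume_close_to_analytic_shell(self, spherical_spec, spherical_stack):
        psi = ss.compute_psi(spherical_stack, mode="global_max")
        model = ss.build_layered_model(spherical_stack, psi, n_layers=5)
        mesh = build_labeled_mesh_from_layers(model, psi, ss.DEFAULT_CONFIGS[1])
        analytic = spherical_spec.analytic_shell_volume_mm3()
        # ring polygonization and apical caps cost a few percent
        assert abs(mesh.total_volume_mm3() - analytic) / analytic < 0.05
        assert np.all(mesh.element_volumes_mm3() >= 0)

    def test_crossed_layers_raise_with_layer_pair_named(self, spherical_stack):
        psi = ss.compute_psi(spherical_stack, mode="global_max")
        model = ss.build_layered_model(spherical_stack, psi, n_layers=3, n_rays=24)
        # invert: swap endo and epi surfaces so cells between 0 and 1 cross
        model.layers[0], model.layers[2] = model.layers[2], model.layers[0]
        inner = model.layers[1].vertices.copy()
        model.layers[1].vertices[:] = model.layers[0].vertices
        model.layers[0].vertices[:] = inner * 0.2
        with pytest.raises(ValueError, match="layers"):
            build_labeled_mesh_from_layers(model, psi, ss.DEFAULT_CONFIGS[1])


def test_bz_core_surface_lowest_for_widest_band():
    """Mean BZ-core interface area at PSI 30-70 falls below each of the
    three narrower bands on transmural-falloff infarct phantoms."""
    per_config = []
    for seed in range(4):
        stack = ss.generate_phantom(ss.realistic_infarct_spec(seed=seed))
        psi = ss.compute_psi(stack)
        areas = []
        for config in ss.DEFAULT_CONFIGS:
            mesh = build_labeled_mesh(ss.classify_psi(psi, config))
            areas.append(interface_area(mesh, "BZ_vs_core"))
        per_config.append(areas)
    mean = np.mean(per_config, axis=0)
    assert mean[3] < mean[0]
    assert mean[3] < mean[1]
    assert mean[3] < mean[2]


def test_interface_report_bundles_both_metrics(noise_free_stack):
    psi = ss.compute_psi(noise_free_stack, mode="global_max")
    mesh = build_labeled_mesh(ss.classify_psi(psi, ss.DEFAULT_CONFIGS[1]))
    rep = interface_report(mesh)
    assert rep.area_healthy_he_cm2 > 0
    assert rep.area_bz_core_cm2 > 0
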
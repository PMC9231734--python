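"""Synthetic-data generator: geometry, kinematics, perturbation, nuisances,
and dataset assembly."""

import numpy as np
import pytest
import trimesh

from fluoropose.geometry import CameraModel, flatten_pose, geodesic_distance
from fluoropose.rendering import render_joint_shadow
from fluoropose.synthetic import (
    KinematicsParams,
    NormalisationConstants,
    NuisanceParams,
    ToyImplantParams,
    XrayImage,
    apply_cutout,
    build_dataset,
    build_silhouette_dataset,
    default_perturbation_sigmas,
    generate_samples,
    generate_toy_implant_pair,
    leave_combination_out,
    perturb_pose,
    sample_base_kinematics,
    synthesize_xray,
)


class TestToyImplants:
    def test_same_seed_is_bit_identical(self):
        a = generate_toy_implant_pair(seed=3)
        b = generate_toy_implant_pair(seed=3)
        assert np.array_equal(a.femur_mesh.vertices, b.femur_mesh.vertices)
        assert np.array_equal(a.tibia_mesh.faces, b.tibia_mesh.faces)

    def test_watertight_with_positive_volume(self, combo):
        for mesh in (combo.femur_mesh, combo.tibia_mesh):
            tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
            assert tm.is_watertight
            assert tm.volume > 0.0

    def test_component_sizes_are_implant_like(self, combo):
        for mesh in (combo.femur_mesh, combo.tibia_mesh):
            extent = mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)
            assert 30.0 < extent.max() < 95.0

    def test_size_scale_is_linear(self):
        base = generate_toy_implant_pair(ToyImplantParams(size_scale=1.0), seed=2)
        doubled = generate_toy_implant_pair(ToyImplantParams(size_scale=2.0), seed=2)
        ratio = doubled.femur_mesh.bounding_box_diagonal / base.femur_mesh.bounding_box_diagonal
        assert ratio == pytest.approx(2.0, abs=1e-6)

    def test_degenerate_params_rejected(self):
        with pytest.raises(ValueError):
            ToyImplantParams(size_scale=-1.0)
        with pytest.raises(ValueError):
            ToyImplantParams(tray_radius=0.0)


class TestKinematics:
    def test_single_frame(self):
        frames = sample_base_kinematics(1, seed=0)
        assert len(frames) == 1

    def test_depth_and_flexion_bounds(self):
        params = KinematicsParams()
        for seed in range(5):
            for jp in sample_base_kinematics(60, params, seed=seed):
                assert params.depth_range_mm[0] <= jp.femur.translation[2] <= params.depth_range_mm[1]
                assert params.depth_range_mm[0] <= jp.tibia.translation[2] <= params.depth_range_mm[1]

    def test_smooth_rotation_steps(self):
        frames = sample_base_kinematics(80, seed=6)
        for a, b in zip(frames, frames[1:]):
            step = np.rad2deg(geodesic_distance(a.femur.rotation, b.femur.rotation))
            assert step < 5.0

    def test_rejects_empty_trajectory(self):
        with pytest.raises(ValueError):
            sample_base_kinematics(0)


class TestPerturbation:
    def test_zero_sigmas_identity(self):
        jp = sample_base_kinematics(1, seed=1)[0]
        out = perturb_pose(jp, np.zeros(18), seed=5)
        assert out is jp

    def test_translation_moments_match_sigmas(self):
        jp = sample_base_kinematics(1, seed=2)[0]
        sigmas = default_perturbation_sigmas()
        flats = np.stack(
            [flatten_pose(perturb_pose(jp, sigmas, seed=s)) for s in range(10_000)]
        )
        base = flatten_pose(jp)
        for idx in (0, 1, 2, 9, 10, 11):
            sd = np.std(flats[:, idx] - base[idx])
            assert abs(sd - sigmas[idx]) / sigmas[idx] < 0.05

    def test_rotations_remain_valid(self):
        jp = sample_base_kinematics(1, seed=3)[0]
        for s in range(50):
            out = perturb_pose(jp, seed=s)
            for rot in (out.femur.rotation, out.tibia.rotation):
                assert np.allclose(rot.T @ rot, np.eye(3), atol=1e-9)

    def test_negative_sigma_rejected(self):
        jp = sample_base_kinematics(1, seed=1)[0]
        with pytest.raises(ValueError):
            perturb_pose(jp, -np.ones(18), seed=0)


class TestCutout:
    def _ones(self, cam):
        return XrayImage(pixels=np.ones((cam.image_size,) * 2), camera=cam)

    def test_probability_zero_is_noop(self, cam64):
        img = self._ones(cam64)
        assert apply_cutout(img, probability=0.0, seed=1) is img

    def test_full_side_square_blanks_image(self, cam64):
        out = apply_cutout(self._ones(cam64), probability=1.0, n_squares=1,
                           side_px=64, seed=2)
        assert out.pixels.sum() == 0  # square as large as the image

    def test_oversized_square_rejected(self, cam64):
        with pytest.raises(ValueError):
            apply_cutout(self._ones(cam64), probability=1.0, side_px=128, seed=2)

    def test_zeroed_fraction_bounded(self, cam64):
        n = cam64.image_size
        side = n // 4
        for seed in range(10):
            out = apply_cutout(self._ones(cam64), probability=1.0, n_squares=4,
                               side_px=side, seed=seed)
            zeroed = 1.0 - out.pixels.mean()
            assert zeroed <= 4 * side**2 / n**2 + 1e-12

    def test_default_side_is_quarter_of_image(self):
        cam512 = CameraModel.standard(512)
        img = XrayImage(pixels=np.ones((512, 512)), camera=cam512)
        out = apply_cutout(img, probability=1.0, n_squares=1, seed=7)
        zeroed_px = int((out.pixels == 0).sum())
        assert 0 < zeroed_px <= 128 * 128


class TestXraySynthesis:
    def test_degenerate_settings_give_inverted_shadow(self, combo, cam64):
        jp = sample_base_kinematics(1, seed=4)[0]
        shadow = render_joint_shadow(combo, jp, cam64)
        img = synthesize_xray(shadow, NuisanceParams.off(), seed=0)
        assert np.array_equal(img.pixels, 1.0 - shadow.pixels)

    def test_extreme_params_stay_in_range(self, combo, cam64):
        jp = sample_base_kinematics(1, seed=4)[0]
        shadow = render_joint_shadow(combo, jp, cam64)
        params = NuisanceParams(contrast=1.0, background_amplitude=0.9,
                                n_occluders=3, occluder_opacity=1.0, noise_sigma=0.5)
        img = synthesize_xray(shadow, params, seed=1)
        assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0

    def test_implant_brightness_monotone_in_occluder_opacity(self, combo, cam64):
        jp = sample_base_kinematics(1, seed=4)[0]
        shadow = render_joint_shadow(combo, jp, cam64)
        mask = shadow.pixels.astype(bool)
        means = []
        for opacity in (0.0, 0.2, 0.4, 0.6):
            params = NuisanceParams(n_occluders=1, occluder_opacity=opacity, noise_sigma=0.0)
            img = synthesize_xray(shadow, params, seed=11)
            means.append(img.pixels[mask].mean())
        assert all(b > a for a, b in zip(means, means[1:]))


class TestDatasetAssembly:
    def test_sample_shadow_consistency(self, combo, cam64):
        samples = generate_samples(combo, 3, cam64, seed=5)
        for s in samples:
            rerender = render_joint_shadow(combo, s.true_pose, cam64)
            assert np.array_equal(rerender.pixels, s.true_shadow.pixels)

    def test_silhouette_dataset_reproducible(self, combo, cam64):
        a = build_silhouette_dataset(combo, 5, cam64, seed=9)
        b = build_silhouette_dataset(combo, 5, cam64, seed=9)
        assert np.array_equal(a.shadows, b.shadows)
        assert np.array_equal(a.targets, b.targets)

    def test_leave_combination_out(self, combo, cam64):
        other = generate_toy_implant_pair(seed=8)
        samples = generate_samples(combo, 2, cam64, seed=1) + generate_samples(other, 2, cam64, seed=2)
        train, test = leave_combination_out(samples, combo.combo_id)
        assert all(s.combo_id != combo.combo_id for s in train)
        assert all(s.combo_id == combo.combo_id for s in test)
        assert len(train) + len(test) == len(samples)

    def test_build_dataset_manifest_and_determinism(self, combo, cam64, tmp_path):
        other = generate_toy_implant_pair(seed=8)
        manifest1 = build_dataset([combo, other], 3, NuisanceParams(), 7,
                                  tmp_path / "d1", cam=cam64,
                                  test_combo_ids=[other.combo_id])
        manifest2 = build_dataset([combo, other], 3, NuisanceParams(), 7,
                                  tmp_path / "d2", cam=cam64,
                                  test_combo_ids=[other.combo_id])
        assert len(manifest1["samples"]) == 6
        assert manifest1["samples"] == manifest2["samples"]
        assert manifest1["normalisation"] == manifest2["normalisation"]
        splits = {s["combo_id"]: s["split"] for s in manifest1["samples"]}
        assert splits[other.combo_id] == "test" and splits[combo.combo_id] == "train"

    def test_duplicate_combo_id_rejected(self, combo, cam64, tmp_path):
        with pytest.raises(ValueError):
            build_dataset([combo, combo], 1, NuisanceParams(), 0, tmp_path / "dup", cam=cam64)


class TestNormalisation:
    def test_roundtrip(self, rng):
        norm = NormalisationConstants(mean=rng.normal(0, 5, 6), std=rng.uniform(1, 3, 6))
        flat = rng.normal(0, 10, 18)
        assert np.allclose(norm.denormalise(norm.normalise(flat)), flat, atol=1e-12)

    def test_degenerate_std_floored(self):
        norm = NormalisationConstants(mean=np.zeros(6), std=np.zeros(6))
        assert np.all(norm.std >= 1e-3)
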
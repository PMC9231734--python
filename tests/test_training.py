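"""Training protocols: accumulation equivalence, freezing, reproducibility,
learning sanity, and the iterative inference loop."""

import numpy as np
import pytest

from fluoropose.geometry import CameraModel
from fluoropose.losses import pose_loss_with_grad
from fluoropose.networks import ModelSpec, build_model
from fluoropose.rendering import render_joint_shadow
from fluoropose.synthetic import (
    NormalisationConstants,
    NuisanceParams,
    build_silhouette_dataset,
    generate_samples,
    generate_toy_implant_pair,
)
from fluoropose.training import (
    RegistryError,
    TrainConfig,
    personalise_synthnet,
    pretrain_synthnet,
    run_damn,
    shadownet_config,
    synthnet_config,
    train_shadownet,
)


@pytest.fixture(scope="module")
def small_dataset(combo, cam64):
    return build_silhouette_dataset(combo, 200, cam64, seed=21)


class TestTrainConfig:
    def test_momentum_forced_zero_for_shadownet(self):
        cfg = TrainConfig(stage="shadownet", batch_size=2, accumulation_target=16,
                          optimiser="sgd", learning_rate=1e-2, epochs=1, seed=0,
                          momentum=0.9)
        assert cfg.momentum == 0.0

    def test_accumulation_must_be_multiple_of_batch(self):
        with pytest.raises(ValueError):
            TrainConfig(stage="synthnet", batch_size=3, accumulation_target=32,
                        optimiser="adam", learning_rate=1e-3, epochs=1, seed=0)

    def test_unknown_optimiser_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(stage="synthnet", batch_size=4, accumulation_target=32,
                        optimiser="lbfgs", learning_rate=1e-3, epochs=1, seed=0)


class TestGradientAccumulation:
    def test_accumulated_singles_equal_batch(self, small_dataset):
        """Instance norm + mean-reduced losses make eight accumulated
        single-sample gradients identical to one batch-of-eight gradient."""
        x = small_dataset.shadows[:8]
        t = small_dataset.targets[:8]

        def grads(batch_sizes):
            model = build_model(ModelSpec(stage="synthnet", scale="tiny"), seed=4)
            model.zero_grad()
            start = 0
            for bs in batch_sizes:
                xb, tb = x[start : start + bs], t[start : start + bs]
                y = model.forward(xb)
                g = np.stack([pose_loss_with_grad(tb[i], y[i])[1] for i in range(bs)])
                model.backward(g / 8.0)
                start += bs
            return [p.grad.copy() for p in model.parameters()]

        accumulated = grads([1] * 8)
        batched = grads([8])
        worst = max(np.abs(a - b).max() for a, b in zip(accumulated, batched))
        assert worst < 1e-5


class TestPretraining:
    def test_loss_decreases(self, combo, small_dataset):
        model = build_model(ModelSpec(stage="synthnet", scale="tiny"), seed=0)
        model, log = pretrain_synthnet(combo, small_dataset, synthnet_config(epochs=3, seed=0), model)
        assert log[-1]["mean_pose_loss"] < log[0]["mean_pose_loss"]

    def test_seed_reproducibility(self, combo, small_dataset):
        cfg = synthnet_config(epochs=2, seed=11)
        m1, log1 = pretrain_synthnet(combo, small_dataset,
                                     cfg, build_model(ModelSpec(stage="synthnet", scale="tiny"), seed=1))
        m2, log2 = pretrain_synthnet(combo, small_dataset,
                                     cfg, build_model(ModelSpec(stage="synthnet", scale="tiny"), seed=1))
        assert log1 == log2
        for p1, p2 in zip(m1.parameters(), m2.parameters()):
            assert np.array_equal(p1.data, p2.data)

    def test_empty_dataset_rejected(self, combo, small_dataset, cam64):
        from dataclasses import replace

        empty = replace(small_dataset, shadows=small_dataset.shadows[:0],
                        targets=small_dataset.targets[:0])
        with pytest.raises(ValueError):
            pretrain_synthnet(combo, empty, synthnet_config(epochs=1, seed=0),
                              build_model(ModelSpec(stage="synthnet", scale="tiny"), seed=0))


class TestPersonalisation:
    def test_frozen_prefix_unchanged_and_rest_updated(self, combo, small_dataset):
        base = build_model(ModelSpec(stage="synthnet", scale="tiny"), seed=2)
        base_params = [p.data.copy() for p in base.parameters()]
        model, _ = personalise_synthnet(base, combo, small_dataset,
                                        synthnet_config(epochs=2, seed=3))
        n_first = len(base[0].parameters())
        for i, p in enumerate(model.parameters()):
            if i < n_first:
                assert np.array_equal(p.data, base_params[i])
        assert any(not np.array_equal(p.data, b)
                   for p, b in zip(model.parameters(), base_params))

    def test_full_freeze_returns_identical_model(self, combo, small_dataset):
        base = build_model(ModelSpec(stage="synthnet", scale="tiny"), seed=2)
        model, log = personalise_synthnet(base, combo, small_dataset,
                                          synthnet_config(epochs=2, seed=3),
                                          freeze_fraction=1.0)
        assert log == []
        for p, b in zip(model.parameters(), base.parameters()):
            assert np.array_equal(p.data, b.data)

    def test_personalisation_beats_base_on_target_combo(self, combo, cam64):
        """A regressor pretrained on a different implant pair improves on the
        target pair after frozen-prefix transfer."""
        other = generate_toy_implant_pair(seed=40)
        base_set = build_silhouette_dataset(other, 300, cam64, seed=31)
        base = build_model(ModelSpec(stage="synthnet", scale="tiny"), seed=5)
        base, _ = pretrain_synthnet(other, base_set, synthnet_config(epochs=8, seed=5), base)

        target_set = build_silhouette_dataset(combo, 300, cam64, seed=32, norm=base_set.norm)
        held_out = build_silhouette_dataset(combo, 60, cam64, seed=33, norm=base_set.norm)
        personal, _ = personalise_synthnet(base, combo, target_set,
                                           synthnet_config(epochs=8, seed=6))

        def mean_loss(model):
            y = model.forward(held_out.shadows)
            return np.mean([pose_loss_with_grad(held_out.targets[i], y[i])[0]
                            for i in range(len(held_out))])

        assert mean_loss(personal) < mean_loss(base)


@pytest.fixture(scope="module")
def shadow_training_setup(combo, cam64):
    """Samples plus briefly pretrained per-combination regressors: the
    segmentation stage is always trained against personalised regressors,
    never randomly initialised ones."""
    other = generate_toy_implant_pair(seed=50)
    samples = (generate_samples(combo, 30, cam64, seed=61, nuisance=NuisanceParams())
               + generate_samples(other, 30, cam64, seed=62, nuisance=NuisanceParams()))
    from fluoropose.geometry import flatten_pose

    norm = NormalisationConstants.from_flat_poses(
        np.stack([flatten_pose(s.true_pose) for s in samples]))
    registry = {}
    for seed, c in ((7, combo), (8, other)):
        train_set = build_silhouette_dataset(c, 120, cam64, seed=seed * 100, norm=norm)
        model = build_model(ModelSpec(stage="synthnet", scale="tiny"), seed=seed)
        model, _ = pretrain_synthnet(c, train_set, synthnet_config(epochs=3, seed=seed), model)
        registry[c.combo_id] = model
    meshes = {combo.combo_id: combo, other.combo_id: other}
    return samples, registry, norm, meshes


class TestShadownetTraining:
    def test_synthnets_frozen_and_loss_decreases(self, shadow_training_setup):
        samples, registry, norm, meshes = shadow_training_setup
        before = {cid: [p.data.copy() for p in m.parameters()] for cid, m in registry.items()}
        shadownet = build_model(ModelSpec(stage="shadownet", scale="tiny"), seed=9)
        shadownet, log = train_shadownet(shadownet, samples, registry,
                                         shadownet_config(epochs=6, seed=10), norm)
        assert log[-1]["mean_total_loss"] < log[0]["mean_total_loss"]
        for cid, model in registry.items():
            for p, b in zip(model.parameters(), before[cid]):
                assert np.array_equal(p.data, b)
        assert set(log[0]["per_combo"]) == set(registry)

    def test_missing_synthnet_raises(self, shadow_training_setup):
        samples, registry, norm, _ = shadow_training_setup
        partial = {next(iter(registry)): next(iter(registry.values()))}
        shadownet = build_model(ModelSpec(stage="shadownet", scale="tiny"), seed=9)
        with pytest.raises(RegistryError):
            train_shadownet(shadownet, samples, partial,
                            shadownet_config(epochs=1, seed=0), norm)


class _RecordingNet:
    """Wraps a network and records every forward input."""

    def __init__(self, inner):
        self.inner = inner
        self.inputs = []

    def forward(self, x):
        self.inputs.append(x.copy())
        return self.inner.forward(x)

    def __getattr__(self, name):
        return getattr(self.inner, name)


class TestRunDamn:
    def test_single_iteration_uses_black_feedback(self, combo, cam64):
        shadownet = _RecordingNet(build_model(ModelSpec(stage="shadownet", scale="tiny"), seed=0))
        synthnet = build_model(ModelSpec(stage="synthnet", scale="tiny"), seed=1)
        samples = generate_samples(combo, 1, cam64, seed=70)
        pose, iterations = run_damn(samples[0].image, combo, shadownet, synthnet, cam64,
                                    n_iterations=1)
        assert len(iterations) == 1
        assert np.all(shadownet.inputs[0][0, 1] == 0.0)
        assert np.isclose(np.linalg.det(pose.femur.rotation), 1.0, atol=1e-9)

    def test_second_feedback_is_render_of_first_pose(self, combo, cam64):
        shadownet = _RecordingNet(build_model(ModelSpec(stage="shadownet", scale="tiny"), seed=0))
        synthnet = build_model(ModelSpec(stage="synthnet", scale="tiny"), seed=1)
        # identity normalisation would put predictions at depth ~0; use
        # constants that map raw outputs to plausible depths
        norm = NormalisationConstants(mean=np.array([0, 0, 500, 0, 0, 500], dtype=float),
                                      std=np.array([20, 20, 50, 20, 20, 50], dtype=float))
        samples = generate_samples(combo, 1, cam64, seed=71)
        pose, iterations = run_damn(samples[0].image, combo, shadownet, synthnet, cam64,
                                    n_iterations=2, norm=norm)
        expected = render_joint_shadow(combo, iterations[0].pose, cam64).pixels.astype(float)
        assert np.array_equal(shadownet.inputs[1][0, 1], expected)

    def test_unrenderable_intermediate_falls_back_to_black(self, combo, cam64):
        shadownet = _RecordingNet(build_model(ModelSpec(stage="shadownet", scale="tiny"), seed=0))
        synthnet = build_model(ModelSpec(stage="synthnet", scale="tiny"), seed=1)
        samples = generate_samples(combo, 1, cam64, seed=72)
        # identity constants leave predicted depths near zero -> behind camera
        pose, iterations = run_damn(samples[0].image, combo, shadownet, synthnet, cam64,
                                    n_iterations=2)
        assert len(iterations) == 2
        assert np.all(shadownet.inputs[1][0, 1] == 0.0)

    def test_rejects_zero_iterations(self, combo, cam64):
        shadownet = build_model(ModelSpec(stage="shadownet", scale="tiny"), seed=0)
        synthnet = build_model(ModelSpec(stage="synthnet", scale="tiny"), seed=1)
        samples = generate_samples(combo, 1, cam64, seed=73)
        with pytest.raises(ValueError):
            run_damn(samples[0].image, combo, shadownet, synthnet, cam64, n_iterations=0)
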
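"""Loss functions against brute-force oracles and finite differences."""

import itertools

import numpy as np
import pytest

from fluoropose.geometry import (
    JointPose,
    RigidPose,
    flatten_pose,
    random_rotation,
)
from fluoropose.losses import (
    LossWeights,
    lovasz_hinge,
    lovasz_hinge_with_grad,
    pose_loss,
    pose_loss_with_grad,
    rotation_loss,
    total_loss,
    translation_loss,
)
from fluoropose.rendering import ShadowImage
from fluoropose.geometry import CameraModel


def _rot_x(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])


def _random_pose(rng):
    return JointPose(
        femur=RigidPose(rotation=random_rotation(rng), translation=rng.normal(0, 30, 3)),
        tibia=RigidPose(rotation=random_rotation(rng), translation=rng.normal(0, 30, 3)),
    )


class TestTranslationLoss:
    def test_zero_at_equality(self):
        assert translation_loss([1, 2, 3], [1, 2, 3]) == 0.0

    @pytest.mark.parametrize("delta,expected", [((1, 0, 0), 10.0), ((0, 0, 1), 1.0),
                                                ((1, 1, 1), 21.0)])
    def test_weighting(self, delta, expected):
        assert translation_loss([0, 0, 0], delta) == pytest.approx(expected)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            translation_loss([np.nan, 0, 0], [0, 0, 0])


class TestRotationLoss:
    def test_zero_at_equality_and_closed_form(self):
        assert rotation_loss(np.eye(3), np.eye(3)) == 0.0
        assert rotation_loss(np.eye(3), _rot_x(0.5)) == pytest.approx(0.5, abs=1e-12)

    def test_symmetric(self, rng):
        for _ in range(20):
            a, b = random_rotation(rng), random_rotation(rng)
            assert rotation_loss(a, b) == pytest.approx(rotation_loss(b, a), abs=1e-12)


class TestPoseLoss:
    def test_zero_at_equality(self, rng):
        jp = _random_pose(rng)
        assert pose_loss(jp, jp) == pytest.approx(0.0, abs=1e-7)

    def test_femur_only_translation(self, rng):
        jp = _random_pose(rng)
        moved = JointPose(
            femur=RigidPose(rotation=jp.femur.rotation,
                            translation=jp.femur.translation + [1, 0, 0]),
            tibia=jp.tibia,
        )
        assert pose_loss(jp, moved) == pytest.approx(10.0, abs=1e-7)

    def test_decomposes_into_four_terms(self, rng):
        w = LossWeights()
        for _ in range(10):
            a, b = _random_pose(rng), _random_pose(rng)
            expected = (
                translation_loss(a.femur.translation, b.femur.translation, w)
                + rotation_loss(a.femur.rotation, b.femur.rotation)
                + translation_loss(a.tibia.translation, b.tibia.translation, w)
                + rotation_loss(a.tibia.rotation, b.tibia.rotation)
            )
            assert pose_loss(a, b, w) == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_component_relabeling(self, rng):
        a, b = _random_pose(rng), _random_pose(rng)
        a_sw = JointPose(femur=a.tibia, tibia=a.femur)
        b_sw = JointPose(femur=b.tibia, tibia=b.femur)
        assert pose_loss(a, b) == pytest.approx(pose_loss(a_sw, b_sw), abs=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        pt = flatten_pose(_random_pose(rng))
        pp = pt + rng.normal(0, 0.3, 18)
        _, grad = pose_loss_with_grad(pt, pp)
        eps = 1e-6
        for i in range(18):
            d = np.zeros(18)
            d[i] = eps
            fd = (pose_loss_with_grad(pt, pp + d)[0] - pose_loss_with_grad(pt, pp - d)[0]) / (2 * eps)
            assert grad[i] == pytest.approx(fd, abs=1e-5)


def _lovasz_bruteforce(logits: np.ndarray, truth: np.ndarray) -> float:
    """Direct evaluation of the Lovasz extension of the Jaccard loss over
    sorted hinge errors, from the set-function definition: the loss is the
    sum of hinge errors weighted by increments of the Jaccard loss of
    growing mispredicted prefix sets."""
    gt = truth.reshape(-1).astype(bool)
    lg = logits.reshape(-1)
    signs = np.where(gt, 1.0, -1.0)
    errors = np.maximum(1.0 - lg * signs, 0.0)
    order = np.argsort(-errors, kind="stable")

    def jaccard_loss_of_prefix(k: int) -> float:
        mis = np.zeros(gt.size, dtype=bool)
        mis[order[:k]] = True
        intersection = np.logical_and(gt, ~mis).sum()
        union = gt.sum() + np.logical_and(mis, ~gt).sum()
        return 1.0 - intersection / union

    loss = 0.0
    for k in range(1, gt.size + 1):
        delta = jaccard_loss_of_prefix(k) - jaccard_loss_of_prefix(k - 1)
        loss += errors[order[k - 1]] * delta
    return loss


class TestLovaszHinge:
    def test_perfect_confident_prediction_is_zero(self):
        truth = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        logits = np.where(truth, 2.0, -2.0)
        assert lovasz_hinge(logits, truth) == 0.0

    def test_bruteforce_oracle_all_3x3_truths(self):
        rng = np.random.default_rng(99)
        worst = 0.0
        for bits in itertools.product((0, 1), repeat=9):
            truth = np.array(bits, dtype=np.uint8).reshape(3, 3)
            if truth.sum() == 0:
                continue  # degenerate Jaccard gradient; covered below
            logits = rng.normal(0.0, 2.0, (3, 3))
            worst = max(worst, abs(lovasz_hinge(logits, truth) - _lovasz_bruteforce(logits, truth)))
        assert worst < 1e-9

    def test_empty_truth_falls_back_to_mean_hinge(self):
        truth = np.zeros((3, 3), dtype=np.uint8)
        logits = np.full((3, 3), -2.0)
        assert lovasz_hinge(logits, truth) == 0.0
        logits[0, 0] = 1.0  # one wrong, confident pixel
        assert lovasz_hinge(logits, truth) == pytest.approx(2.0 / 9.0)

    def test_monotone_in_wrong_logit(self, rng):
        truth = (rng.uniform(size=(4, 4)) > 0.5).astype(np.uint8)
        logits = rng.normal(0, 1, (4, 4))
        base = lovasz_hinge(logits, truth)
        signs = np.where(truth, 1.0, -1.0)
        for (i, j) in np.argwhere(signs * logits < 1.0)[:6]:  # positive hinge error
            worse = logits.copy()
            worse[i, j] -= signs[i, j]  # push further onto the wrong side
            assert lovasz_hinge(worse, truth) >= base - 1e-12

    def test_reduces_to_jaccard_loss_at_unit_margin(self, rng):
        """With unit-magnitude logits, mispredicted pixels all carry hinge
        error 2 and correct ones 0, so the extension collapses to twice the
        Jaccard loss of the thresholded prediction."""
        from fluoropose.evaluation import jaccard

        truth = (rng.uniform(size=(6, 6)) > 0.5).astype(np.uint8)
        pred = (rng.uniform(size=(6, 6)) > 0.5).astype(np.uint8)
        logits = np.where(pred, 1.0, -1.0).astype(float)
        assert lovasz_hinge(logits, truth) == pytest.approx(
            2.0 * (1.0 - jaccard(pred, truth)), abs=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        truth = (rng.uniform(size=(4, 4)) > 0.5).astype(np.uint8)
        logits = rng.normal(0, 1, (4, 4))
        _, grad = lovasz_hinge_with_grad(logits, truth)
        eps = 1e-7
        for i in range(4):
            for j in range(4):
                d = np.zeros((4, 4))
                d[i, j] = eps
                fd = (lovasz_hinge_with_grad(logits + d, truth)[0]
                      - lovasz_hinge_with_grad(logits - d, truth)[0]) / (2 * eps)
                assert grad[i, j] == pytest.approx(fd, abs=1e-6)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            lovasz_hinge(np.zeros((2, 2)), np.zeros((3, 3), dtype=np.uint8))


class TestTotalLoss:
    def test_zero_at_perfect_prediction(self, rng):
        jp = _random_pose(rng)
        cam = CameraModel.standard(4)
        truth = ShadowImage(pixels=np.eye(4, dtype=np.uint8), camera=cam)
        logits = np.where(truth.pixels, 3.0, -3.0)
        assert total_loss(jp, jp, truth, logits) == pytest.approx(0.0, abs=1e-7)

    def test_decomposition_on_seeded_inputs(self, rng):
        w = LossWeights()
        cam = CameraModel.standard(8)
        for _ in range(5):
            a, b = _random_pose(rng), _random_pose(rng)
            truth = ShadowImage(pixels=(rng.uniform(size=(8, 8)) > 0.5).astype(np.uint8), camera=cam)
            logits = rng.normal(0, 1, (8, 8))
            expected = w.segmentation_w * lovasz_hinge(logits, truth) + pose_loss(a, b, w)
            assert total_loss(a, b, truth, logits, w) == pytest.approx(expected, abs=1e-12)
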
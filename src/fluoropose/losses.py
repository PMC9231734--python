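"""Training objectives: weighted-L1 translation loss, geodesic rotation
loss, the combined 18-component pose loss, the Lovasz-hinge segmentation
loss, and their weighted total.

Each loss has a plain forward evaluator (the public surface) and a
``*_with_grad`` companion returning the analytic gradient with respect to
the prediction, used by the training loops.  All losses are per-sample;
batch reduction is the mean, which is what makes gradient accumulation
over micro-batches exactly equivalent to one large batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import JointPose, decode_rotation_6d, flatten_pose, geodesic_distance
from .rendering import ShadowImage

__all__ = [
    "LossWeights",
    "translation_loss",
    "rotation_loss",
    "pose_loss",
    "pose_loss_with_grad",
    "lovasz_hinge",
    "lovasz_hinge_with_grad",
    "total_loss",
]

#: clamp on cos(angle) when differentiating arccos, to keep gradients finite
_GRAD_COS_CLAMP = 1e-6


@dataclass(frozen=True)
class LossWeights:
    """Relative weights of the loss terms.

    In-plane translations (x, y) are weighted 10x the out-of-plane depth
    (z): depth only changes apparent size through perspective, so it is
    intrinsically harder to estimate and is deliberately de-emphasised.
    The segmentation term of the total loss carries weight 10 to make it
    comparable in magnitude to the pose term.
    """

    in_plane: float = 10.0
    out_of_plane: float = 1.0
    segmentation_w: float = 10.0

    def __post_init__(self) -> None:
        if min(self.in_plane, self.out_of_plane, self.segmentation_w) <= 0:
            raise ValueError("loss weights must be strictly positive")


def translation_loss(
    t_true: np.ndarray, t_pred: np.ndarray, weights: LossWeights = LossWeights()
) -> float:
    """Weighted L1: ``w_ip * (|dx| + |dy|) + w_op * |dz|``."""
    t_true = np.asarray(t_true, dtype=float).reshape(3)
    t_pred = np.asarray(t_pred, dtype=float).reshape(3)
    if not (np.all(np.isfinite(t_true)) and np.all(np.isfinite(t_pred))):
        raise ValueError("translation loss requires finite inputs")
    delta = np.abs(t_pred - t_true)
    return float(weights.in_plane * (delta[0] + delta[1]) + weights.out_of_plane * delta[2])


def rotation_loss(rot_true: np.ndarray, rot_pred: np.ndarray) -> float:
    """Geodesic distance on SO(3) between true and predicted orientation."""
    return geodesic_distance(rot_pred, rot_true)


def pose_loss(
    jp_true: JointPose, jp_pred: JointPose, weights: LossWeights = LossWeights()
) -> float:
    """Combined pose loss: translation + rotation terms for both components."""
    loss = translation_loss(jp_true.femur.translation, jp_pred.femur.translation, weights)
    loss += rotation_loss(jp_true.femur.rotation, jp_pred.femur.rotation)
    loss += translation_loss(jp_true.tibia.translation, jp_pred.tibia.translation, weights)
    loss += rotation_loss(jp_true.tibia.rotation, jp_pred.tibia.rotation)
    return float(loss)


# ---------------------------------------------------------------------------
# analytic gradients through the 18-vector parameterisation


def _decode_6d_forward(v: np.ndarray):
    # training-path Gram-Schmidt: norms clamped so a degenerate predicted
    # 6D block (e.g. from an all-background segmentation early in training)
    # yields a large finite loss instead of NaN; the strict inference-path
    # decoding lives in geometry.decode_rotation_6d
    a1, a2 = v[:3], v[3:]
    n1 = max(np.linalg.norm(a1), 1e-8)
    b1 = a1 / n1
    s = b1 @ a2
    u2 = a2 - s * b1
    n2 = max(np.linalg.norm(u2), 1e-8)
    b2 = u2 / n2
    b3 = np.cross(b1, b2)
    rot = np.column_stack([b1, b2, b3])
    return rot, (a2, n1, b1, s, n2, b2, b3)


def _decode_6d_backward(cache, g_rot: np.ndarray) -> np.ndarray:
    """Backpropagate d(loss)/d(R) through the Gram-Schmidt decoding."""
    a2, n1, b1, s, n2, b2, b3 = cache
    g_b1 = g_rot[:, 0].copy()
    g_b2 = g_rot[:, 1].copy()
    g_b3 = g_rot[:, 2]
    # b3 = b1 x b2
    g_b1 += np.cross(b2, g_b3)
    g_b2 += np.cross(g_b3, b1)
    # b2 = u2 / |u2|
    g_u2 = (g_b2 - (b2 @ g_b2) * b2) / n2
    # u2 = a2 - (b1.a2) b1
    g_a2 = g_u2 - (b1 @ g_u2) * b1
    g_b1 += -(b1 @ g_u2) * a2 - s * g_u2
    # b1 = a1 / |a1|
    g_a1 = (g_b1 - (b1 @ g_b1) * b1) / n1
    return np.concatenate([g_a1, g_a2])


def _geodesic_with_grad(rot_true: np.ndarray, rot_pred: np.ndarray):
    """Loss and d(loss)/d(R_pred); cos is clamped away from +-1 so the
    arccos derivative stays finite at (near-)perfect predictions."""
    cos_angle = (np.trace(rot_pred @ rot_true.T) - 1.0) / 2.0
    loss = float(abs(np.arccos(np.clip(cos_angle, -1.0, 1.0))))
    c = np.clip(cos_angle, -1.0 + _GRAD_COS_CLAMP, 1.0 - _GRAD_COS_CLAMP)
    g_pred = (-0.5 / np.sqrt(1.0 - c * c)) * rot_true
    return loss, g_pred


def pose_loss_with_grad(
    p_true: np.ndarray, p_pred: np.ndarray, weights: LossWeights = LossWeights()
):
    """Pose loss on flattened 18-vectors and its gradient w.r.t. ``p_pred``.

    The rotation blocks of ``p_pred`` are Gram-Schmidt decoded before the
    geodesic term, exactly as at inference time, and the gradient flows
    back through the decoding.
    """
    p_true = np.asarray(p_true, dtype=float).reshape(18)
    p_pred = np.asarray(p_pred, dtype=float).reshape(18)
    grad = np.zeros(18)
    w = np.array([weights.in_plane, weights.in_plane, weights.out_of_plane])
    loss = 0.0
    for t_slice, r_slice in ((slice(0, 3), slice(3, 9)), (slice(9, 12), slice(12, 18))):
        delta = p_pred[t_slice] - p_true[t_slice]
        loss += float(np.sum(w * np.abs(delta)))
        grad[t_slice] = w * np.sign(delta)
        rot_true, _ = _decode_6d_forward(p_true[r_slice])
        rot_pred, cache = _decode_6d_forward(p_pred[r_slice])
        rot_term, g_rot = _geodesic_with_grad(rot_true, rot_pred)
        loss += rot_term
        grad[r_slice] = _decode_6d_backward(cache, g_rot)
    return loss, grad


# ---------------------------------------------------------------------------
# Lovasz hinge


def _jaccard_grad(gt_sorted: np.ndarray) -> np.ndarray:
    """Vector of increments of the Jaccard loss over growing prefix sets of
    the (descending-error-sorted) pixels; the Lovasz-extension weights."""
    gt_sum = gt_sorted.sum()
    intersection = gt_sum - np.cumsum(gt_sorted)
    union = gt_sum + np.cumsum(1.0 - gt_sorted)
    jaccard = 1.0 - intersection / union
    out = jaccard.copy()
    out[1:] = jaccard[1:] - jaccard[:-1]
    return out


def lovasz_hinge_with_grad(logits: np.ndarray, truth: "ShadowImage | np.ndarray"):
    """Lovasz hinge loss and its gradient with respect to the logits.

    Per-pixel hinge errors ``max(0, 1 - sign(t) * logit)`` (truth mapped to
    +-1) are sorted descending and accumulated against the Jaccard-gradient
    weights of the sorted ground truth -- a convex surrogate whose value at
    large-margin predictions equals 1 minus the Jaccard index of the
    thresholded mask.  An empty-foreground truth makes the Jaccard weights
    degenerate; the loss then falls back to the mean hinge error.
    """
    truth_px = truth.pixels if isinstance(truth, ShadowImage) else np.asarray(truth)
    logits = np.asarray(logits, dtype=float)
    if logits.shape != truth_px.shape:
        raise ValueError(f"shape mismatch: logits {logits.shape} vs truth {truth_px.shape}")
    gt = truth_px.reshape(-1).astype(float)
    lg = logits.reshape(-1)
    signs = 2.0 * gt - 1.0
    errors = 1.0 - lg * signs
    hinge = np.maximum(errors, 0.0)
    if gt.sum() == 0:
        loss = float(hinge.mean())
        grad = np.where(errors > 0, -signs / gt.size, 0.0)
        return loss, grad.reshape(logits.shape)
    order = np.argsort(-errors, kind="stable")
    weights_sorted = _jaccard_grad(gt[order])
    loss = float(hinge[order] @ weights_sorted)
    grad = np.zeros_like(lg)
    active = errors[order] > 0
    grad[order] = np.where(active, -signs[order] * weights_sorted, 0.0)
    return loss, grad.reshape(logits.shape)


def lovasz_hinge(logits: np.ndarray, truth: "ShadowImage | np.ndarray") -> float:
    return lovasz_hinge_with_grad(logits, truth)[0]


def total_loss(
    jp_true: JointPose,
    jp_pred: JointPose,
    s_true: ShadowImage,
    s_pred_logits: np.ndarray,
    weights: LossWeights = LossWeights(),
) -> float:
    """Total two-stage objective: ``w_seg * L_seg + L_pose``."""
    return float(
        weights.segmentation_w * lovasz_hinge(s_pred_logits, s_true)
        + pose_loss(jp_true, jp_pred, weights)
    )


def pose_loss_flat(p_true: np.ndarray, p_pred: np.ndarray, weights: LossWeights = LossWeights()) -> float:
    """Pose loss evaluated directly on flattened 18-vectors."""
    return pose_loss_with_grad(p_true, p_pred, weights)[0]
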
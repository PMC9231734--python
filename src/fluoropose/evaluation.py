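"""Pose-error metrics, percentile summaries, and a classical
silhouette-refinement oracle.

Errors follow the reporting conventions of single-plane fluoroscopic
registration: the in-plane translation error is the Euclidean norm of the
(x, y) residual (per-axis columns are also emitted), the out-of-plane
error is the absolute depth residual, and rotation errors are per-axis
absolute Euler-angle differences in degrees under the package's intrinsic
x-y-z convention, wrapped to [0, 180].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .geometry import (
    CameraModel,
    JointPose,
    RigidPose,
    euler_from_matrix,
    matrix_from_euler,
)
from .rendering import ShadowImage, render_joint_shadow

__all__ = [
    "pose_errors",
    "percentile_curve",
    "jaccard",
    "PoseErrorReport",
    "build_report",
    "RefineOptions",
    "refine_pose_oracle",
    "pixel_equivalent_mm",
]

_DEFAULT_PERCENTILES = (10, 25, 50, 75, 90, 95)


def pixel_equivalent_mm(cam: CameraModel, depth_mm: float) -> float:
    """Millimetres of in-plane object motion per image pixel at a depth."""
    return depth_mm * cam.pixel_pitch / cam.focal_distance


def _component_errors(true: RigidPose, pred: RigidPose, prefix: str) -> dict[str, float]:
    delta = pred.translation - true.translation
    # per-axis angles of the relative rotation: well conditioned at every
    # orientation (differencing absolute Euler angles blows up near the
    # gimbal lock of the lateral view), and identical to the naive
    # difference for small errors away from the singularity
    rel = pred.rotation @ true.rotation.T
    ang = np.abs(np.rad2deg(euler_from_matrix(rel))) % 360.0
    ang = np.minimum(ang, 360.0 - ang)
    out = {
        f"{prefix}_inplane_mm": float(np.hypot(delta[0], delta[1])),
        f"{prefix}_dx_mm": float(abs(delta[0])),
        f"{prefix}_dy_mm": float(abs(delta[1])),
        f"{prefix}_outofplane_mm": float(abs(delta[2])),
    }
    for axis, err in zip("xyz", ang):
        out[f"{prefix}_rot_{axis}_deg"] = float(err)
    return out


def pose_errors(true: JointPose, pred: JointPose) -> dict[str, float]:
    """Per-sample error row for both components."""
    row = _component_errors(true.femur, pred.femur, "femur")
    row.update(_component_errors(true.tibia, pred.tibia, "tibia"))
    return row


def percentile_curve(errors, percentiles) -> np.ndarray:
    """Empirical quantiles with linear interpolation and inclusive
    endpoints (p0 = min, p100 = max); monotone in the percentile."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("cannot take percentiles of an empty error list")
    return np.percentile(errors, np.asarray(percentiles, dtype=float))


def jaccard(a: ShadowImage | np.ndarray, b: ShadowImage | np.ndarray) -> float:
    """Intersection over union of two binary masks; 1.0 when both empty."""
    pa = a.pixels if isinstance(a, ShadowImage) else np.asarray(a)
    pb = b.pixels if isinstance(b, ShadowImage) else np.asarray(b)
    if pa.shape != pb.shape:
        raise ValueError(f"shape mismatch: {pa.shape} vs {pb.shape}")
    pa = pa.astype(bool)
    pb = pb.astype(bool)
    union = np.logical_or(pa, pb).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(pa, pb).sum() / union)


@dataclass(frozen=True)
class PoseErrorReport:
    """Per-sample error rows plus a percentile summary per metric.

    Summaries pool femur and tibia and also keep per-component rows, since
    either convention appears in the literature.
    """

    rows: pd.DataFrame
    summary: pd.DataFrame

    def to_csv(self, rows_path, summary_path) -> None:
        self.rows.to_csv(rows_path, index=False)
        self.summary.to_csv(summary_path)

    def summary_dict(self) -> dict:
        return {
            metric: {str(p): float(v) for p, v in row.items()}
            for metric, row in self.summary.iterrows()
        }


def build_report(
    records: list[tuple[str, str, JointPose, JointPose]],
    percentiles=_DEFAULT_PERCENTILES,
) -> PoseErrorReport:
    """Assemble a report from (sample_id, combo_id, true, predicted) tuples."""
    if not records:
        raise ValueError("no records to report on")
    rows = []
    for sample_id, combo_id, true, pred in records:
        row = {"sample_id": sample_id, "combo_id": combo_id}
        row.update(pose_errors(true, pred))
        rows.append(row)
    frame = pd.DataFrame(rows)
    metric_cols = [c for c in frame.columns if c not in ("sample_id", "combo_id")]
    summary_rows = {}
    for col in metric_cols:
        summary_rows[col] = percentile_curve(frame[col].to_numpy(), percentiles)
    # pooled femur+tibia summaries per metric kind
    for kind in ("inplane_mm", "outofplane_mm", "rot_x_deg", "rot_y_deg", "rot_z_deg"):
        pooled = np.concatenate([frame[f"femur_{kind}"], frame[f"tibia_{kind}"]])
        summary_rows[f"pooled_{kind}"] = percentile_curve(pooled, percentiles)
    summary = pd.DataFrame(summary_rows, index=[f"p{p}" for p in percentiles]).T
    return PoseErrorReport(rows=frame, summary=summary)


# ---------------------------------------------------------------------------
# classical refinement oracle


@dataclass(frozen=True)
class RefineOptions:
    """Budget for the derivative-free silhouette matcher: total objective
    evaluations, random restarts around the best-so-far, and the scale of
    the restart perturbations."""

    max_evaluations: int = 2000
    restarts: int = 3
    seed: int = 0
    translation_step_mm: float = 2.0
    rotation_step_deg: float = 1.5


def _pose_to_vector(jp: JointPose) -> np.ndarray:
    return np.concatenate(
        [
            jp.femur.translation,
            euler_from_matrix(jp.femur.rotation),
            jp.tibia.translation,
            euler_from_matrix(jp.tibia.rotation),
        ]
    )


def _vector_to_pose(v: np.ndarray) -> JointPose:
    return JointPose(
        femur=RigidPose(rotation=matrix_from_euler(v[3:6]), translation=v[0:3]),
        tibia=RigidPose(rotation=matrix_from_euler(v[9:12]), translation=v[6:9]),
    )


def refine_pose_oracle(
    target_shadow: ShadowImage,
    combo,
    cam: CameraModel,
    init: JointPose,
    opts: RefineOptions = RefineOptions(),
) -> JointPose:
    """Maximise silhouette overlap (Jaccard) over the 12 pose degrees of
    freedom with Nelder-Mead, restarting from seeded perturbations of the
    best pose found.  The returned pose never has lower overlap than the
    initialisation.  Deterministic for a fixed ``opts.seed``.

    Silhouette matching cannot constrain the rotation of rotationally
    symmetric geometry, and depth only weakly; this is a refinement
    oracle, to be started near the truth.
    """
    rng = np.random.default_rng(opts.seed)
    target = target_shadow.pixels

    def objective(v: np.ndarray) -> float:
        try:
            shadow = render_joint_shadow(combo, _vector_to_pose(v), cam)
        except Exception:
            return 2.0  # unrenderable candidate: worse than any real overlap
        return 1.0 - jaccard(shadow, target)

    x_best = _pose_to_vector(init)
    f_best = objective(x_best)
    if f_best >= 2.0:
        raise ValueError("initial pose is not renderable")
    budget = max(opts.max_evaluations // max(opts.restarts, 1), 10)
    scale = np.concatenate(
        [
            np.full(3, opts.translation_step_mm),
            np.full(3, np.deg2rad(opts.rotation_step_deg)),
        ]
        * 2
    )
    # depth is nearly unobservable from silhouette scale at these distances;
    # give the simplex a larger step there so it can still move if useful
    scale[[2, 8]] *= 4.0
    x_start = x_best
    for restart in range(max(opts.restarts, 1)):
        result = minimize(
            objective,
            x_start,
            method="Nelder-Mead",
            options={
                "maxfev": budget,
                "xatol": 1e-4,
                "fatol": 1e-6,
                "initial_simplex": _initial_simplex(x_start, scale),
            },
        )
        if result.fun < f_best:
            f_best = float(result.fun)
            x_best = np.asarray(result.x)
        x_start = x_best + rng.normal(0.0, 0.3, 12) * scale
    refined = _vector_to_pose(x_best)
    if objective(x_best) <= objective(_pose_to_vector(init)):
        return refined
    return init  # pragma: no cover - guarded by f_best bookkeeping


def _initial_simplex(x0: np.ndarray, scale: np.ndarray) -> np.ndarray:
    simplex = np.tile(x0, (x0.size + 1, 1))
    for i in range(x0.size):
        simplex[i + 1, i] += scale[i]
    return simplex
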
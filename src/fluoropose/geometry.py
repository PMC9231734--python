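"""Rigid-body poses, rotation encodings, and the fluoroscope camera model.

Conventions
-----------
All lengths are millimetres.  The camera frame is right-handed with ``x``
to the right and ``y`` down in the image, and ``z`` along the optical axis
toward the image intensifier; visible objects have ``z > 0``.  Pixel
``(0, 0)`` is at the top-left of the image and pixel centres sit at
half-integer coordinates.

Rotations are represented three ways:

* a 3x3 orthonormal matrix (body -> camera), the canonical form;
* the continuous 6D encoding used as a regression target -- the first two
  columns of the matrix, decoded back to SO(3) by Gram-Schmidt;
* Euler angles, for human-readable error reporting only.  The default
  convention is intrinsic x-y-z (flexion-like, abduction-like,
  rotation-like), configurable per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation as _ScipyRotation

__all__ = [
    "RigidPose",
    "JointPose",
    "CameraModel",
    "InvalidRotationError",
    "DegenerateEncodingError",
    "BehindCameraError",
    "encode_rotation_6d",
    "decode_rotation_6d",
    "geodesic_distance",
    "matrix_from_euler",
    "euler_from_matrix",
    "flatten_pose",
    "unflatten_pose",
    "standardize_pose",
    "random_rotation",
    "DEFAULT_EULER_CONVENTION",
]

#: Intrinsic rotations about x, then y, then z (scipy upper-case convention).
DEFAULT_EULER_CONVENTION = "XYZ"

_ORTHONORMALITY_TOL = 1e-9
#: slack allowed on the arccos argument before it is treated as a real error
_ACOS_CLAMP_TOL = 1e-7


class InvalidRotationError(ValueError):
    """A matrix fails the orthonormality / determinant checks for SO(3)."""


class DegenerateEncodingError(ValueError):
    """A 6D rotation encoding whose two 3-vectors are zero or parallel."""


class BehindCameraError(ValueError):
    """A pose or vertex lies at or behind the x-ray source plane."""


def _check_rotation(rotation: np.ndarray, tol: float = _ORTHONORMALITY_TOL) -> np.ndarray:
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise InvalidRotationError(f"rotation must be 3x3, got {rotation.shape}")
    if not np.all(np.isfinite(rotation)):
        raise InvalidRotationError("rotation contains non-finite entries")
    err = np.abs(rotation.T @ rotation - np.eye(3)).max()
    if err > tol:
        raise InvalidRotationError(f"matrix is not orthonormal (max deviation {err:.3g})")
    det = np.linalg.det(rotation)
    if abs(det - 1.0) > tol:
        raise InvalidRotationError(f"determinant is {det:.12f}, expected +1")
    return rotation


@dataclass(frozen=True)
class RigidPose:
    """Pose of one implant component: body-frame -> camera-frame transform."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rotation = _check_rotation(self.rotation)
        translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(translation)):
            raise ValueError("translation contains non-finite entries")
        object.__setattr__(self, "rotation", rotation)
        object.__setattr__(self, "translation", translation)

    def transform(self, points: np.ndarray) -> np.ndarray:
        """Map body-frame points (N, 3) into the camera frame."""
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def almost_equals(self, other: "RigidPose", atol: float = 1e-9) -> bool:
        return (
            geodesic_distance(self.rotation, other.rotation) <= atol
            and np.allclose(self.translation, other.translation, atol=atol)
        )


@dataclass(frozen=True)
class JointPose:
    """Femoral and tibial component poses; flattens to the 18-vector target."""

    femur: RigidPose
    tibia: RigidPose

    def almost_equals(self, other: "JointPose", atol: float = 1e-9) -> bool:
        return self.femur.almost_equals(other.femur, atol) and self.tibia.almost_equals(
            other.tibia, atol
        )


@dataclass(frozen=True)
class CameraModel:
    """Pinhole model of the standardised single-plane fluoroscope.

    ``focal_distance`` is the source-to-intensifier distance in mm,
    ``pixel_pitch`` the intensifier pixel size in mm/px, and
    ``principal_point`` the optical-axis piercing point in pixel units.
    """

    focal_distance: float = 970.0
    image_size: int = 512
    pixel_pitch: float = 300.0 / 512.0
    principal_point: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.focal_distance <= 0:
            raise ValueError("focal_distance must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.image_size < 2:
            raise ValueError("image_size must be at least 2 pixels")
        if self.principal_point is None:
            centre = self.image_size / 2.0
            object.__setattr__(self, "principal_point", (centre, centre))
        else:
            pp = tuple(float(v) for v in self.principal_point)
            if len(pp) != 2:
                raise ValueError("principal_point must have two components")
            object.__setattr__(self, "principal_point", pp)

    @classmethod
    def standard(cls, image_size: int = 512) -> "CameraModel":
        """The standardised acquisition geometry: 0.97 m focal distance and a
        0.3 mm pixel at 1000 px, rescaled to the working resolution."""
        return cls(
            focal_distance=970.0,
            image_size=image_size,
            pixel_pitch=300.0 / image_size,
        )

    @property
    def field_of_view_mm(self) -> float:
        return self.image_size * self.pixel_pitch


def encode_rotation_6d(rotation: np.ndarray) -> np.ndarray:
    """First two columns of a rotation matrix, concatenated column-major.

    This 6-vector is the continuous rotation representation used as the
    regression target; unlike Euler angles or quaternions it has no
    discontinuities over SO(3).
    """
    rotation = _check_rotation(rotation)
    return np.concatenate([rotation[:, 0], rotation[:, 1]])


def decode_rotation_6d(values: np.ndarray) -> np.ndarray:
    """Gram-Schmidt decoding of a 6-vector to a valid rotation matrix.

    The first 3-vector is normalised, the second orthogonalised against it
    and normalised, and the third column is their cross product.  Any
    non-degenerate input decodes to a proper rotation, which is what makes
    the encoding safe to perturb with additive noise.
    """
    values = np.asarray(values, dtype=float).reshape(6)
    a1, a2 = values[:3], values[3:]
    n1 = np.linalg.norm(a1)
    if n1 < 1e-12:
        raise DegenerateEncodingError("first 6D vector is (numerically) zero")
    b1 = a1 / n1
    u2 = a2 - (b1 @ a2) * b1
    n2 = np.linalg.norm(u2)
    if n2 < 1e-12:
        raise DegenerateEncodingError("6D vectors are (numerically) parallel")
    b2 = u2 / n2
    b3 = np.cross(b1, b2)
    return np.column_stack([b1, b2, b3])


def geodesic_distance(rot_a: np.ndarray, rot_b: np.ndarray) -> float:
    """Angle (radians, in [0, pi]) of the relative rotation between two
    orientations: ``|arccos((tr(Ra Rb^T) - 1) / 2)|``.

    The arccos argument is clamped when it exceeds [-1, 1] by floating-point
    drift; a violation beyond the clamping tolerance raises instead.
    """
    rot_a = _check_rotation(rot_a)
    rot_b = _check_rotation(rot_b)
    rel = rot_a @ rot_b.T
    cos_angle = (np.trace(rel) - 1.0) / 2.0
    if abs(cos_angle) > 1.0 + _ACOS_CLAMP_TOL:
        raise InvalidRotationError(f"trace out of range (cos = {cos_angle!r})")
    # |sin(angle)| from the skew-symmetric part: numerically exact near 0
    # and pi, where arccos of the clamped trace loses ~8 digits
    skew = 0.5 * np.array(
        [rel[2, 1] - rel[1, 2], rel[0, 2] - rel[2, 0], rel[1, 0] - rel[0, 1]]
    )
    return float(abs(np.arctan2(np.linalg.norm(skew), cos_angle)))


def matrix_from_euler(
    angles: np.ndarray, convention: str = DEFAULT_EULER_CONVENTION
) -> np.ndarray:
    """Rotation matrix from Euler angles in radians."""
    angles = np.asarray(angles, dtype=float).reshape(3)
    return _ScipyRotation.from_euler(convention, angles).as_matrix()


def euler_from_matrix(
    rotation: np.ndarray, convention: str = DEFAULT_EULER_CONVENTION
) -> np.ndarray:
    """Euler angles in (-pi, pi] for a rotation matrix.

    At gimbal lock the decomposition is not unique; the canonical branch
    (third angle zero for intrinsic conventions) is returned and always
    re-encodes to the same matrix.
    """
    rotation = _check_rotation(rotation)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns at gimbal lock; branch is canonical
        return _ScipyRotation.from_matrix(rotation).as_euler(convention)


def flatten_pose(joint_pose: JointPose) -> np.ndarray:
    """Flatten to the 18-vector regression target.

    Ordering: femur translation (3), femur rotation-6D (6), tibia
    translation (3), tibia rotation-6D (6).
    """
    return np.concatenate(
        [
            joint_pose.femur.translation,
            encode_rotation_6d(joint_pose.femur.rotation),
            joint_pose.tibia.translation,
            encode_rotation_6d(joint_pose.tibia.rotation),
        ]
    )


def unflatten_pose(values: np.ndarray) -> JointPose:
    """Inverse of :func:`flatten_pose`; rotation blocks are Gram-Schmidt
    decoded, so noisy 18-vectors still yield valid poses."""
    values = np.asarray(values, dtype=float).reshape(-1)
    if values.shape != (18,):
        raise ValueError(f"pose vector must have length 18, got {values.shape[0]}")
    femur = RigidPose(rotation=decode_rotation_6d(values[3:9]), translation=values[0:3])
    tibia = RigidPose(rotation=decode_rotation_6d(values[12:18]), translation=values[9:12])
    return JointPose(femur=femur, tibia=tibia)


def standardize_pose(
    pose: RigidPose, native: CameraModel, standard: CameraModel
) -> RigidPose:
    """Re-express a pose annotated under a native acquisition geometry so
    that its projection under the standard camera matches, to first order
    at the object centre, the native projection.

    Depth is rescaled to preserve apparent (pixel) magnification, and the
    in-plane translation is shifted so the projected object centre lands on
    the same pixel despite the principal-point and focal changes.
    """
    x, y, z = pose.translation
    if z <= 0:
        raise BehindCameraError(f"object depth must be positive, got z = {z:.3f} mm")
    # preserve magnification f / (z * pitch)
    z_new = z * (standard.focal_distance * native.pixel_pitch) / (
        native.focal_distance * standard.pixel_pitch
    )
    u = native.focal_distance * x / (z * native.pixel_pitch) + native.principal_point[0]
    v = native.focal_distance * y / (z * native.pixel_pitch) + native.principal_point[1]
    x_new = (u - standard.principal_point[0]) * z_new * standard.pixel_pitch / standard.focal_distance
    y_new = (v - standard.principal_point[1]) * z_new * standard.pixel_pitch / standard.focal_distance
    return replace(pose, translation=np.array([x_new, y_new, z_new]))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (Haar measure on SO(3))."""
    return _ScipyRotation.random(rng=rng).as_matrix()
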
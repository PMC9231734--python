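"""Binary silhouette ("shadow") rendering of posed triangle meshes.

Knee implants are nearly radio-opaque, so their fluoroscopic appearance is
well approximated by the binary projection footprint of the component
geometry.  This module rasterises that footprint under the pinhole camera:
a pixel is foreground iff its centre lies inside the perspective projection
of at least one mesh triangle.  Rasterisation is exact point-in-triangle
testing with the top-left edge rule -- no anti-aliasing, matching the
binarised segmentation targets used for training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .geometry import BehindCameraError, CameraModel, JointPose, RigidPose

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import ImplantCombination

__all__ = [
    "TriangleMesh",
    "ShadowImage",
    "EmptyGeometryError",
    "project_vertices",
    "render_shadow",
    "render_joint_shadow",
]

#: minimum depth (mm) in front of the source for a projectable vertex
_MIN_DEPTH_MM = 1.0


class EmptyGeometryError(ValueError):
    """A mesh with no faces (or no vertices) was passed to the renderer."""


@dataclass(frozen=True)
class TriangleMesh:
    """Triangle surface in the implant body frame, coordinates in mm."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if faces.shape[0] < 1:
            raise EmptyGeometryError("mesh has no faces")
        if not np.all(np.isfinite(vertices)):
            raise ValueError("mesh vertices contain non-finite coordinates")
        if faces.min() < 0 or faces.max() >= vertices.shape[0]:
            raise ValueError("face indices out of range")
        object.__setattr__(self, "vertices", vertices)
        object.__setattr__(self, "faces", faces)

    @classmethod
    def from_trimesh(cls, mesh) -> "TriangleMesh":
        return cls(vertices=np.asarray(mesh.vertices), faces=np.asarray(mesh.faces))

    def scaled(self, factor: float) -> "TriangleMesh":
        return TriangleMesh(vertices=self.vertices * float(factor), faces=self.faces)

    @property
    def bounding_box_diagonal(self) -> float:
        extent = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return float(np.linalg.norm(extent))


@dataclass(frozen=True)
class ShadowImage:
    """Binary silhouette raster tied to the camera that produced it."""

    pixels: np.ndarray
    camera: CameraModel

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels)
        size = self.camera.image_size
        if pixels.shape != (size, size):
            raise ValueError(
                f"shadow shape {pixels.shape} does not match camera size {size}"
            )
        unique = np.unique(pixels)
        if not np.all(np.isin(unique, (0, 1))):
            raise ValueError("shadow pixels must be strictly binary")
        object.__setattr__(self, "pixels", pixels.astype(np.uint8))

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    def union(self, other: "ShadowImage") -> "ShadowImage":
        if other.pixels.shape != self.pixels.shape:
            raise ValueError("shadow shapes differ")
        return ShadowImage(pixels=np.maximum(self.pixels, other.pixels), camera=self.camera)


def project_vertices(
    mesh: TriangleMesh, pose: RigidPose, cam: CameraModel
) -> np.ndarray:
    """Perspective-project mesh vertices to pixel coordinates (N, 2).

    ``u = f*x / (z*pitch) + cx`` and likewise for ``v``; all transformed
    vertices must lie at least 1 mm in front of the source.
    """
    pts = pose.transform(mesh.vertices)
    z = pts[:, 2]
    if np.any(z < _MIN_DEPTH_MM):
        raise BehindCameraError(
            f"{int(np.sum(z < _MIN_DEPTH_MM))} vertices at or behind the camera plane"
        )
    scale = cam.focal_distance / (z * cam.pixel_pitch)
    u = pts[:, 0] * scale + cam.principal_point[0]
    v = pts[:, 1] * scale + cam.principal_point[1]
    return np.column_stack([u, v])


try:  # jitted kernel; the pure-NumPy path below is the fallback
    import numba as _numba

    @_numba.njit(cache=False)
    def _raster_kernel(tri: np.ndarray, size: int, out: np.ndarray) -> None:  # pragma: no cover
        for t in range(tri.shape[0]):
            ax, ay = tri[t, 0, 0], tri[t, 0, 1]
            bx, by = tri[t, 1, 0], tri[t, 1, 1]
            cx, cy = tri[t, 2, 0], tri[t, 2, 1]
            area2 = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
            if area2 == 0.0:
                continue
            if area2 < 0.0:
                bx, by, cx, cy = cx, cy, bx, by
            lox = min(ax, min(bx, cx))
            hix = max(ax, max(bx, cx))
            loy = min(ay, min(by, cy))
            hiy = max(ay, max(by, cy))
            x0 = max(int(np.floor(lox - 0.5)), 0)
            x1 = min(int(np.ceil(hix + 0.5)), size - 1)
            y0 = max(int(np.floor(loy - 0.5)), 0)
            y1 = min(int(np.ceil(hiy + 0.5)), size - 1)
            for py in range(y0, y1 + 1):
                yc = py + 0.5
                for px in range(x0, x1 + 1):
                    xc = px + 0.5
                    ok = True
                    for e in range(3):
                        if e == 0:
                            p0x, p0y, ex, ey = ax, ay, bx - ax, by - ay
                        elif e == 1:
                            p0x, p0y, ex, ey = bx, by, cx - bx, cy - by
                        else:
                            p0x, p0y, ex, ey = cx, cy, ax - cx, ay - cy
                        w = ex * (yc - p0y) - ey * (xc - p0x)
                        if w < 0.0 or (w == 0.0 and not ((ey == 0.0 and ex > 0.0) or ey < 0.0)):
                            ok = False
                            break
                    if ok:
                        out[py, px] = 1

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _rasterize_triangles(uv: np.ndarray, faces: np.ndarray, size: int) -> np.ndarray:
    """Fill pixels whose centres (half-integer coords) fall inside any
    projected triangle.  Pixels exactly on an edge follow the top-left rule
    so shared edges are covered exactly once."""
    out = np.zeros((size, size), dtype=np.uint8)
    tri = np.ascontiguousarray(uv[faces], dtype=np.float64)  # (M, 3, 2)
    if _HAVE_NUMBA:
        _raster_kernel(tri, size, out)
        return out
    # consistent counter-clockwise winding in the y-down pixel frame
    area2 = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    flip = area2 < 0
    tri[flip] = tri[flip][:, ::-1]
    area2 = np.abs(area2)

    lo = np.maximum(np.floor(tri.min(axis=1) - 0.5).astype(int), 0)
    hi = np.minimum(np.ceil(tri.max(axis=1) + 0.5).astype(int), size - 1)

    for t in range(tri.shape[0]):
        if area2[t] == 0.0:
            continue  # degenerate sliver: zero coverage at pixel centres
        (x0, y0), (x1, y1) = lo[t], hi[t]
        if x1 < x0 or y1 < y0:
            continue
        xs = np.arange(x0, x1 + 1) + 0.5
        ys = np.arange(y0, y1 + 1) + 0.5
        px, py = np.meshgrid(xs, ys)
        a, b, c = tri[t]
        inside = np.ones(px.shape, dtype=bool)
        for p, q in ((a, b), (b, c), (c, a)):
            ex, ey = q[0] - p[0], q[1] - p[1]
            w = ex * (py - p[1]) - ey * (px - p[0])
            # top-left rule in a y-down frame: top edge runs +x, left edge runs -y
            top_left = (ey == 0 and ex > 0) or ey < 0
            inside &= (w > 0) | ((w == 0) & top_left)
            if not inside.any():
                break
        else:
            out[y0 : y1 + 1, x0 : x1 + 1] |= inside
    return out


def render_shadow(mesh: TriangleMesh, pose: RigidPose, cam: CameraModel) -> ShadowImage:
    """Render the binary silhouette of one posed component.

    Deterministic for fixed inputs; a mesh entirely outside the field of
    view yields an all-zero image.
    """
    uv = project_vertices(mesh, pose, cam)
    pixels = _rasterize_triangles(uv, mesh.faces, cam.image_size)
    return ShadowImage(pixels=pixels, camera=cam)


def render_joint_shadow(
    combo: "ImplantCombination", joint_pose: JointPose, cam: CameraModel
) -> ShadowImage:
    """Union of the femoral and tibial component silhouettes.

    X-ray attenuation is cumulative, so after binarisation the two-component
    shadow is the pixel-wise union; occlusion ordering is irrelevant.
    """
    femur = render_shadow(combo.femur_mesh, joint_pose.femur, cam)
    tibia = render_shadow(combo.tibia_mesh, joint_pose.tibia, cam)
    return femur.union(tibia)
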
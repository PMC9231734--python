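"""File formats: meshes (STL/PLY/OBJ via trimesh), images (PNG), pose
annotations (CSV with a JSON manifest sidecar), and dataset layout.

Shadows are stored as 8-bit PNG (0/255); greyscale x-ray-like images as
16-bit PNG to preserve the synthetic dynamic range.  Pose tables store
rotations in the 6D encoding, which is lossless with respect to the
training representation; Euler angles appear only in evaluation outputs.
Every manifest records the coordinate conventions (camera frame, mm,
pixel origin) to prevent silent mismatches between producers and
consumers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import trimesh

from .geometry import CameraModel, JointPose, flatten_pose, unflatten_pose
from .rendering import EmptyGeometryError, ShadowImage, TriangleMesh
from .synthetic import (
    ImplantCombination,
    NormalisationConstants,
    NuisanceParams,
    Sample,
    XrayImage,
)

__all__ = [
    "AnnotationRecord",
    "read_mesh",
    "write_mesh",
    "read_annotations",
    "write_annotations",
    "downscale_image",
    "write_shadow_png",
    "read_shadow_png",
    "write_xray_png",
    "read_xray_png",
    "write_dataset",
    "load_dataset",
]

_POSE_COLUMNS = [f"p{i:02d}" for i in range(18)]
_CONVENTIONS = {
    "frame": "camera (x right, y down, z toward intensifier)",
    "units": "mm",
    "pixel_origin": "top-left, pixel centres at half-integers",
    "pose_ordering": "femur t(3), femur 6D(6), tibia t(3), tibia 6D(6)",
}


@dataclass(frozen=True)
class AnnotationRecord:
    """One pose annotation row; the pose block is the flattened 18-vector."""

    sample_id: str
    combo_id: str
    image_path: str
    split: str
    pose: np.ndarray

    def __post_init__(self) -> None:
        pose = np.asarray(self.pose, dtype=float).reshape(-1)
        if pose.shape != (18,):
            raise ValueError(f"pose block must have 18 components, got {pose.shape[0]}")
        unflatten_pose(pose)  # validates decodability
        object.__setattr__(self, "pose", pose)

    @property
    def joint_pose(self) -> JointPose:
        return unflatten_pose(self.pose)


def read_mesh(path) -> TriangleMesh:
    """Load an implant surface (binary/ASCII STL, PLY, or OBJ; mm units),
    welding duplicate vertices."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        mesh = trimesh.load_mesh(path, process=True)
    except Exception as exc:
        raise ValueError(f"could not parse mesh file {path}: {exc}") from exc
    if isinstance(mesh, trimesh.Scene):
        geoms = list(mesh.geometry.values())
        if not geoms:
            raise EmptyGeometryError(f"{path} contains no geometry")
        mesh = trimesh.util.concatenate(geoms)
    if mesh.faces.shape[0] == 0:
        raise EmptyGeometryError(f"{path} contains no faces")
    mesh.merge_vertices()
    return TriangleMesh.from_trimesh(mesh)


def write_mesh(mesh: TriangleMesh, path) -> None:
    trimesh.Trimesh(mesh.vertices, mesh.faces, process=False).export(path)


def write_annotations(records: list[AnnotationRecord], path, camera: CameraModel,
                      extras: dict | None = None) -> None:
    """CSV pose table plus a JSON sidecar with camera parameters and
    dataset-level constants; floats at full precision."""
    path = Path(path)
    rows = []
    for r in records:
        row = {"sample_id": r.sample_id, "combo_id": r.combo_id,
               "image_path": r.image_path, "split": r.split}
        row.update({c: v for c, v in zip(_POSE_COLUMNS, r.pose)})
        rows.append(row)
    columns = ["sample_id", "combo_id", "image_path", "split", *_POSE_COLUMNS]
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "camera": asdict(camera),
        "conventions": _CONVENTIONS,
        **(extras or {}),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_annotations(path) -> tuple[list[AnnotationRecord], CameraModel, dict]:
    """Inverse of :func:`write_annotations`; validates the schema and that
    every pose block decodes."""
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("sample_id", "combo_id", "image_path", "split", *_POSE_COLUMNS)
               if c not in frame.columns]
    if missing:
        raise ValueError(f"annotation table is missing columns: {missing}")
    records = [
        AnnotationRecord(
            sample_id=str(row["sample_id"]),
            combo_id=str(row["combo_id"]),
            image_path=str(row["image_path"]),
            split=str(row["split"]),
            pose=row[_POSE_COLUMNS].to_numpy(dtype=float),
        )
        for _, row in frame.iterrows()
    ]
    sidecar_path = path.with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    cam_kwargs = sidecar.get("camera")
    camera = CameraModel(**{**cam_kwargs, "principal_point": tuple(cam_kwargs["principal_point"])}) \
        if cam_kwargs else CameraModel.standard()
    return records, camera, sidecar


def downscale_image(image: np.ndarray, factor: int) -> np.ndarray:
    """Area-averaging downscale by an integer factor; the output side is
    ``floor(side / factor)`` and the intensity mean over the retained
    region is preserved exactly (up to float rounding)."""
    image = np.asarray(image, dtype=float)
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    h, w = image.shape[:2]
    if factor > min(h, w):
        raise ValueError("factor larger than image side")
    if factor == 1:
        return image.copy()
    h_out, w_out = h // factor, w // factor
    cropped = image[: h_out * factor, : w_out * factor]
    return cropped.reshape(h_out, factor, w_out, factor).mean(axis=(1, 3))


def write_shadow_png(shadow: ShadowImage, path) -> None:
    iio.imwrite(path, (shadow.pixels * 255).astype(np.uint8))


def read_shadow_png(path, camera: CameraModel) -> ShadowImage:
    pixels = np.asarray(iio.imread(path))
    return ShadowImage(pixels=(pixels > 127).astype(np.uint8), camera=camera)


def write_xray_png(image: XrayImage, path) -> None:
    iio.imwrite(path, np.round(image.pixels * 65535.0).astype(np.uint16))


def read_xray_png(path, camera: CameraModel) -> XrayImage:
    pixels = np.asarray(iio.imread(path)).astype(float) / 65535.0
    return XrayImage(pixels=np.clip(pixels, 0.0, 1.0), camera=camera)


# ---------------------------------------------------------------------------
# dataset layout


def write_dataset(out_dir, combos: list[ImplantCombination], samples: list[Sample],
                  camera: CameraModel, norm: NormalisationConstants, seed: int,
                  nuisance_params: NuisanceParams | None = None,
                  sigmas: np.ndarray | None = None,
                  test_combo_ids: list[str] | None = None) -> dict:
    """Write images, shadows, meshes, the pose table, and a JSON manifest;
    returns the manifest dictionary."""
    out_dir = Path(out_dir)
    for sub in ("images", "shadows", "meshes"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)
    test_ids = set(test_combo_ids or [])
    records = []
    for s in samples:
        image_rel = f"images/{s.sample_id}.png"
        shadow_rel = f"shadows/{s.sample_id}.png"
        write_xray_png(s.image, out_dir / image_rel)
        write_shadow_png(s.true_shadow, out_dir / shadow_rel)
        records.append(
            AnnotationRecord(
                sample_id=s.sample_id,
                combo_id=s.combo_id,
                image_path=image_rel,
                split="test" if s.combo_id in test_ids else "train",
                pose=flatten_pose(s.true_pose),
            )
        )
    combo_entries = {}
    for combo in combos:
        femur_rel = f"meshes/{combo.combo_id}_femur.stl"
        tibia_rel = f"meshes/{combo.combo_id}_tibia.stl"
        write_mesh(combo.femur_mesh, out_dir / femur_rel)
        write_mesh(combo.tibia_mesh, out_dir / tibia_rel)
        combo_entries[combo.combo_id] = {"femur": femur_rel, "tibia": tibia_rel}
    manifest = {
        "seed": seed,
        "camera": asdict(camera),
        "conventions": _CONVENTIONS,
        "normalisation": {"mean": norm.mean.tolist(), "std": norm.std.tolist()},
        "nuisance_params": asdict(nuisance_params) if nuisance_params else None,
        "perturbation_sigmas": None if sigmas is None else np.asarray(sigmas).tolist(),
        "test_combo_ids": sorted(test_ids),
        "combos": combo_entries,
        "samples": [
            {"sample_id": r.sample_id, "combo_id": r.combo_id,
             "image": r.image_path, "shadow": f"shadows/{r.sample_id}.png",
             "split": r.split}
            for r in records
        ],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    write_annotations(records, out_dir / "poses.csv", camera,
                      extras={"normalisation": manifest["normalisation"]})
    return manifest


def load_dataset(root) -> tuple[list[ImplantCombination], list[Sample], CameraModel,
                                NormalisationConstants, dict]:
    """Read back a dataset written by :func:`write_dataset`."""
    root = Path(root)
    manifest = json.loads((root / "manifest.json").read_text())
    cam_kwargs = dict(manifest["camera"])
    cam_kwargs["principal_point"] = tuple(cam_kwargs["principal_point"])
    camera = CameraModel(**cam_kwargs)
    norm = NormalisationConstants(
        mean=np.asarray(manifest["normalisation"]["mean"]),
        std=np.asarray(manifest["normalisation"]["std"]),
    )
    combos = [
        ImplantCombination(
            combo_id=cid,
            femur_mesh=read_mesh(root / entry["femur"]),
            tibia_mesh=read_mesh(root / entry["tibia"]),
        )
        for cid, entry in manifest["combos"].items()
    ]
    records, _, _ = read_annotations(root / "poses.csv")
    by_id = {r.sample_id: r for r in records}
    samples = []
    for entry in manifest["samples"]:
        record = by_id[entry["sample_id"]]
        samples.append(
            Sample(
                sample_id=entry["sample_id"],
                combo_id=entry["combo_id"],
                image=read_xray_png(root / entry["image"], camera),
                true_pose=record.joint_pose,
                true_shadow=read_shadow_png(root / entry["shadow"], camera),
            )
        )
    return combos, samples, camera, norm, manifest
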
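"""Synthetic stand-ins for the proprietary fluoroscopy dataset.

Real training material for this problem -- manufacturer implant surface
files and ~10^5 manually annotated x-ray frames -- is not publicly
available.  This module fabricates everything at desk scale:

* toy two-component implant geometries (a two-lobed condylar femoral
  solid and a tibial tray-plus-stem), watertight triangle meshes sized
  like real knee implants (50-90 mm);
* gait-like base kinematics: a near-static tibia and a femoral flexion
  angle following a seeded sinusoid plus drift, depths in the 400-700 mm
  range of a moving fluoroscope;
* Gaussian perturbation of the 18 flattened pose components, mirroring
  how training poses are scattered around activities of daily living;
* CutOut occlusion (default 4 squares of a quarter of the image side,
  probability 0.3) and x-ray-like greyscale synthesis with background
  shading, contrast loss, occluder blobs and pixel noise;
* dataset assembly with leave-combination-out splits and the
  translation-normalisation constants stored in the manifest.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .geometry import (
    CameraModel,
    JointPose,
    RigidPose,
    flatten_pose,
    matrix_from_euler,
    unflatten_pose,
)
from .rendering import ShadowImage, TriangleMesh, render_joint_shadow

logger = logging.getLogger(__name__)

__all__ = [
    "ImplantCombination",
    "XrayImage",
    "Sample",
    "ToyImplantParams",
    "KinematicsParams",
    "NuisanceParams",
    "NormalisationConstants",
    "SilhouetteDataset",
    "generate_toy_implant_pair",
    "sample_base_kinematics",
    "default_perturbation_sigmas",
    "perturb_pose",
    "apply_cutout",
    "synthesize_xray",
    "generate_samples",
    "build_silhouette_dataset",
    "build_dataset",
    "leave_combination_out",
]

#: flattened-vector indices of the six translation components
TRANSLATION_INDICES = np.array([0, 1, 2, 9, 10, 11])
#: minimum/maximum depth (mm) for a pose to count as renderable
_DEPTH_BOUNDS_MM = (150.0, 1800.0)
_MAX_RESAMPLES = 100


@dataclass(frozen=True)
class ImplantCombination:
    """A femoral + tibial component pair; the unit of personalisation."""

    combo_id: str
    femur_mesh: TriangleMesh
    tibia_mesh: TriangleMesh


@dataclass(frozen=True)
class XrayImage:
    """Greyscale x-ray-like raster with values in [0, 1]."""

    pixels: np.ndarray
    camera: CameraModel

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels, dtype=float)
        size = self.camera.image_size
        if pixels.shape != (size, size):
            raise ValueError(f"image shape {pixels.shape} does not match camera size {size}")
        if pixels.min() < 0.0 or pixels.max() > 1.0:
            raise ValueError("x-ray pixel values must lie in [0, 1]")
        object.__setattr__(self, "pixels", pixels)


@dataclass(frozen=True)
class Sample:
    """One annotated frame: image, true pose, and the shadow rendered at
    the true pose (the segmentation target)."""

    sample_id: str
    combo_id: str
    image: XrayImage
    true_pose: JointPose
    true_shadow: ShadowImage


# ---------------------------------------------------------------------------
# toy implant geometry


@dataclass(frozen=True)
class ToyImplantParams:
    """Dimensions (mm) of the toy implant pair; ``size_scale`` scales the
    whole geometry linearly."""

    size_scale: float = 1.0
    condyle_major_radius: float = 21.0
    condyle_tube_radius: float = 8.0
    condyle_spacing: float = 42.0  # centre-to-centre, medial-lateral
    condyle_arc_deg: tuple[float, float] = (-50.0, 130.0)
    bridge_size: tuple[float, float, float] = (42.0, 14.0, 16.0)
    tray_radius: float = 31.0
    tray_aspect: float = 0.7  # anterior-posterior vs medial-lateral half-axis
    tray_thickness: float = 7.0
    stem_radius: float = 6.5
    stem_length: float = 36.0
    stem_offset: tuple[float, float] = (6.0, 10.0)  # (x, z) from tray centre
    keel_size: tuple[float, float, float] = (4.0, 22.0, 26.0)
    keel_angle_deg: float = 25.0
    segments: int = 20

    def __post_init__(self) -> None:
        if self.size_scale <= 0:
            raise ValueError("size_scale must be positive")
        if min(self.condyle_major_radius, self.condyle_tube_radius, self.tray_radius,
               self.tray_thickness, self.stem_radius, self.stem_length) <= 0:
            raise ValueError("all dimensions must be positive")
        if self.segments < 8:
            raise ValueError("need at least 8 segments for a valid solid")


def _partial_torus(major_r: float, tube_r: float, phi0: float, phi1: float,
                   axis_offset: float, n_phi: int, n_theta: int) -> tuple[np.ndarray, np.ndarray]:
    """Watertight torus segment with flat end caps.

    The ring lies in the y-z plane (torus axis along x, the medial-lateral
    direction), offset by ``axis_offset`` along x.
    """
    phis = np.linspace(phi0, phi1, n_phi + 1)
    thetas = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    verts = []
    for phi in phis:
        radial = np.array([0.0, np.cos(phi), np.sin(phi)])
        centre = major_r * radial
        for theta in thetas:
            p = centre + tube_r * (np.cos(theta) * radial + np.sin(theta) * np.array([1.0, 0, 0]))
            verts.append(p + np.array([axis_offset, 0.0, 0.0]))
    verts = np.asarray(verts)
    faces = []
    for i in range(n_phi):
        for j in range(n_theta):
            a = i * n_theta + j
            b = i * n_theta + (j + 1) % n_theta
            c = (i + 1) * n_theta + j
            d = (i + 1) * n_theta + (j + 1) % n_theta
            faces.append((a, b, d))
            faces.append((a, d, c))
    # end caps: triangle fans around the tube-section centres
    for ring, phi in ((0, phis[0]), (n_phi, phis[-1])):
        centre = major_r * np.array([0.0, np.cos(phi), np.sin(phi)]) + np.array([axis_offset, 0.0, 0.0])
        ci = len(verts)
        verts = np.vstack([verts, centre])
        base = ring * n_theta
        for j in range(n_theta):
            faces.append((ci, base + j, base + (j + 1) % n_theta))
    return verts, np.asarray(faces, dtype=np.int64)


def _box(extents: tuple[float, float, float], centre: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    import trimesh

    box = trimesh.creation.box(extents=extents)
    return np.asarray(box.vertices) + centre, np.asarray(box.faces)


def _cylinder(radius: float, height: float, centre: np.ndarray, axis: str, sections: int):
    import trimesh

    cyl = trimesh.creation.cylinder(radius=radius, height=height, sections=sections)
    verts = np.asarray(cyl.vertices)
    if axis == "y":  # trimesh cylinders extrude along z
        verts = verts[:, [0, 2, 1]][:, :]  # swap y and z
    return verts + centre, np.asarray(cyl.faces)


def _concat(parts: list[tuple[np.ndarray, np.ndarray]]) -> TriangleMesh:
    import trimesh

    verts, faces, offset = [], [], 0
    for v, f in parts:
        verts.append(v)
        faces.append(f + offset)
        offset += v.shape[0]
    mesh = trimesh.Trimesh(np.vstack(verts), np.vstack(faces), process=False)
    trimesh.repair.fix_normals(mesh)
    return TriangleMesh.from_trimesh(mesh)


def generate_toy_implant_pair(
    params: ToyImplantParams = ToyImplantParams(), seed: int = 0
) -> ImplantCombination:
    """Deterministic toy femoral + tibial component pair.

    The femoral component is two partial tori (the condylar lobes) bridged
    by a box; the tibial component is a circular tray plate with a stem
    cylinder.  The seed jitters the dimensions by a few percent so that
    distinct combinations have genuinely distinct geometry, emulating the
    different implant models and sizes of a real cohort.
    """
    rng = np.random.default_rng(seed)
    jitter = lambda: 1.0 + rng.uniform(-0.06, 0.06)  # noqa: E731
    s = params.size_scale
    major = params.condyle_major_radius * jitter() * s
    tube = params.condyle_tube_radius * jitter() * s
    spacing = params.condyle_spacing * jitter() * s
    phi0, phi1 = np.deg2rad(params.condyle_arc_deg)
    n = params.segments
    femur = _concat(
        [
            _partial_torus(major, tube, phi0, phi1, -spacing / 2.0, n, n),
            _partial_torus(major, tube, phi0, phi1, +spacing / 2.0, n, n),
            _box(tuple(np.array(params.bridge_size) * s), np.array([0.0, major * 0.5, 0.0])),
        ]
    )
    # the tibial component is deliberately asymmetric (elliptical tray,
    # offset stem, oblique keel fin): like real tibial trays, and necessary
    # for its out-of-plane rotation to be observable in a silhouette at all
    tray_r = params.tray_radius * jitter() * s
    tray_t = params.tray_thickness * s
    stem_len = params.stem_length * jitter() * s
    tray_v, tray_f = _cylinder(tray_r, tray_t, np.array([0.0, tray_t / 2.0, 0.0]), "y", n * 2)
    tray_v = tray_v * np.array([1.0, 1.0, params.tray_aspect])
    ox, oz = np.array(params.stem_offset) * s
    keel_v, keel_f = _box(tuple(np.array(params.keel_size) * s), np.zeros(3))
    ang = np.deg2rad(params.keel_angle_deg)
    rot_y = np.array([[np.cos(ang), 0.0, np.sin(ang)], [0.0, 1.0, 0.0],
                      [-np.sin(ang), 0.0, np.cos(ang)]])
    keel_v = keel_v @ rot_y.T + np.array([ox / 2.0, tray_t + params.keel_size[1] * s / 2.0, oz / 2.0])
    tibia = _concat(
        [
            (tray_v, tray_f),
            _cylinder(
                params.stem_radius * s,
                stem_len,
                np.array([ox, tray_t + stem_len / 2.0, oz]),
                "y",
                n,
            ),
            (keel_v, keel_f),
        ]
    )
    return ImplantCombination(combo_id=f"toy-{seed:04d}", femur_mesh=femur, tibia_mesh=tibia)


# ---------------------------------------------------------------------------
# kinematics


@dataclass(frozen=True)
class KinematicsParams:
    """Gait-like trajectory generator settings.

    The femoral flexion angle follows ``offset + amplitude * sin`` plus a
    slow drift, clipped to the stated bounds; normal walking covers
    roughly 0-60 degrees of knee flexion, which the defaults emulate.
    The flexion axis is the optical axis (the knee is imaged
    medio-laterally), so flexion appears as in-plane silhouette rotation.
    """

    flexion_offset_deg: float = 30.0
    flexion_amplitude_deg: float = 25.0
    flexion_bounds_deg: tuple[float, float] = (0.0, 120.0)
    cycle_frames: float = 50.0
    drift_deg_per_frame: float = 0.05
    depth_range_mm: tuple[float, float] = (400.0, 700.0)
    femur_offset_mm: tuple[float, float] = (0.0, -28.0)
    tibia_offset_mm: tuple[float, float] = (0.0, 14.0)
    sway_amplitude_mm: float = 6.0
    tilt_amplitude_deg: float = 4.0
    #: dataset assembly draws many short trials (each with its own depth,
    #: tilt and phase) rather than one long sequence, like a measurement
    #: campaign of separate activity recordings
    frames_per_sequence: int = 50


def sample_base_kinematics(
    n_frames: int,
    activity_params: KinematicsParams = KinematicsParams(),
    seed: int = 0,
) -> list[JointPose]:
    """Smooth joint-pose trajectory: near-static tibia, sinusoid-plus-drift
    femoral flexion, shared depth within the fluoroscope working range."""
    if n_frames < 1:
        raise ValueError("n_frames must be at least 1")
    p = activity_params
    rng = np.random.default_rng(seed)
    depth = rng.uniform(*p.depth_range_mm)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    amp = p.flexion_amplitude_deg * rng.uniform(0.7, 1.0)
    drift = p.drift_deg_per_frame * rng.uniform(-1.0, 1.0)
    tilt = np.deg2rad(rng.uniform(-p.tilt_amplitude_deg, p.tilt_amplitude_deg, size=3))
    # fixed base orientation: condyle (medial-lateral) axis along the optical
    # axis, i.e. the standard lateral view
    base_fem = matrix_from_euler([0.0, np.pi / 2.0, 0.0]) @ matrix_from_euler(tilt)
    base_tib = matrix_from_euler(np.deg2rad(rng.uniform(-p.tilt_amplitude_deg, p.tilt_amplitude_deg, size=3)))
    sway = rng.uniform(-1.0, 1.0, size=2)

    frames = []
    lo, hi = p.flexion_bounds_deg
    for k in range(n_frames):
        t = 2.0 * np.pi * k / p.cycle_frames + phase
        flexion = np.clip(p.flexion_offset_deg + amp * np.sin(t) + drift * k, lo, hi)
        rot_fem = matrix_from_euler([0.0, 0.0, np.deg2rad(flexion)]) @ base_fem
        sway_xy = p.sway_amplitude_mm * sway * np.sin(t / 2.0)
        fem_t = np.array([p.femur_offset_mm[0] + sway_xy[0], p.femur_offset_mm[1] + sway_xy[1], depth])
        tib_t = np.array([p.tibia_offset_mm[0] + 0.3 * sway_xy[0], p.tibia_offset_mm[1], depth])
        frames.append(
            JointPose(
                femur=RigidPose(rotation=rot_fem, translation=fem_t),
                tibia=RigidPose(rotation=base_tib, translation=tib_t),
            )
        )
    return frames


def _multi_sequence_kinematics(n: int, kinematics: KinematicsParams,
                               rng: np.random.Generator) -> list[JointPose]:
    """Concatenate short independent trials until ``n`` frames are drawn."""
    frames: list[JointPose] = []
    while len(frames) < n:
        take = min(kinematics.frames_per_sequence, n - len(frames))
        frames.extend(
            sample_base_kinematics(take, kinematics, seed=int(rng.integers(2**31)))
        )
    return frames


# ---------------------------------------------------------------------------
# perturbation and image nuisances


def default_perturbation_sigmas() -> np.ndarray:
    """Per-component Gaussian SDs in flatten ordering: 5 mm in-plane,
    15 mm out-of-plane, 0.05 per 6D rotation component (a few degrees)."""
    sigmas = np.empty(18)
    for base in (0, 9):
        sigmas[base : base + 2] = 5.0
        sigmas[base + 2] = 15.0
        sigmas[base + 3 : base + 9] = 0.05
    return sigmas


def perturb_pose(
    joint_pose: JointPose, sigmas: np.ndarray | None = None, seed: int = 0
) -> JointPose:
    """Add independent zero-mean Gaussian noise to the 18 flattened pose
    components; the rotation blocks are re-orthonormalised by the 6D
    decoding, so any draw yields a valid pose.

    Draws that leave either component outside the renderable depth range
    are rejected and resampled (cap 100, then an error is raised).
    """
    sigmas = default_perturbation_sigmas() if sigmas is None else np.asarray(sigmas, dtype=float)
    if np.any(sigmas < 0):
        raise ValueError("sigmas must be non-negative")
    rng = np.random.default_rng(seed)
    flat = flatten_pose(joint_pose)
    lo, hi = _DEPTH_BOUNDS_MM
    for attempt in range(_MAX_RESAMPLES):
        candidate = flat + rng.normal(0.0, 1.0, 18) * sigmas
        if lo <= candidate[2] <= hi and lo <= candidate[11] <= hi:
            if attempt:
                logger.info("perturb_pose resampled %d time(s)", attempt)
            if np.all(sigmas == 0.0):
                return joint_pose
            return unflatten_pose(candidate)
    raise RuntimeError(f"perturb_pose exceeded {_MAX_RESAMPLES} resampling attempts")


def apply_cutout(
    image: XrayImage,
    probability: float = 0.3,
    n_squares: int = 4,
    side_px: int | None = None,
    seed: int = 0,
) -> XrayImage:
    """Occlusion augmentation: with the given probability, zero
    ``n_squares`` axis-aligned squares (default side: a quarter of the
    image, i.e. 128 px at the 512 px working resolution) at uniformly
    random centres, clamped at the borders so each square lies fully
    inside the image."""
    size = image.camera.image_size
    side = size // 4 if side_px is None else int(side_px)
    if side > size:
        raise ValueError("cutout side exceeds image size")
    rng = np.random.default_rng(seed)
    if rng.uniform() >= probability:
        return image
    pixels = image.pixels.copy()
    for _ in range(n_squares):
        y0, x0 = _cutout_corner(rng, size, side)
        pixels[y0 : y0 + side, x0 : x0 + side] = 0.0
    return replace(image, pixels=pixels)


def _cutout_corner(rng: np.random.Generator, size: int, side: int) -> tuple[int, int]:
    cy, cx = rng.uniform(0, size, size=2)
    y0 = int(np.clip(round(cy - side / 2.0), 0, size - side))
    x0 = int(np.clip(round(cx - side / 2.0), 0, size - side))
    return y0, x0


@dataclass(frozen=True)
class NuisanceParams:
    """Image-degradation settings for the x-ray synthesiser.

    With everything zeroed and ``contrast = 1`` the image is exactly
    ``1 - shadow``.  Occluders emulate the contralateral leg passing
    through the beam: grey elliptical blobs that lift the implant region
    toward the occluder grey level, reducing contrast.
    """

    contrast: float = 0.9
    background_amplitude: float = 0.12
    background_cells: int = 6
    n_occluders: int = 1
    occluder_opacity: float = 0.35
    occluder_level: float = 0.55
    occluder_axes_px: tuple[float, float] = (0.35, 0.18)  # fractions of image side
    noise_sigma: float = 0.02

    @classmethod
    def off(cls) -> "NuisanceParams":
        return cls(contrast=1.0, background_amplitude=0.0, n_occluders=0, noise_sigma=0.0)


def _smooth_field(size: int, cells: int, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency random field in [0, 1]: coarse uniform noise upsampled
    with bilinear interpolation."""
    coarse = rng.uniform(0.0, 1.0, (cells, cells))
    xs = np.linspace(0.0, cells - 1.0, size)
    i0 = np.clip(xs.astype(int), 0, cells - 2)
    frac = xs - i0
    rows = coarse[i0] * (1 - frac)[:, None] + coarse[i0 + 1] * frac[:, None]
    cols = rows[:, i0] * (1 - frac)[None, :] + rows[:, i0 + 1] * frac[None, :]
    return cols


def synthesize_xray(
    shadow: ShadowImage, nuisance_params: NuisanceParams = NuisanceParams(), seed: int = 0
) -> XrayImage:
    """Map a binary implant shadow to a greyscale x-ray-like image."""
    p = nuisance_params
    rng = np.random.default_rng(seed)
    size = shadow.camera.image_size
    mask = shadow.pixels.astype(float)
    background = 1.0 - p.background_amplitude * _smooth_field(size, p.background_cells, rng)
    image = background * (1.0 - p.contrast * mask)
    if p.n_occluders > 0 and mask.any():
        ys, xs = np.nonzero(mask)
        yy, xx = np.mgrid[0:size, 0:size]
        for _ in range(p.n_occluders):
            # occluders cross the implant region, like the second leg in gait
            cy = rng.uniform(ys.min(), ys.max() + 1)
            cx = rng.uniform(xs.min(), xs.max() + 1)
            ay = max(p.occluder_axes_px[0] * size, 1.0)
            ax = max(p.occluder_axes_px[1] * size, 1.0)
            blob = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
            image = image + p.occluder_opacity * blob * (p.occluder_level - image)
    if p.noise_sigma > 0:
        image = image + rng.normal(0.0, p.noise_sigma, image.shape)
    return XrayImage(pixels=np.clip(image, 0.0, 1.0), camera=shadow.camera)


# ---------------------------------------------------------------------------
# dataset assembly


@dataclass(frozen=True)
class NormalisationConstants:
    """Per-component z-score constants for the six translation components
    (rotation 6D components are left unnormalised).  Stored in the dataset
    manifest so they travel with every model trained on it."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float).reshape(6)
        std = np.asarray(self.std, dtype=float).reshape(6)
        std = np.maximum(std, 1e-3)  # guard against a degenerate (static) component
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "std", std)

    @classmethod
    def identity(cls) -> "NormalisationConstants":
        return cls(mean=np.zeros(6), std=np.ones(6))

    @classmethod
    def from_flat_poses(cls, flats: np.ndarray) -> "NormalisationConstants":
        flats = np.asarray(flats, dtype=float).reshape(-1, 18)
        t = flats[:, TRANSLATION_INDICES]
        return cls(mean=t.mean(axis=0), std=t.std(axis=0))

    def normalise(self, flat: np.ndarray) -> np.ndarray:
        out = np.array(flat, dtype=float, copy=True)
        out[..., TRANSLATION_INDICES] = (out[..., TRANSLATION_INDICES] - self.mean) / self.std
        return out

    def denormalise(self, flat: np.ndarray) -> np.ndarray:
        out = np.array(flat, dtype=float, copy=True)
        out[..., TRANSLATION_INDICES] = out[..., TRANSLATION_INDICES] * self.std + self.mean
        return out


@dataclass(frozen=True)
class SilhouetteDataset:
    """In-memory training set for the regression stage: rendered binary
    shadows and normalised 18-vector targets."""

    shadows: np.ndarray  # (N, 1, H, W) float
    targets: np.ndarray  # (N, 18), translations normalised
    norm: NormalisationConstants
    camera: CameraModel
    combo_id: str

    def __len__(self) -> int:
        return self.shadows.shape[0]


def generate_samples(
    combo: ImplantCombination,
    n: int,
    cam: CameraModel,
    seed: int = 0,
    kinematics: KinematicsParams = KinematicsParams(),
    sigmas: np.ndarray | None = None,
    nuisance: NuisanceParams = NuisanceParams(),
) -> list[Sample]:
    """Fabricate ``n`` annotated frames for one combination: perturbed
    gait-like poses, their rendered shadows, and degraded x-ray images."""
    rng = np.random.default_rng(seed)
    base = _multi_sequence_kinematics(n, kinematics, rng)
    samples = []
    for k, base_pose in enumerate(base):
        pose = perturb_pose(base_pose, sigmas, seed=int(rng.integers(2**31)))
        shadow = render_joint_shadow(combo, pose, cam)
        image = synthesize_xray(shadow, nuisance, seed=int(rng.integers(2**31)))
        samples.append(
            Sample(
                sample_id=f"{combo.combo_id}-{k:05d}",
                combo_id=combo.combo_id,
                image=image,
                true_pose=pose,
                true_shadow=shadow,
            )
        )
    return samples


def build_silhouette_dataset(
    combo: ImplantCombination,
    n: int,
    cam: CameraModel,
    seed: int = 0,
    kinematics: KinematicsParams = KinematicsParams(),
    sigmas: np.ndarray | None = None,
    norm: NormalisationConstants | None = None,
) -> SilhouetteDataset:
    """Rendered-shadow regression set for pretraining / personalising the
    pose regressor (no greyscale nuisances: the regressor sees ideal
    binary renders by construction)."""
    rng = np.random.default_rng(seed)
    base = _multi_sequence_kinematics(n, kinematics, rng)
    shadows = np.empty((n, 1, cam.image_size, cam.image_size))
    flats = np.empty((n, 18))
    for k, base_pose in enumerate(base):
        pose = perturb_pose(base_pose, sigmas, seed=int(rng.integers(2**31)))
        shadows[k, 0] = render_joint_shadow(combo, pose, cam).pixels
        flats[k] = flatten_pose(pose)
    if norm is None:
        norm = NormalisationConstants.from_flat_poses(flats)
    return SilhouetteDataset(
        shadows=shadows,
        targets=norm.normalise(flats),
        norm=norm,
        camera=cam,
        combo_id=combo.combo_id,
    )


def leave_combination_out(samples: list[Sample], held_out: str) -> tuple[list[Sample], list[Sample]]:
    """Split into (training, held-out) partitions by combination id, so a
    model can be evaluated on a combination entirely absent from training."""
    train = [s for s in samples if s.combo_id != held_out]
    test = [s for s in samples if s.combo_id == held_out]
    return train, test


def build_dataset(
    combos: list[ImplantCombination],
    n_per_combo: int,
    nuisance_params: NuisanceParams,
    seed: int,
    out_dir,
    cam: CameraModel | None = None,
    kinematics: KinematicsParams = KinematicsParams(),
    sigmas: np.ndarray | None = None,
    test_combo_ids: list[str] | None = None,
):
    """Write a full on-disk dataset (images, shadows, meshes, pose table,
    manifest) and return the manifest dictionary.

    ``test_combo_ids`` marks whole combinations as the held-out split;
    normalisation constants are computed over the training split only.
    """
    from . import io as fio  # local import to avoid a cycle at import time

    if not combos:
        raise ValueError("need at least one implant combination")
    ids = [c.combo_id for c in combos]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate combo_id in combination list")
    cam = cam or CameraModel.standard(image_size=128)
    test_ids = set(test_combo_ids or [])
    rng = np.random.default_rng(seed)
    all_samples: list[Sample] = []
    for combo in combos:
        all_samples.extend(
            generate_samples(
                combo, n_per_combo, cam, seed=int(rng.integers(2**31)),
                kinematics=kinematics, sigmas=sigmas, nuisance=nuisance_params,
            )
        )
    train = [s for s in all_samples if s.combo_id not in test_ids]
    norm_source = train if train else all_samples
    norm = NormalisationConstants.from_flat_poses(
        np.stack([flatten_pose(s.true_pose) for s in norm_source])
    )
    return fio.write_dataset(
        out_dir, combos, all_samples, cam, norm, seed=seed,
        nuisance_params=nuisance_params, sigmas=sigmas, test_combo_ids=sorted(test_ids),
    )
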
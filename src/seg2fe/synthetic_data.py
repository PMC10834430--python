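"""Synthetic study data: a bone-like shape population with known latent
modes, degraded segmentation masks emulating automatic-segmentation output,
cartilage surfaces for extrusion tests, and smooth 1-D trajectory ensembles.

The shape family is a distal-femur-like implicit surface — two ellipsoidal
condyles and a cylindrical shaft blended by a smooth union — chosen for
controllable latent modes of variation rather than anatomical realism. The
degradation model reproduces the failure modes of automatic segmentations:
a coarse voxel grid, surface noise, spherical holes, and random boundary
misclassifications.

Every generator is seed-deterministic: identical spec + seed produce
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure as _sk_measure

from .mesh_core import GridSpec, TriMesh, VoxelMask, voxelize_surface
from .spm_stats import Trajectory

__all__ = [
    "LatentMode",
    "PopulationSpec",
    "DegradationSpec",
    "OAI_SPACING",
    "synth_population",
    "synth_bone",
    "synth_degrade",
    "synth_cartilage_surface",
    "synth_trajectories",
]

#: anisotropic voxel spacing (mm) matching the knee-MRI protocol of the OAI cohort
OAI_SPACING = (0.36, 0.36, 0.7)

_SQRT8LN2 = float(np.sqrt(8.0 * np.log(2.0)))


@dataclass
class LatentMode:
    """One named geometric parameter of the shape family."""

    name: str
    mean: float
    sd: float

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("latent-mode SD must be >= 0")


@dataclass
class PopulationSpec:
    """Population of bone-like shapes with a few latent modes of variation.

    Default modes: condyle width (mm, semi-axis) and condyle separation
    (mm, center-to-center) are active; the shaft radius is frozen. SDs are
    roughly 8-10% of the means, a plausible anatomical spread.
    """

    n_shapes: int = 30
    latent_modes: list = field(
        default_factory=lambda: [
            LatentMode("condyle_width", 11.0, 1.0),
            LatentMode("condyle_separation", 24.0, 2.0),
            LatentMode("shaft_radius", 9.0, 0.0),
        ]
    )
    pitch: float = 1.2  # marching-cubes grid pitch, mm
    seed: int = 0

    def __post_init__(self):
        if self.n_shapes < 2:
            raise ValueError("n_shapes must be >= 2")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")


@dataclass
class DegradationSpec:
    """Degraded-mask parameters emulating automatic segmentation output."""

    spacing: tuple = (0.5, 0.5, 0.5)
    jitter_sd: float = 0.3  # mm, per-vertex surface noise
    n_holes: int = 3
    hole_radius: float = 2.0  # mm
    flip_probability: float = 0.02  # boundary-voxel misclassification rate
    seed: int = 0

    def __post_init__(self):
        self.spacing = tuple(float(s) for s in np.broadcast_to(np.asarray(self.spacing, float), (3,)))
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be positive")
        for val, name in (
            (self.jitter_sd, "jitter_sd"),
            (self.n_holes, "n_holes"),
            (self.hole_radius, "hole_radius"),
            (self.flip_probability, "flip_probability"),
        ):
            if val < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# shape family
# ---------------------------------------------------------------------------

_CONDYLE_DEPTH = 13.0  # mm, fixed y semi-axis
_CONDYLE_HEIGHT = 10.0  # mm, fixed z semi-axis
_SHAFT_LENGTH = 22.0  # mm
_BLEND = 3.0  # mm, smooth-union radius
# medial/lateral asymmetry, as in a real distal femur: the lateral condyle is
# enlarged by a fixed factor and the shaft sits off the condylar midline, so
# the shape has well-defined principal axes (no mirror ambiguity)
_LATERAL_SCALE = 1.15
_SHAFT_OFFSET_Y = 2.5  # mm


def _ellipsoid_field(pts, center, axes):
    q = (pts - center) / axes
    return (np.linalg.norm(q, axis=1) - 1.0) * min(axes)


def _capsule_field(pts, p0, p1, radius):
    d = p1 - p0
    t = np.clip((pts - p0) @ d / (d @ d), 0.0, 1.0)
    return np.linalg.norm(pts - (p0 + t[:, None] * d), axis=1) - radius


def _smooth_union(fields, k=_BLEND):
    return -k * np.logaddexp.reduce([-f / k for f in fields], axis=0)


def synth_bone(condyle_width: float, condyle_separation: float, shaft_radius: float, pitch: float = 1.2) -> TriMesh:
    """Mesh one distal-femur-like shape from its latent parameters."""
    if min(condyle_width, condyle_separation, shaft_radius) <= 0:
        raise ValueError("all shape parameters must be positive")
    half = condyle_separation / 2.0
    axes = np.array([condyle_width, _CONDYLE_DEPTH, _CONDYLE_HEIGHT])
    margin = 2.5 * pitch + _BLEND
    wide = condyle_width * _LATERAL_SCALE
    lo = np.array([-(half + condyle_width), -_CONDYLE_DEPTH * _LATERAL_SCALE, -_CONDYLE_HEIGHT * _LATERAL_SCALE]) - margin
    hi = np.array(
        [half + wide, _CONDYLE_DEPTH * _LATERAL_SCALE + _SHAFT_OFFSET_Y, _SHAFT_LENGTH + shaft_radius]
    ) + margin
    shape = np.ceil((hi - lo) / pitch).astype(int) + 1

    ii = [lo[a] + np.arange(shape[a]) * pitch for a in range(3)]
    grid = np.stack(np.meshgrid(*ii, indexing="ij"), axis=-1).reshape(-1, 3)
    shaft_axis = np.array([0.0, _SHAFT_OFFSET_Y, 0.0])
    f = _smooth_union(
        [
            _ellipsoid_field(grid, np.array([-half, 0.0, 0.0]), axes),
            _ellipsoid_field(grid, np.array([half, 0.0, 0.0]), axes * _LATERAL_SCALE),
            _capsule_field(
                grid, shaft_axis, shaft_axis + np.array([0.0, 0.0, _SHAFT_LENGTH]), shaft_radius
            ),
        ]
    ).reshape(shape)
    verts, faces, _, _ = _sk_measure.marching_cubes(f, level=0.0, spacing=(pitch,) * 3)
    mesh = TriMesh(verts + lo, faces)
    import trimesh as _tm

    tm = _tm.Trimesh(mesh.vertices, mesh.faces, process=True)
    _tm.repair.fix_normals(tm)
    return TriMesh.from_trimesh(tm)


def synth_population(spec: PopulationSpec):
    """Draw a population of shapes; returns (meshes, latent_parameters).

    `latent_parameters` is an (n_shapes, n_modes) array of the true drawn
    values, column order following `spec.latent_modes`.
    """
    rng = np.random.default_rng(spec.seed)
    means = np.array([m.mean for m in spec.latent_modes])
    sds = np.array([m.sd for m in spec.latent_modes])
    params = rng.normal(means, sds, size=(spec.n_shapes, len(means)))
    if np.any(params <= 0):
        raise ValueError("degenerate (non-positive) latent parameter drawn; reduce SDs")
    by_name = {m.name: i for i, m in enumerate(spec.latent_modes)}
    meshes = [
        synth_bone(
            row[by_name["condyle_width"]],
            row[by_name["condyle_separation"]],
            row[by_name["shaft_radius"]],
            pitch=spec.pitch,
        )
        for row in params
    ]
    return meshes, params


# ---------------------------------------------------------------------------
# degraded masks
# ---------------------------------------------------------------------------


def synth_degrade(gt: TriMesh, spec: DegradationSpec) -> VoxelMask:
    """Degraded binary mask of a ground-truth surface.

    Pipeline: voxelize on the spec grid; surface noise by re-voxelizing a
    vertex-jittered copy; carve spherical holes at random surface-adjacent
    centers; flip boundary voxels with the stated probability.
    """
    if gt.boundary_edge_count() != 0:
        raise ValueError("ground-truth surface must be closed")
    extent = gt.vertices.max(axis=0) - gt.vertices.min(axis=0)
    if spec.n_holes > 0 and 2 * spec.hole_radius > extent.min():
        raise ValueError("hole radius larger than the shape extent")
    rng = np.random.default_rng(spec.seed)
    grid = GridSpec.around(gt.vertices, spec.spacing, margin_mm=3.0)

    source = gt
    if spec.jitter_sd > 0:
        source = TriMesh(gt.vertices + rng.normal(0.0, spec.jitter_sd, gt.vertices.shape), gt.faces)
    mask = voxelize_surface(source, grid)
    values = mask.values.copy()

    if spec.n_holes > 0 and spec.hole_radius > 0:
        centers = gt.vertices[rng.integers(0, len(gt.vertices), spec.n_holes)]
        idx = np.stack(
            np.meshgrid(*[np.arange(s) for s in grid.shape], indexing="ij"), axis=-1
        ).reshape(-1, 3)
        world = grid.origin + idx * grid.spacing
        for center in centers:
            inside = np.linalg.norm(world - center, axis=1) <= spec.hole_radius
            values.reshape(-1)[inside] = 0

    if spec.flip_probability > 0:
        boundary = ndimage.binary_dilation(values) & ~ndimage.binary_erosion(values)
        flips = boundary & (rng.random(values.shape) < spec.flip_probability)
        values = np.where(flips, 1 - values, values)

    return VoxelMask(values, grid.spacing, grid.origin)


# ---------------------------------------------------------------------------
# cartilage surfaces
# ---------------------------------------------------------------------------


def synth_cartilage_surface(bone: TriMesh, patch, thickness_profile) -> TriMesh:
    """Articular surface: a bone patch offset along vertex normals.

    `patch` is a PatchSelection (or any object with `face_indices`);
    `thickness_profile` is either a constant (mm) or a callable mapping
    (K, 3) positions to per-vertex offsets. Raises if the offset folds the
    surface over itself (local self-intersection).
    """
    face_indices = np.asarray(getattr(patch, "face_indices", patch), dtype=np.int64)
    faces = bone.faces[face_indices]
    used = np.unique(faces.ravel())
    remap = np.full(len(bone.vertices), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    sub = TriMesh(bone.vertices[used], remap[faces])

    tri = sub.triangles
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    normals = np.zeros_like(sub.vertices)
    np.add.at(normals, sub.faces.ravel(), np.repeat(fn, 3, axis=0))
    normals /= np.maximum(np.linalg.norm(normals, axis=1, keepdims=True), 1e-300)

    if callable(thickness_profile):
        offset = np.asarray(thickness_profile(sub.vertices), dtype=np.float64).reshape(-1)
    else:
        offset = np.full(len(sub.vertices), float(thickness_profile))
    if np.any(offset <= 0):
        raise ValueError("thickness profile must be positive everywhere")

    moved = sub.vertices + normals * offset[:, None]
    out = TriMesh(moved, sub.faces.copy())
    new_fn = np.cross(
        out.triangles[:, 1] - out.triangles[:, 0], out.triangles[:, 2] - out.triangles[:, 0]
    )
    if np.any(np.einsum("ij,ij->i", new_fn, fn) <= 0):
        raise ValueError("offset folds the surface over itself (self-intersection)")
    return out


# ---------------------------------------------------------------------------
# trajectory ensembles
# ---------------------------------------------------------------------------


def synth_trajectories(
    n_per_group: int,
    effect_size: float,
    fwhm_nodes: float,
    Q: int = 101,
    seed: int = 0,
):
    """Two groups of smooth unit-variance Gaussian trajectories.

    Node-wise white noise is convolved with a Gaussian kernel of the given
    FWHM and rescaled so each node has unit process variance (the kernel's
    L2 norm); group B is mean-shifted by `effect_size` (in SD units, since
    the process variance is 1). Padding before convolution keeps the
    process stationary across the whole domain.
    """
    if Q < 8:
        raise ValueError("Q must be >= 8")
    if fwhm_nodes <= 0:
        raise ValueError("fwhm_nodes must be positive")
    rng = np.random.default_rng(seed)
    sigma = fwhm_nodes / _SQRT8LN2
    pad = int(np.ceil(4 * sigma)) + 1

    def draw(n, shift):
        white = rng.standard_normal((n, Q + 2 * pad))
        smooth = ndimage.gaussian_filter1d(white, sigma, axis=1, mode="constant")
        # unit process variance: divide by the L2 norm of the kernel
        kernel = ndimage.gaussian_filter1d(
            np.eye(1, 2 * pad + 1, pad).ravel(), sigma, mode="constant"
        )
        smooth = smooth[:, pad:-pad] / np.sqrt(np.sum(kernel**2))
        return [Trajectory(row + shift) for row in smooth]

    return draw(n_per_group, 0.0), draw(n_per_group, effect_size)
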
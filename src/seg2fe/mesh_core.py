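"""Mesh and voxel-mask data structures, I/O, and surface processing.

All coordinates are in millimetres, world frame. Voxel grids follow the
NIfTI convention used throughout: 0-based indices, the origin is the world
position of the *center* of voxel (0, 0, 0), and the world position of voxel
(i, j, k) is ``origin + index * spacing``.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import trimesh as _tm
from scipy.spatial import cKDTree
from skimage import measure as _sk_measure

from ._closest import SurfaceQuery
from ._rays import vertical_ray_crossings as _vertical_ray_crossings

__all__ = [
    "VoxelMask",
    "TriMesh",
    "QuadMesh",
    "SurfacePointSet",
    "GridSpec",
    "MeshFormatError",
    "read_mesh",
    "write_mesh",
    "read_mask",
    "write_mask",
    "mask_to_surface",
    "voxelize_surface",
    "taubin_smooth",
    "remesh_template",
    "poisson_disk_sample",
    "uniformize_points",
]


class MeshFormatError(ValueError):
    """Raised when a mesh file cannot be parsed or written."""


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------


@dataclass
class VoxelMask:
    """Binary 3-D segmentation on a regular grid.

    values : (ni, nj, nk) array in {0, 1}
    spacing : mm per axis, all positive
    origin : world mm of the center of voxel (0, 0, 0)
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("mask values must be a 3-D array")
        uniq = np.unique(self.values)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be binary {0,1}")
        self.values = self.values.astype(np.uint8)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive on all axes")

    @property
    def shape(self):
        return self.values.shape

    @property
    def n_foreground(self) -> int:
        return int(self.values.sum())

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(indices, dtype=np.float64) * self.spacing

    def same_grid(self, other: "VoxelMask", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def copy(self) -> "VoxelMask":
        return VoxelMask(self.values.copy(), self.spacing.copy(), self.origin.copy())


@dataclass
class GridSpec:
    """Voxel-grid geometry without the values: spacing, origin, shape."""

    spacing: np.ndarray
    origin: np.ndarray
    shape: tuple

    def __post_init__(self):
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.shape = tuple(int(s) for s in self.shape)
        if np.any(self.spacing <= 0) or any(s <= 0 for s in self.shape):
            raise ValueError("grid spacing and shape must be positive")

    @classmethod
    def around(cls, points: np.ndarray, spacing, margin_mm: float = 2.0) -> "GridSpec":
        """Smallest grid at `spacing` covering `points` plus a margin."""
        spacing = np.broadcast_to(np.asarray(spacing, dtype=np.float64), (3,))
        lo = points.min(axis=0) - margin_mm
        hi = points.max(axis=0) + margin_mm
        shape = np.ceil((hi - lo) / spacing).astype(int) + 1
        return cls(spacing, lo, tuple(shape))


def _validate_faces(vertices, faces, width):
    if faces.ndim != 2 or faces.shape[1] != width:
        raise ValueError(f"faces must be (M, {width})")
    if len(faces) and (faces.min() < 0 or faces.max() >= len(vertices)):
        raise ValueError("face indices out of range")
    for row in range(width):
        for col in range(row + 1, width):
            if np.any(faces[:, row] == faces[:, col]):
                raise ValueError("degenerate face with repeated vertex index")


@dataclass
class TriMesh:
    """Triangle surface mesh: vertices (N, 3) mm, faces (M, 3) 0-based."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("vertex coordinates must be finite")
        _validate_faces(self.vertices, self.faces, 3)

    # interop ---------------------------------------------------------------
    def to_trimesh(self) -> _tm.Trimesh:
        return _tm.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, m: _tm.Trimesh) -> "TriMesh":
        return cls(np.asarray(m.vertices, dtype=np.float64), np.asarray(m.faces, dtype=np.int64))

    # geometry --------------------------------------------------------------
    @property
    def triangles(self) -> np.ndarray:
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        t = self.triangles
        return 0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)

    @property
    def area(self) -> float:
        return float(self.face_areas().sum())

    def vertex_areas(self) -> np.ndarray:
        """Barycentric area ownership: each vertex owns 1/3 of incident faces."""
        fa = self.face_areas()
        va = np.zeros(len(self.vertices))
        np.add.at(va, self.faces.ravel(), np.repeat(fa / 3.0, 3))
        return va

    def edges_unique(self) -> np.ndarray:
        e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        return np.unique(e, axis=0)

    def boundary_edge_count(self) -> int:
        e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return int(np.sum(counts == 1))

    def is_closed(self) -> bool:
        return self.boundary_edge_count() == 0

    def surface_query(self) -> SurfaceQuery:
        return SurfaceQuery(self.vertices, self.faces)

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy())


@dataclass
class QuadMesh:
    """Quadrilateral surface mesh: vertices (N, 3) mm, faces (M, 4) 0-based."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("vertex coordinates must be finite")
        _validate_faces(self.vertices, self.faces, 4)

    def copy(self) -> "QuadMesh":
        return QuadMesh(self.vertices.copy(), self.faces.copy())


@dataclass
class SurfacePointSet:
    """Points sampled on a surface, tagged with the surface they came from."""

    points: np.ndarray
    source_mesh_id: str = ""

    def __post_init__(self):
        self.points = np.ascontiguousarray(self.points, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points must be finite")

    def __len__(self):
        return len(self.points)


# ---------------------------------------------------------------------------
# mesh I/O
# ---------------------------------------------------------------------------

_TRIMESH_FORMATS = {"ply", "stl", "off"}
_ALL_FORMATS = _TRIMESH_FORMATS | {"vtk"}


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is None:
        fmt = os.path.splitext(path)[1].lstrip(".")
    fmt = fmt.lower()
    if fmt not in _ALL_FORMATS:
        raise MeshFormatError(f"unsupported mesh format {fmt!r}; supported: {sorted(_ALL_FORMATS)}")
    return fmt


def _weld_vertices(vertices, faces, tol=1e-9):
    """Merge vertices coincident within `tol` (STL face soup -> indexed mesh)."""
    key = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    return vertices[first], inverse[faces]


def read_mesh(path, fmt: str | None = None):
    """Read a surface mesh (PLY/STL/OFF/VTK). Returns TriMesh or QuadMesh."""
    fmt = _infer_format(str(path), fmt)
    if not os.path.exists(path):
        raise MeshFormatError(f"no such file: {path}")
    if os.path.getsize(path) == 0:
        raise MeshFormatError(f"empty file: {path}")
    if fmt == "vtk":
        return _read_vtk(path)
    try:
        m = _tm.load(str(path), file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - file parsing failures vary by loader
        raise MeshFormatError(f"cannot parse {path}: {exc}") from exc
    vertices = np.asarray(m.vertices, dtype=np.float64)
    faces = np.asarray(m.faces, dtype=np.int64)
    if len(vertices) == 0 or len(faces) == 0:
        raise MeshFormatError(f"{path}: no usable geometry")
    if fmt == "stl":  # STL is a face soup; rebuild shared vertices
        vertices, faces = _weld_vertices(vertices, faces)
    return TriMesh(vertices, faces)


def write_mesh(mesh, path, fmt: str | None = None) -> None:
    """Write a TriMesh or QuadMesh to PLY/STL/OFF/VTK."""
    fmt = _infer_format(str(path), fmt)
    if fmt == "vtk":
        _write_vtk(mesh, path)
        return
    if isinstance(mesh, QuadMesh):
        raise MeshFormatError("quad meshes are only supported in VTK format")
    mesh.to_trimesh().export(str(path), file_type=fmt)


_VTK_CELL = {3: 5, 4: 9}  # VTK_TRIANGLE, VTK_QUAD


def _write_vtk(mesh, path) -> None:
    faces = mesh.faces
    width = faces.shape[1]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nseg2fe surface\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(mesh.vertices)} double\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        fh.write(f"CELLS {len(faces)} {len(faces) * (width + 1)}\n")
        for f in faces:
            fh.write(str(width) + " " + " ".join(str(i) for i in f) + "\n")
        fh.write(f"CELL_TYPES {len(faces)}\n")
        fh.write("\n".join([str(_VTK_CELL[width])] * len(faces)) + "\n")


def _read_vtk(path):
    with open(path) as fh:
        tokens_lines = fh.read().split("\n")
    tokens = " ".join(
        line for line in tokens_lines if not line.startswith("#") and line.strip()
    ).split()
    try:
        up = [t.upper() for t in tokens]
        ip = up.index("POINTS")
        n_pts = int(tokens[ip + 1])
        coords = np.array(tokens[ip + 3 : ip + 3 + 3 * n_pts], dtype=np.float64).reshape(-1, 3)
        ic = up.index("CELLS")
        n_cells = int(tokens[ic + 1])
        total = int(tokens[ic + 2])
        flat = np.array(tokens[ic + 3 : ic + 3 + total], dtype=np.int64)
    except (ValueError, IndexError) as exc:
        raise MeshFormatError(f"cannot parse VTK file {path}: {exc}") from exc
    cells, pos = [], 0
    for _ in range(n_cells):
        w = flat[pos]
        cells.append(flat[pos + 1 : pos + 1 + w])
        pos += w + 1
    widths = {len(c) for c in cells}
    if widths == {3}:
        return TriMesh(coords, np.array(cells))
    if widths == {4}:
        return QuadMesh(coords, np.array(cells))
    raise MeshFormatError(f"{path}: mixed or unsupported VTK cell sizes {sorted(widths)}")


# ---------------------------------------------------------------------------
# mask I/O
# ---------------------------------------------------------------------------


def read_mask(path) -> VoxelMask:
    """Read a NIfTI label volume as a binary mask (any nonzero label -> 1).

    Only axis-aligned affines are supported; negative-step axes are flipped
    so spacing is positive, adjusting the origin accordingly. Oblique grids
    raise.
    """
    img = nib.load(str(path))
    affine = img.affine
    lin = affine[:3, :3]
    if np.abs(lin - np.diag(np.diag(lin))).max() > 1e-6 * np.abs(np.diag(lin)).max():
        raise ValueError("unsupported oblique/non-axis-aligned NIfTI affine")
    step = np.diag(lin).astype(np.float64)
    if np.any(step == 0):
        raise ValueError("degenerate NIfTI affine with zero spacing")
    values = (np.asanyarray(img.dataobj) != 0).astype(np.uint8)
    if values.ndim == 4 and values.shape[3] == 1:
        values = values[..., 0]
    origin = affine[:3, 3].astype(np.float64)
    for axis in range(3):
        if step[axis] < 0:
            values = np.flip(values, axis=axis)
            origin[axis] = origin[axis] + step[axis] * (values.shape[axis] - 1)
            step[axis] = -step[axis]
    mask = VoxelMask(values, step, origin)
    if mask.n_foreground == 0:
        warnings.warn(f"{path}: mask has zero foreground voxels", stacklevel=2)
    return mask


def write_mask(mask: VoxelMask, path) -> None:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(mask.spacing)
    affine[:3, 3] = mask.origin
    nib.save(nib.Nifti1Image(mask.values.astype(np.uint8), affine), str(path))


# ---------------------------------------------------------------------------
# mask <-> surface
# ---------------------------------------------------------------------------


def mask_to_surface(mask: VoxelMask, iso: float = 0.5, keep_largest: bool = True) -> TriMesh:
    """Marching-cubes surface of a binary mask, in world mm.

    The volume is zero-padded so the surface closes at the grid boundary.
    By default only the largest connected surface component is kept, which
    discards speckle artifacts typical of automatic segmentation output.
    """
    if mask.n_foreground == 0:
        raise ValueError("cannot extract a surface from an empty mask")
    padded = np.pad(mask.values.astype(np.float32), 1)
    verts, faces, _, _ = _sk_measure.marching_cubes(padded, level=iso, spacing=tuple(mask.spacing))
    verts = verts + (mask.origin - mask.spacing)
    mesh = _tm.Trimesh(verts, faces, process=True)
    if keep_largest:
        parts = mesh.split(only_watertight=False)
        if len(parts) > 1:
            mesh = max(parts, key=lambda p: p.area)
    _tm.repair.fix_normals(mesh)
    return TriMesh.from_trimesh(mesh)


def _column_parity_fill(mesh: TriMesh, grid: GridSpec) -> np.ndarray:
    """Inside test for all voxel centers by z-ray parity, one ray per column."""
    spacing, origin, shape = grid.spacing, grid.origin, grid.shape
    xs = origin[0] + np.arange(shape[0]) * spacing[0]
    ys = origin[1] + np.arange(shape[1]) * spacing[1]
    zs = origin[2] + np.arange(shape[2]) * spacing[2]

    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    n_col = xx.size
    # deterministic sub-voxel jitter avoids rays grazing marching-cubes
    # vertices that are aligned with voxel centers
    rng = np.random.default_rng(123456789)
    jitter = (rng.random((n_col, 2)) - 0.5) * 2e-3 * spacing[:2]
    ray_xy = np.column_stack([xx.ravel() + jitter[:, 0], yy.ravel() + jitter[:, 1]])

    index_ray, z_hits_all = _vertical_ray_crossings(ray_xy, mesh.triangles)

    values = np.zeros(shape, dtype=np.uint8)
    if len(index_ray) == 0:
        return values
    order = np.lexsort((z_hits_all, index_ray))
    ray_sorted = index_ray[order]
    z_sorted = z_hits_all[order]
    starts = np.searchsorted(ray_sorted, np.arange(n_col))
    ends = np.searchsorted(ray_sorted, np.arange(n_col) + 1)
    for col in range(n_col):
        z_hits = z_sorted[starts[col] : ends[col]]
        if len(z_hits) == 0:
            continue
        # collapse duplicate hits on shared edges/vertices
        z_hits = z_hits[np.concatenate(([True], np.diff(z_hits) > 1e-9))]
        counts = np.searchsorted(z_hits, zs, side="right")
        i, j = divmod(col, shape[1])
        values[i, j, :] = counts % 2
    return values


def voxelize_surface(mesh: TriMesh, grid: GridSpec) -> VoxelMask:
    """Binary mask: voxel = 1 iff its center lies inside the closed surface."""
    n_boundary = mesh.boundary_edge_count()
    if n_boundary:
        raise ValueError(
            f"voxelize_surface requires a watertight mesh; found {n_boundary} boundary edges"
        )
    values = _column_parity_fill(mesh, grid)
    return VoxelMask(values, grid.spacing, grid.origin)


# ---------------------------------------------------------------------------
# smoothing and remeshing
# ---------------------------------------------------------------------------


def _vertex_neighbors(n_vertices, faces):
    edges = np.vstack(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]], faces[:, [1, 0]], faces[:, [2, 1]], faces[:, [0, 2]]]
    )
    edges = np.unique(edges, axis=0)
    counts = np.bincount(edges[:, 0], minlength=n_vertices)
    order = np.argsort(edges[:, 0], kind="stable")
    return edges[order, 1], np.concatenate(([0], np.cumsum(counts)))


def _laplacian_step(vertices, neigh, offsets, factor):
    sums = np.add.reduceat(vertices[neigh], offsets[:-1], axis=0)
    counts = np.diff(offsets)[:, None]
    valid = counts[:, 0] > 0
    out = vertices.copy()
    out[valid] += factor * (sums[valid] / counts[valid] - vertices[valid])
    return out


def taubin_smooth(mesh: TriMesh, lam: float = 0.5, mu: float = -0.53, iterations: int = 10) -> TriMesh:
    """Taubin lambda/mu smoothing: volume-preserving alternative to Laplacian.

    Each iteration shrinks with factor `lam` then inflates with factor `mu`
    (negative), cancelling the low-frequency shrinkage of plain Laplacian
    smoothing while still attenuating high-frequency noise.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if mu >= 0:
        raise ValueError("mu must be < 0")
    if iterations == 0:
        return mesh.copy()
    neigh, offsets = _vertex_neighbors(len(mesh.vertices), mesh.faces)
    v = mesh.vertices.copy()
    for _ in range(iterations):
        v = _laplacian_step(v, neigh, offsets, lam)
        v = _laplacian_step(v, neigh, offsets, mu)
    return TriMesh(v, mesh.faces.copy())


def _min_angles(mesh: TriMesh) -> np.ndarray:
    t = mesh.triangles
    out = []
    for i in range(3):
        a = t[:, (i + 1) % 3] - t[:, i]
        b = t[:, (i + 2) % 3] - t[:, i]
        cosang = np.einsum("ij,ij->i", a, b) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1) + 1e-300
        )
        out.append(np.arccos(np.clip(cosang, -1, 1)))
    return np.min(out, axis=0)


def remesh_template(mesh: TriMesh, target_vertex_count: int, tol_fraction: float = 0.1) -> TriMesh:
    """Resample a closed surface to approximately `target_vertex_count` vertices.

    Implemented as isotropic resampling: the surface's occupancy field is
    re-extracted by marching cubes at a pitch chosen (by secant iteration on
    the vertex count) to land within ``tol_fraction`` of the target, then
    relaxed tangentially and projected back onto the input surface so the
    result stays within a tight Hausdorff budget of the original.
    """
    if target_vertex_count < 4:
        raise ValueError("target_vertex_count must be >= 4")
    if mesh.boundary_edge_count() != 0:
        raise ValueError("remesh_template requires a closed, manifold surface")
    n_now = len(mesh.vertices)
    if abs(n_now - target_vertex_count) <= tol_fraction * target_vertex_count:
        return mesh.copy()

    area = mesh.area
    pitch = float(np.sqrt(2.0 * area / target_vertex_count))
    query = mesh.surface_query()
    best = None
    for _ in range(8):
        grid = GridSpec.around(mesh.vertices, pitch, margin_mm=2 * pitch)
        coarse = mask_to_surface(voxelize_surface(mesh, grid))
        achieved = len(coarse.vertices)
        if best is None or abs(achieved - target_vertex_count) < abs(best[0] - target_vertex_count):
            best = (achieved, coarse)
        if abs(achieved - target_vertex_count) <= tol_fraction * target_vertex_count:
            break
        pitch *= float(np.sqrt(achieved / target_vertex_count))
    result = best[1]

    neigh, offsets = _vertex_neighbors(len(result.vertices), result.faces)
    v = result.vertices
    for _ in range(4):
        v = _laplacian_step(v, neigh, offsets, 0.5)
        v = query.project(v)
    return TriMesh(v, result.faces)


# ---------------------------------------------------------------------------
# surface point sampling
# ---------------------------------------------------------------------------


def poisson_disk_sample(
    mesh: TriMesh, n_points: int, seed: int, oversample: int = 15, mesh_id: str = ""
) -> SurfacePointSet:
    """Blue-noise surface sampling: dense uniform pool + farthest-point pick.

    Farthest-point selection from an area-uniform candidate pool yields the
    Poisson-disk property (a guaranteed empty disk around every sample); the
    pick is deterministic given the seed.
    """
    if n_points < 4:
        raise ValueError("n_points must be >= 4")
    pool_size = oversample * n_points
    if n_points > pool_size:
        raise ValueError("n_points exceeds the oversampling pool budget")
    pool, _ = _tm.sample.sample_surface(mesh.to_trimesh(), pool_size, seed=int(seed))
    pool = np.asarray(pool, dtype=np.float64)

    chosen = np.empty(n_points, dtype=np.int64)
    chosen[0] = 0
    dist = np.linalg.norm(pool - pool[0], axis=1)
    for k in range(1, n_points):
        chosen[k] = int(np.argmax(dist))
        np.minimum(dist, np.linalg.norm(pool - pool[chosen[k]], axis=1), out=dist)
    return SurfacePointSet(pool[chosen], mesh_id)


def uniformize_points(
    points: SurfacePointSet,
    mesh: TriMesh,
    iterations: int = 20,
    neighbor_radius_factor: float = 1.3,
    step: float = 0.3,
) -> SurfacePointSet:
    """Equalize neighbor distances of on-surface points (spring relaxation).

    Each point feels a spring force from neighbors closer than
    ``neighbor_radius_factor`` x the median nearest-neighbor distance, with
    rest length equal to the mean nearest-neighbor distance; after each step
    points are re-projected onto the surface. A perfectly uniform set is a
    fixed point. A step is rejected (and the step size halved) if it would
    increase the spread of nearest-neighbor distances.
    """
    if len(points) < 4:
        raise ValueError("need at least 4 points")
    query = mesh.surface_query()
    pts = points.points.copy()

    def nn_dist(p):
        tree = cKDTree(p)
        d, _ = tree.query(p, k=2)
        return d[:, 1]

    for _ in range(iterations):
        nn = nn_dist(pts)
        rest = float(nn.mean())
        radius = neighbor_radius_factor * float(np.median(nn))
        tree = cKDTree(pts)
        pairs = tree.query_pairs(radius, output_type="ndarray")
        if len(pairs) == 0:
            break
        delta = pts[pairs[:, 1]] - pts[pairs[:, 0]]
        length = np.linalg.norm(delta, axis=1)
        unit = delta / length[:, None]
        force = np.zeros_like(pts)
        f = (length - rest)[:, None] * unit
        np.add.at(force, pairs[:, 0], f)
        np.add.at(force, pairs[:, 1], -f)
        deg = np.zeros(len(pts))
        np.add.at(deg, pairs.ravel(), 1.0)
        deg = np.maximum(deg, 1.0)[:, None]

        spread = float(nn.std())
        local_step = step
        for _attempt in range(4):
            candidate = query.project(pts + local_step * force / deg)
            if float(nn_dist(candidate).std()) <= spread + 1e-15:
                pts = candidate
                break
            local_step *= 0.5
        else:
            break
    return SurfacePointSet(pts, points.source_mesh_id)
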
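"""Cartilage meshing: bone-cartilage contact patch selection, quadrilateral
patch meshing, layered hexahedral extrusion to the articular surface, mesh
quality checks, and Abaqus INP export.

The extrusion follows standard cartilage FE practice: the quadrilateral
bone-surface patch in the calcified zone is swept toward the articular
surface along per-node directions, producing `n_layers` (default 5) layers
of 8-node hexahedra whose bottom nodes are shared verbatim with the bone
patch, so bone and cartilage meshes are conforming at the interface.
Element size presets of 2, 1 and 0.5 mm cover the coarse/fine/very-fine
resolutions commonly exercised in mesh-sensitivity studies.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from ._rays import ray_cast_first_hit
from .mesh_core import QuadMesh, TriMesh

__all__ = [
    "HexMesh",
    "QualityReport",
    "PatchSelection",
    "ELEMENT_SIZE_PRESETS",
    "select_contact_patch",
    "quad_patch",
    "extrude_cartilage",
    "hex_quality",
    "write_inp",
    "read_inp",
    "write_hex_vtk",
]

#: coarse / fine / very fine target element sizes (mm)
ELEMENT_SIZE_PRESETS = {"coarse": 2.0, "fine": 1.0, "very_fine": 0.5}

# scaled-Jacobian corner edge triples for C3D8 node ordering
_CORNER_EDGES = (
    (1, 3, 4),
    (2, 0, 5),
    (3, 1, 6),
    (0, 2, 7),
    (7, 5, 0),
    (4, 6, 1),
    (5, 7, 2),
    (6, 4, 3),
)


@dataclass
class PatchSelection:
    """Faces (and their vertices) of a bone surface selected as the contact patch."""

    face_indices: np.ndarray
    vertex_indices: np.ndarray

    def __post_init__(self):
        self.face_indices = np.asarray(self.face_indices, dtype=np.int64).reshape(-1)
        self.vertex_indices = np.asarray(self.vertex_indices, dtype=np.int64).reshape(-1)


@dataclass
class HexMesh:
    """Layered hexahedral mesh in Abaqus C3D8 node ordering.

    elements[:, :4] is the bottom quad (counter-clockwise about the
    extrusion direction), elements[:, 4:] the top quad. `node_sets` holds at
    least 'bone_interface' and 'articular_surface'; `element_sets` one entry
    per layer.
    """

    nodes: np.ndarray
    elements: np.ndarray
    layer_id: np.ndarray
    node_sets: dict = field(default_factory=dict)
    element_sets: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.ascontiguousarray(self.nodes, dtype=np.float64).reshape(-1, 3)
        self.elements = np.ascontiguousarray(self.elements, dtype=np.int64)
        self.layer_id = np.asarray(self.layer_id, dtype=np.int64).reshape(-1)
        if self.elements.ndim != 2 or self.elements.shape[1] != 8:
            raise ValueError("elements must be (M, 8)")
        if len(self.elements) and (self.elements.min() < 0 or self.elements.max() >= len(self.nodes)):
            raise ValueError("element node indices out of range")
        if len(self.layer_id) != len(self.elements):
            raise ValueError("one layer id per element required")

    @property
    def n_layers(self) -> int:
        return len(np.unique(self.layer_id))


@dataclass
class QualityReport:
    """Element-quality summary for a hexahedral mesh."""

    min_scaled_jacobian: float
    n_inverted: int
    min_thickness_mm: float
    max_thickness_mm: float
    max_aspect_ratio: float


# ---------------------------------------------------------------------------
# patch selection and quad meshing
# ---------------------------------------------------------------------------


def select_contact_patch(bone: TriMesh, cartilage_surface: TriMesh, max_distance: float = 2.0) -> PatchSelection:
    """Bone faces whose centroids lie within `max_distance` mm of the cartilage.

    Only the largest edge-connected component of the selection is kept, so
    isolated faces that happen to pass the distance test are dropped.
    """
    centroids = bone.triangles.mean(axis=1)
    d = cartilage_surface.surface_query().distance(centroids)
    selected = np.flatnonzero(d <= max_distance)
    if len(selected) == 0:
        raise ValueError(
            f"no bone faces within {max_distance} mm of the cartilage surface; increase max_distance"
        )
    # face adjacency within the selection (shared edge)
    faces = bone.faces[selected]
    edges = np.sort(
        np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1
    )
    owner = np.tile(np.arange(len(selected)), 3)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    edges, owner = edges[order], owner[order]
    same = np.all(edges[1:] == edges[:-1], axis=1)
    i, j = owner[:-1][same], owner[1:][same]
    graph = coo_matrix((np.ones(len(i)), (i, j)), shape=(len(selected),) * 2)
    n_comp, labels = connected_components(graph, directed=False)
    if n_comp > 1:
        counts = np.bincount(labels)
        selected = selected[labels == np.argmax(counts)]
    verts = np.unique(bone.faces[selected].ravel())
    return PatchSelection(selected, verts)


def quad_patch(bone: TriMesh, patch: PatchSelection, grid=(10, 10), max_offset_factor: float = 2.0) -> QuadMesh:
    """Structured quadrilateral mesh over a selected bone patch.

    A regular nu x nv node grid is laid over the patch's least-squares plane
    (principal axes of the patch vertices) and each node is projected onto
    the patch submesh. Projection is considered failed for a node whose
    plane point is farther from the patch than `max_offset_factor` x the
    grid cell diagonal; more than 5% failures raise.
    """
    nu, nv = int(grid[0]), int(grid[1])
    if nu < 2 or nv < 2:
        raise ValueError("grid must be at least 2x2 nodes")
    pv = bone.vertices[patch.vertex_indices]
    center = pv.mean(axis=0)
    _, _, Vt = np.linalg.svd(pv - center, full_matrices=False)
    eu, ev = Vt[0], Vt[1]  # in-plane axes of the least-squares plane
    # rotate the in-plane frame to the minimum-area bounding rectangle so
    # the grid hugs the patch footprint (the SVD direction is arbitrary for
    # isotropic patches, and an oversized grid degenerates at the rim)
    u0 = (pv - center) @ eu
    v0 = (pv - center) @ ev
    best = None
    for angle in np.linspace(0.0, np.pi / 2, 19):
        c, s = np.cos(angle), np.sin(angle)
        ur = c * u0 + s * v0
        vr = -s * u0 + c * v0
        area = np.ptp(ur) * np.ptp(vr)
        if best is None or area < best[0]:
            best = (area, angle)
    c, s = np.cos(best[1]), np.sin(best[1])
    eu, ev = c * eu + s * ev, -s * eu + c * ev
    uu = (pv - center) @ eu
    vv = (pv - center) @ ev
    us = np.linspace(uu.min(), uu.max(), nu)
    vs = np.linspace(vv.min(), vv.max(), nv)
    gu, gv = np.meshgrid(us, vs, indexing="ij")
    plane_pts = center + gu.ravel()[:, None] * eu + gv.ravel()[:, None] * ev

    sub = TriMesh(bone.vertices, bone.faces[patch.face_indices])
    dist, projected, _ = sub.surface_query().query(plane_pts)
    cell_diag = float(np.hypot(us[1] - us[0], vs[1] - vs[0]))
    failed = dist > max_offset_factor * cell_diag
    if failed.mean() > 0.05:
        raise ValueError(
            f"projection failed at {failed.sum()}/{len(plane_pts)} grid nodes; "
            "the patch is too curved or too irregular for this grid"
        )

    quads = []
    for a in range(nu - 1):
        for b in range(nv - 1):
            n00 = a * nv + b
            quads.append([n00, n00 + nv, n00 + nv + 1, n00 + 1])
    return QuadMesh(projected, np.asarray(quads, dtype=np.int64))


# ---------------------------------------------------------------------------
# hexahedral extrusion
# ---------------------------------------------------------------------------


def _quad_normals(mesh: QuadMesh) -> np.ndarray:
    q = mesh.vertices[mesh.faces]
    n = np.cross(q[:, 2] - q[:, 0], q[:, 3] - q[:, 1])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    return n / np.maximum(norm, 1e-300)


def _node_normals(mesh: QuadMesh) -> np.ndarray:
    q = mesh.vertices[mesh.faces]
    fn = np.cross(q[:, 2] - q[:, 0], q[:, 3] - q[:, 1])  # area-weighted
    out = np.zeros_like(mesh.vertices)
    for k in range(4):
        np.add.at(out, mesh.faces[:, k], fn)
    norm = np.linalg.norm(out, axis=1, keepdims=True)
    return out / np.maximum(norm, 1e-300)


def extrude_cartilage(
    patch: QuadMesh,
    articular: TriMesh,
    n_layers: int = 5,
    min_thickness: float = 0.1,
) -> HexMesh:
    """Extrude a bone quad patch to the articular surface as layered hexes.

    Per node, the thickness is the distance along the area-weighted vertex
    normal ray to the articular surface (nearest-point fallback when the
    ray misses), floored at `min_thickness` mm, and split into `n_layers`
    equal segments. Interface nodes are the patch nodes verbatim, so the
    cartilage mesh is conforming with the bone surface mesh; the top node
    layer lies on the articular surface.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    normals = _node_normals(patch)
    # orient toward the articular surface
    to_art = articular.vertices.mean(axis=0) - patch.vertices.mean(axis=0)
    if float(np.einsum("ij,j->", normals, to_art)) < 0:
        normals = -normals

    tri = articular.triangles
    t_hit, hit = ray_cast_first_hit(patch.vertices, normals, tri)
    thickness = t_hit.copy()
    directions = normals.copy()
    if not np.all(hit):
        # margin nodes whose normal ray misses the articular surface taper:
        # the extrusion stays along the normal (skewed columns would invert
        # neighbors) with the along-normal component of the nearest-point
        # offset as thickness
        miss = ~hit
        _, closest, _ = articular.surface_query().query(patch.vertices[miss])
        along = np.einsum("ij,ij->i", closest - patch.vertices[miss], normals[miss])
        thickness[miss] = np.maximum(along, 0.0)
    floored = thickness < min_thickness
    if np.any(floored):
        warnings.warn(
            f"{int(floored.sum())} node(s) floored to min_thickness={min_thickness} mm",
            stacklevel=2,
        )
        thickness = np.maximum(thickness, min_thickness)

    n_nodes = len(patch.vertices)
    levels = [patch.vertices.copy()]  # level 0: bit-identical interface nodes
    for level in range(1, n_layers + 1):
        levels.append(patch.vertices + directions * (thickness * (level / n_layers))[:, None])
    nodes = np.vstack(levels)

    # orient each quad counter-clockwise about its extrusion direction
    faces = patch.faces.copy()
    qn = _quad_normals(patch)
    mean_dir = directions[patch.faces].mean(axis=1)
    flip = np.einsum("ij,ij->i", qn, mean_dir) < 0
    faces[flip] = faces[flip][:, ::-1]

    elements, layer_id = [], []
    for layer in range(n_layers):
        bottom = faces + layer * n_nodes
        top = faces + (layer + 1) * n_nodes
        elements.append(np.hstack([bottom, top]))
        layer_id.append(np.full(len(faces), layer + 1))
    elements = np.vstack(elements)
    layer_id = np.concatenate(layer_id)

    node_sets = {
        "bone_interface": np.arange(n_nodes),
        "articular_surface": np.arange(n_nodes) + n_layers * n_nodes,
    }
    element_sets = {
        f"layer_{layer}": np.flatnonzero(layer_id == layer) for layer in range(1, n_layers + 1)
    }
    return HexMesh(nodes, elements, layer_id, node_sets, element_sets)


# ---------------------------------------------------------------------------
# quality
# ---------------------------------------------------------------------------


def _corner_scaled_jacobians(hexes: np.ndarray) -> np.ndarray:
    """Scaled Jacobian at each of the 8 corners; (M, 8)."""
    out = np.empty((len(hexes), 8))
    for corner, (i, j, k) in enumerate(_CORNER_EDGES):
        e1 = hexes[:, i] - hexes[:, corner]
        e2 = hexes[:, j] - hexes[:, corner]
        e3 = hexes[:, k] - hexes[:, corner]
        det = np.einsum("ij,ij->i", np.cross(e1, e2), e3)
        norms = (
            np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1) * np.linalg.norm(e3, axis=1)
        )
        out[:, corner] = det / np.maximum(norms, 1e-300)
    return out


def hex_quality(mesh: HexMesh) -> QualityReport:
    """Scaled-Jacobian, inversion, thickness and aspect-ratio summary."""
    hexes = mesh.nodes[mesh.elements]
    sj = _corner_scaled_jacobians(hexes)
    min_sj = float(sj.min())
    n_inverted = int(np.sum(sj.min(axis=1) <= 0))

    # per-element thickness: mean bottom-to-top corner distance
    thick = np.linalg.norm(hexes[:, 4:] - hexes[:, :4], axis=2).mean(axis=1)
    edges_b = np.linalg.norm(hexes[:, [1, 2, 3, 0], :] - hexes[:, :4], axis=2)
    longest = edges_b.max(axis=1)
    shortest = np.minimum(edges_b.min(axis=1), thick)
    aspect = longest / np.maximum(shortest, 1e-300)
    aspect = np.maximum(aspect, thick / np.maximum(edges_b.min(axis=1), 1e-300))
    return QualityReport(
        min_scaled_jacobian=min_sj,
        n_inverted=n_inverted,
        min_thickness_mm=float(thick.min()),
        max_thickness_mm=float(thick.max()),
        max_aspect_ratio=float(aspect.max()),
    )


# ---------------------------------------------------------------------------
# Abaqus INP and VTK export
# ---------------------------------------------------------------------------


def _write_id_lines(fh, ids, per_line=16):
    ids = np.asarray(ids) + 1  # Abaqus is 1-based
    for start in range(0, len(ids), per_line):
        fh.write(", ".join(str(i) for i in ids[start : start + per_line]) + "\n")


def write_inp(mesh: HexMesh, path, element_type: str = "C3D8P", part_name: str = "CARTILAGE") -> None:
    """Write an Abaqus INP: *NODE, *ELEMENT (pore-pressure hexes by default),
    and node/element sets for the interface, articular surface, and layers."""
    if len(mesh.elements) == 0:
        raise ValueError("cannot export an empty hex mesh")
    with open(path, "w") as fh:
        fh.write(f"*HEADING\nseg2fe cartilage mesh, part {part_name}, units mm\n")
        fh.write("*NODE\n")
        for i, (x, y, z) in enumerate(mesh.nodes, start=1):
            fh.write(f"{i}, {x:.9g}, {y:.9g}, {z:.9g}\n")
        fh.write(f"*ELEMENT, TYPE={element_type}, ELSET={part_name}\n")
        for i, el in enumerate(mesh.elements + 1, start=1):
            fh.write(str(i) + ", " + ", ".join(str(n) for n in el) + "\n")
        for name, ids in mesh.node_sets.items():
            fh.write(f"*NSET, NSET={name.upper()}\n")
            _write_id_lines(fh, ids)
        for name, ids in mesh.element_sets.items():
            fh.write(f"*ELSET, ELSET={name.upper()}\n")
            _write_id_lines(fh, ids)


def read_inp(path) -> HexMesh:
    """Minimal reader for INP files produced by `write_inp`."""
    nodes, elements = [], []
    node_sets, element_sets = {}, {}
    section, set_name = None, None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("**"):
                continue
            if line.startswith("*"):
                key = line.split(",")[0].upper()
                match = re.search(r"(?:NSET|ELSET)\s*=\s*([\w-]+)", line, flags=re.I)
                set_name = match.group(1).lower() if match else None
                section = key
                if key == "*NSET":
                    node_sets[set_name] = []
                elif key == "*ELSET":
                    element_sets[set_name] = []
                continue
            parts = [p for p in line.replace(",", " ").split() if p]
            if section == "*NODE":
                nodes.append([float(v) for v in parts[1:4]])
            elif section == "*ELEMENT":
                elements.append([int(v) - 1 for v in parts[1:9]])
            elif section == "*NSET":
                node_sets[set_name].extend(int(v) - 1 for v in parts)
            elif section == "*ELSET":
                element_sets[set_name].extend(int(v) - 1 for v in parts)
    nodes = np.asarray(nodes)
    elements = np.asarray(elements, dtype=np.int64)
    element_sets = {k: np.asarray(v, dtype=np.int64) for k, v in element_sets.items()}
    node_sets = {k: np.asarray(v, dtype=np.int64) for k, v in node_sets.items()}
    layer_id = np.zeros(len(elements), dtype=np.int64)
    for name, ids in element_sets.items():
        match = re.fullmatch(r"layer_(\d+)", name)
        if match:
            layer_id[ids] = int(match.group(1))
    if not layer_id.any():
        layer_id[:] = 1
    return HexMesh(nodes, elements, layer_id, node_sets, element_sets)


def write_hex_vtk(mesh: HexMesh, path) -> None:
    """Legacy-VTK export of the hex mesh for visualization."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nseg2fe hex mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(mesh.nodes)} double\n")
        for x, y, z in mesh.nodes:
            fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
        fh.write(f"CELLS {len(mesh.elements)} {len(mesh.elements) * 9}\n")
        for el in mesh.elements:
            fh.write("8 " + " ".join(str(n) for n in el) + "\n")
        fh.write(f"CELL_TYPES {len(mesh.elements)}\n")
        fh.write("\n".join(["12"] * len(mesh.elements)) + "\n")
        fh.write(f"CELL_DATA {len(mesh.elements)}\nSCALARS layer int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(l) for l in mesh.layer_id) + "\n")
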
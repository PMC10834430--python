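"""Dice, Hausdorff/average surface distance, and displaced-area fraction.

The distance tests include an exhaustive point-to-triangle oracle written
independently of the package's spatial-index implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
import trimesh

from conftest import flat_grid_mesh
from seg2fe.mesh_core import GridSpec, TriMesh, VoxelMask
from seg2fe.metrics import (
    area_fraction_over,
    dice,
    evaluate_segmentation,
    iou,
    report_to_csv,
    surface_distances,
)


def brute_force_directed(points, mesh):
    """Exact directed point-to-surface distances by closed-form projection
    onto every triangle (independent re-derivation, no spatial index)."""
    tri = mesh.triangles
    out = np.empty(len(points))
    for i, p in enumerate(points):
        a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
        ab, ac, ap = b - a, c - a, p - a
        d1 = np.einsum("ij,ij->i", ab, ap)
        d2 = np.einsum("ij,ij->i", ac, ap)
        bp = p - b
        d3 = np.einsum("ij,ij->i", ab, bp)
        d4 = np.einsum("ij,ij->i", ac, bp)
        cp = p - c
        d5 = np.einsum("ij,ij->i", ab, cp)
        d6 = np.einsum("ij,ij->i", ac, cp)
        va = d3 * d6 - d4 * d5
        vb = d5 * d2 - d1 * d6
        vc = d1 * d4 - d3 * d2
        with np.errstate(divide="ignore", invalid="ignore"):
            u = np.clip(d1 / (d1 - d3), 0, 1)
            v_ac = np.clip(d2 / (d2 - d6), 0, 1)
            w_bc = np.clip((d4 - d3) / ((d4 - d3) + (d5 - d6)), 0, 1)
            denom = va + vb + vc
            bv, bw = vb / denom, vc / denom
        cand = [a, b, c, a + u[:, None] * ab, a + v_ac[:, None] * ac,
                b + w_bc[:, None] * (c - b)]
        d = np.min([np.linalg.norm(p - q, axis=1) for q in cand], axis=0)
        # the orthogonal foot point only counts when it falls inside
        interior = (va > 0) & (vb > 0) & (vc > 0)
        foot = a + bv[:, None] * ab + bw[:, None] * ac
        d_foot = np.where(interior, np.linalg.norm(p - foot, axis=1), np.inf)
        out[i] = min(d.min(), d_foot.min())
    return out


def block_mask(lo, hi, shape=(6, 6, 6)):
    values = np.zeros(shape, dtype=np.uint8)
    values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = 1
    return VoxelMask(values, (1, 1, 1), (0, 0, 0))


class TestDice:
    def test_identity_is_one(self):
        m = block_mask((1, 1, 1), (4, 4, 4))
        assert dice(m, m) == 1.0

    def test_disjoint_is_zero(self):
        assert dice(block_mask((0, 0, 0), (2, 2, 2)), block_mask((3, 3, 3), (5, 5, 5))) == 0.0

    def test_shifted_block_half_overlap(self):
        # 2x2x2 blocks shifted by one voxel along x: overlap 4 voxels
        a = block_mask((1, 1, 1), (3, 3, 3))
        b = block_mask((2, 1, 1), (4, 3, 3))
        assert dice(a, b) == pytest.approx(2 * 4 / (8 + 8))
        assert iou(a, b) == pytest.approx(4 / 12)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(0)
        a = VoxelMask(rng.integers(0, 2, (5, 5, 5)), (1, 1, 1), (0, 0, 0))
        b = VoxelMask(rng.integers(0, 2, (5, 5, 5)), (1, 1, 1), (0, 0, 0))
        assert dice(a, b) == dice(b, a)
        assert 0 <= dice(a, b) <= 1

    def test_overlap_growth_monotone(self):
        a = block_mask((1, 1, 1), (4, 4, 4))
        b = block_mask((1, 1, 1), (3, 4, 4))
        grown = b.copy()
        grown.values[3, 1, 1] = 1  # add one voxel that is also in a
        assert dice(a, grown) >= dice(a, b)

    def test_both_empty_is_one_with_warning(self):
        e = VoxelMask(np.zeros((3, 3, 3)), (1, 1, 1), (0, 0, 0))
        with pytest.warns(UserWarning):
            assert dice(e, e.copy()) == 1.0

    def test_grid_mismatch_rejected(self):
        a = block_mask((1, 1, 1), (3, 3, 3))
        b = VoxelMask(a.values.copy(), (0.5, 1, 1), (0, 0, 0))
        with pytest.raises(ValueError, match="grid"):
            dice(a, b)


class TestSurfaceDistances:
    def test_identical_meshes_zero(self, sphere5):
        rep = surface_distances(sphere5, sphere5)
        assert rep.hausdorff == 0.0
        assert rep.average == 0.0

    def test_uniform_offset_plane(self, flat_plane):
        shifted = TriMesh(flat_plane.vertices + [0, 0, 2.0], flat_plane.faces)
        rep = surface_distances(flat_plane, shifted)
        assert rep.hausdorff == pytest.approx(2.0)
        assert rep.average == pytest.approx(2.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        a = TriMesh.from_trimesh(trimesh.creation.icosphere(2, radius=4.0))
        jitter = rng.normal(0, 0.3, a.vertices.shape)
        b = TriMesh(a.vertices * 1.1 + jitter + [0.5, -0.3, 0.2], a.faces)
        assert len(a.vertices) <= 500
        rep = surface_distances(a, b)
        d_ab = brute_force_directed(a.vertices, b)
        d_ba = brute_force_directed(b.vertices, a)
        np.testing.assert_allclose(rep.per_vertex_pred_to_gt, d_ab, atol=1e-9)
        np.testing.assert_allclose(rep.per_vertex_gt_to_pred, d_ba, atol=1e-9)
        assert rep.hausdorff == pytest.approx(max(d_ab.max(), d_ba.max()), abs=1e-9)
        assert rep.average == pytest.approx(np.concatenate([d_ab, d_ba]).mean(), abs=1e-9)

    def test_hausdorff_symmetric_and_dominates_average(self, sphere5):
        other = TriMesh(sphere5.vertices * 1.2, sphere5.faces)
        ab = surface_distances(sphere5, other)
        ba = surface_distances(other, sphere5)
        assert ab.hausdorff == ba.hausdorff
        assert ab.hausdorff >= ab.average >= 0


class TestAreaFraction:
    def test_identical_is_zero(self, sphere5):
        assert area_fraction_over(sphere5, sphere5) == 0.0

    def test_full_offset_is_hundred(self, flat_plane):
        shifted = TriMesh(flat_plane.vertices + [0, 0, 2.0], flat_plane.faces)
        assert area_fraction_over(shifted, flat_plane, threshold=1.0) == 100.0

    def test_half_offset_strip(self):
        # strip along x: half at z=0 (on gt), half at z=2 (beyond 1 mm)
        strip = flat_grid_mesh(n=11, extent=10.0)
        verts = strip.vertices.copy()
        verts[:, 2] = np.where(verts[:, 0] >= 5.0, 2.0, 0.0)
        pred = TriMesh(verts, strip.faces)
        gt = flat_grid_mesh(n=11, extent=10.0)
        frac = area_fraction_over(pred, gt, threshold=1.0)
        # vertex-area bookkeeping puts the boundary column partly on each
        # side; allow the discretization band
        assert 35.0 < frac < 65.0

    def test_bad_threshold_rejected(self, sphere5):
        with pytest.raises(ValueError):
            area_fraction_over(sphere5, sphere5, threshold=0.0)


class TestEvaluateSegmentation:
    def test_identical_masks_perfect_scores(self):
        m = block_mask((1, 1, 1), (5, 5, 5), shape=(7, 7, 7))
        rep = evaluate_segmentation(m, m.copy())
        assert rep.dsc == 1.0
        assert rep.hausdorff_mm == 0.0
        assert rep.average_mm == 0.0
        assert rep.area_fraction_gt_1mm == 0.0

    def test_matches_individually_called_ops(self, sphere5):
        jittered = TriMesh(sphere5.vertices * 1.05, sphere5.faces)
        grid = GridSpec.around(sphere5.vertices, 0.5, margin_mm=3.0)
        rep = evaluate_segmentation(jittered, sphere5, grid=grid)
        dist = surface_distances(jittered, sphere5)
        assert rep.hausdorff_mm == pytest.approx(dist.hausdorff)
        assert rep.average_mm == pytest.approx(dist.average)
        assert rep.area_fraction_gt_1mm == pytest.approx(area_fraction_over(jittered, sphere5))
        from seg2fe.mesh_core import voxelize_surface

        assert rep.dsc == pytest.approx(
            dice(voxelize_surface(jittered, grid), voxelize_surface(sphere5, grid))
        )

    def test_csv_layout(self, tmp_path, sphere5):
        rep = evaluate_segmentation(
            sphere5, sphere5, grid=GridSpec.around(sphere5.vertices, 1.0)
        )
        path = tmp_path / "metrics.csv"
        frame = report_to_csv(rep, path)
        assert list(frame.columns) == ["dsc", "hausdorff_mm", "average_mm", "delta_area_pct_gt_1mm"]
        assert path.exists()
        assert rep.dsc_pct == pytest.approx(100.0 * rep.dsc)


class TestDiceProperties:
    """Property-based Dice invariants on arbitrary binary masks."""

    @given(seed=st.integers(0, 2**16), density=st.floats(0.05, 0.95))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_symmetry_range_and_self_similarity(self, seed, density):
        rng = np.random.default_rng(seed)
        a = VoxelMask((rng.random((4, 4, 4)) < density).astype(int), (1, 1, 1), (0, 0, 0))
        b = VoxelMask((rng.random((4, 4, 4)) < density).astype(int), (1, 1, 1), (0, 0, 0))
        if a.n_foreground == 0 and b.n_foreground == 0:
            return
        d = dice(a, b)
        assert d == dice(b, a)
        assert 0.0 <= d <= 1.0
        if a.n_foreground:
            assert dice(a, a.copy()) == 1.0
        assert iou(a, b) <= d + 1e-12
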
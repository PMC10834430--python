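"""Mesh/mask I/O, mask-surface conversion, smoothing, remeshing, sampling."""

import warnings

import nibabel as nib
import numpy as np
import pytest
import trimesh
from scipy.spatial import cKDTree

from conftest import flat_grid_mesh
from seg2fe import mesh_core as mc
from seg2fe.mesh_core import (
    GridSpec,
    MeshFormatError,
    QuadMesh,
    SurfacePointSet,
    TriMesh,
    VoxelMask,
    mask_to_surface,
    poisson_disk_sample,
    read_mask,
    read_mesh,
    remesh_template,
    taubin_smooth,
    uniformize_points,
    voxelize_surface,
    write_mask,
    write_mesh,
)

TET = TriMesh(
    np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]),
    np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]]),
)


class TestMeshIO:
    @pytest.mark.parametrize("fmt", ["ply", "stl", "off", "vtk"])
    def test_round_trip_tetrahedron(self, tmp_path, fmt):
        path = tmp_path / f"tet.{fmt}"
        write_mesh(TET, path)
        back = read_mesh(path)
        if fmt == "stl":  # face soup: vertex order may permute, compare as sets
            assert len(back.vertices) == 4
            d = np.abs(back.vertices[:, None, :] - TET.vertices[None]).sum(axis=2).min(axis=1)
            assert d.max() < 1e-9
        else:
            np.testing.assert_allclose(back.vertices, TET.vertices, atol=1e-6)
            np.testing.assert_array_equal(back.faces, TET.faces)

    def test_stl_soup_deduplicated(self, tmp_path):
        path = tmp_path / "cube.stl"
        box = TriMesh.from_trimesh(trimesh.creation.box())
        write_mesh(box, path)
        back = read_mesh(path)
        assert len(back.vertices) == 8  # 12 triangles x 3 corners welded to 8

    def test_quad_mesh_vtk_round_trip(self, tmp_path):
        quad = QuadMesh(
            np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]), np.array([[0, 1, 2, 3]])
        )
        path = tmp_path / "quad.vtk"
        write_mesh(quad, path)
        back = read_mesh(path)
        assert isinstance(back, QuadMesh)
        np.testing.assert_allclose(back.vertices, quad.vertices)

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.ply"
        path.write_text("")
        with pytest.raises(MeshFormatError):
            read_mesh(path)

    def test_unsupported_format_errors(self, tmp_path):
        with pytest.raises(MeshFormatError, match="unsupported"):
            write_mesh(TET, tmp_path / "m.obj2", fmt="obj2")

    def test_degenerate_face_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            TriMesh(np.eye(3), np.array([[0, 1, 1]]))


class TestMaskIO:
    def test_oai_spacing_preserved(self, tmp_path):
        values = np.zeros((8, 8, 8), dtype=np.uint8)
        values[2:6, 2:6, 2:6] = 1
        mask = VoxelMask(values, (0.36, 0.36, 0.7), (0, 0, 0))
        path = tmp_path / "m.nii.gz"
        write_mask(mask, path)
        back = read_mask(path)
        np.testing.assert_allclose(back.spacing, (0.36, 0.36, 0.7))
        np.testing.assert_array_equal(back.values, values)

    def test_all_zero_mask_warns(self, tmp_path):
        path = tmp_path / "z.nii.gz"
        nib.save(nib.Nifti1Image(np.zeros((4, 4, 4), dtype=np.uint8), np.eye(4)), path)
        with pytest.warns(UserWarning, match="zero foreground"):
            mask = read_mask(path)
        assert mask.n_foreground == 0

    def test_multi_label_collapsed_to_binary(self, tmp_path):
        labels = np.zeros((5, 5, 5), dtype=np.int16)
        labels[1:3, 1:3, 1:3] = 2
        path = tmp_path / "l.nii.gz"
        nib.save(nib.Nifti1Image(labels, np.eye(4)), path)
        mask = read_mask(path)
        assert set(np.unique(mask.values)) == {0, 1}
        assert mask.n_foreground == 8

    def test_oblique_affine_rejected(self, tmp_path):
        affine = np.eye(4)
        affine[0, 1] = 0.3
        path = tmp_path / "o.nii.gz"
        nib.save(nib.Nifti1Image(np.ones((4, 4, 4), dtype=np.uint8), affine), path)
        with pytest.raises(ValueError, match="oblique"):
            read_mask(path)

    def test_negative_step_axis_flipped(self, tmp_path):
        values = np.zeros((6, 4, 4), dtype=np.uint8)
        values[0, :, :] = 1
        affine = np.diag([-1.0, 1.0, 1.0, 1.0])
        path = tmp_path / "f.nii.gz"
        nib.save(nib.Nifti1Image(values, affine), path)
        mask = read_mask(path)
        assert mask.spacing[0] == 1.0
        assert mask.values[-1].sum() == 16  # flipped to the far end


class TestMaskSurfaceConversion:
    def test_sphere_surface_area(self):
        grid = GridSpec((0.5, 0.5, 0.5), (-6, -6, -6), (25, 25, 25))
        xs = [grid.origin[a] + np.arange(grid.shape[a]) * 0.5 for a in range(3)]
        xg, yg, zg = np.meshgrid(*xs, indexing="ij")
        ball = (xg**2 + yg**2 + zg**2 <= 25).astype(np.uint8)
        surf = mask_to_surface(VoxelMask(ball, grid.spacing, grid.origin))
        assert surf.is_closed()
        assert abs(surf.area - 4 * np.pi * 25) / (4 * np.pi * 25) < 0.10

    def test_single_voxel_closed_genus0(self):
        values = np.zeros((5, 5, 5), dtype=np.uint8)
        values[2, 2, 2] = 1
        surf = mask_to_surface(VoxelMask(values, (1, 1, 1), (0, 0, 0)))
        assert surf.is_closed()
        euler = len(surf.vertices) - len(surf.edges_unique()) + len(surf.faces)
        assert euler == 2

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            mask_to_surface(VoxelMask(np.zeros((3, 3, 3)), (1, 1, 1), (0, 0, 0)))

    def test_voxelize_sphere_volume(self, sphere5):
        grid = GridSpec.around(sphere5.vertices, 0.5)
        mask = voxelize_surface(sphere5, grid)
        vol = mask.n_foreground * np.prod(mask.spacing)
        true = 4.0 / 3.0 * np.pi * 125.0
        assert abs(vol - true) / true < 0.05

    def test_voxelize_round_trip_dsc(self, sphere5):
        grid = GridSpec.around(sphere5.vertices, 0.5)
        mask = voxelize_surface(sphere5, grid)
        mask2 = voxelize_surface(mask_to_surface(mask), grid)
        inter = np.logical_and(mask.values, mask2.values).sum()
        dsc = 2.0 * inter / (mask.n_foreground + mask2.n_foreground)
        assert dsc > 0.95

    def test_mesh_outside_grid_all_zero(self, sphere5):
        grid = GridSpec((1, 1, 1), (100, 100, 100), (10, 10, 10))
        assert voxelize_surface(sphere5, grid).n_foreground == 0

    def test_open_mesh_rejected_with_edge_count(self, flat_plane):
        with pytest.raises(ValueError, match=r"\d+ boundary edges"):
            voxelize_surface(flat_plane, GridSpec((1, 1, 1), (0, 0, 0), (5, 5, 5)))


class TestSmoothing:
    def test_zero_iterations_is_identity(self, sphere5):
        out = taubin_smooth(sphere5, iterations=0)
        np.testing.assert_array_equal(out.vertices, sphere5.vertices)

    def test_noise_reduced_on_sphere(self, sphere5):
        rng = np.random.default_rng(0)
        noisy = TriMesh(sphere5.vertices + rng.normal(0, 0.2, sphere5.vertices.shape), sphere5.faces)
        before = np.abs(np.linalg.norm(noisy.vertices, axis=1) - 5.0).mean()
        smoothed = taubin_smooth(noisy)
        after = np.abs(np.linalg.norm(smoothed.vertices, axis=1) - 5.0).mean()
        assert after < before

    def test_shrinks_less_than_pure_laplacian(self, sphere5):
        taubin = taubin_smooth(sphere5, iterations=10)
        laplacian = taubin_smooth(sphere5, lam=0.5, mu=-1e-12, iterations=10)
        r_t = np.linalg.norm(taubin.vertices, axis=1).mean()
        r_l = np.linalg.norm(laplacian.vertices, axis=1).mean()
        assert 5.0 - r_t < 5.0 - r_l

    def test_parameter_validation(self, sphere5):
        with pytest.raises(ValueError):
            taubin_smooth(sphere5, lam=-0.1)
        with pytest.raises(ValueError):
            taubin_smooth(sphere5, mu=0.1)


class TestRemesh:
    def test_sphere_downsample_fidelity(self):
        dense = TriMesh.from_trimesh(trimesh.creation.icosphere(5, radius=10.0))
        out = remesh_template(dense, 2000)
        assert abs(len(out.vertices) - 2000) <= 0.1 * 2000
        from seg2fe.metrics import surface_distances

        assert surface_distances(out, dense).hausdorff < 0.1

    def test_target_near_current_is_identity(self, sphere5):
        out = remesh_template(sphere5, len(sphere5.vertices))
        np.testing.assert_array_equal(out.vertices, sphere5.vertices)

    def test_tiny_target_rejected(self, sphere5):
        with pytest.raises(ValueError):
            remesh_template(sphere5, 3)


class TestSampling:
    def test_seed_determinism(self, sphere5):
        a = poisson_disk_sample(sphere5, 200, seed=42)
        b = poisson_disk_sample(sphere5, 200, seed=42)
        np.testing.assert_array_equal(a.points, b.points)

    def test_packing_bound_on_square(self, flat_plane):
        # unit-area square (rescale the 10x10 plane)
        unit = TriMesh(flat_plane.vertices / 10.0, flat_plane.faces)
        pts = poisson_disk_sample(unit, 100, seed=0)
        d, _ = cKDTree(pts.points).query(pts.points, k=2)
        r_max = np.sqrt(1.0 / (2 * np.sqrt(3.0) * 100))
        assert d[:, 1].min() >= 0.5 * r_max

    def test_points_on_surface(self, sphere5):
        pts = poisson_disk_sample(sphere5, 100, seed=1)
        assert sphere5.surface_query().distance(pts.points).max() < 1e-6

    def test_uniform_grid_is_fixed_point(self):
        # grid at cell centers of the square partition: spring rest length
        # equals the spacing exactly, so forces vanish
        plane = flat_grid_mesh(n=2, extent=8.0)
        s = 1.0
        gx, gy = np.meshgrid(np.arange(0.5, 8, s), np.arange(0.5, 8, s), indexing="ij")
        grid_pts = SurfacePointSet(np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)]))
        out = uniformize_points(grid_pts, plane, iterations=5)
        assert np.abs(out.points - grid_pts.points).max() < 1e-3 * s

    def test_clumped_sphere_cv_drops(self, sphere5):
        rng = np.random.default_rng(2)
        base = poisson_disk_sample(sphere5, 150, seed=3).points
        clumped = sphere5.surface_query().project(base + rng.normal(0, 0.4, base.shape))
        pts = SurfacePointSet(clumped)

        def cv(p):
            d, _ = cKDTree(p).query(p, k=2)
            return d[:, 1].std() / d[:, 1].mean()

        out = uniformize_points(pts, sphere5, iterations=20)
        assert cv(out.points) <= 0.7 * cv(pts.points)
        assert sphere5.surface_query().distance(out.points).max() < 1e-6

    def test_zero_iterations_identity(self, sphere5):
        pts = poisson_disk_sample(sphere5, 50, seed=4)
        out = uniformize_points(pts, sphere5, iterations=0)
        np.testing.assert_array_equal(out.points, pts.points)

    def test_too_few_points_rejected(self, sphere5):
        with pytest.raises(ValueError):
            uniformize_points(SurfacePointSet(np.zeros((3, 3))), sphere5)
        with pytest.raises(ValueError):
            poisson_disk_sample(sphere5, 3, seed=0)
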
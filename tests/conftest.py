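"""Shared fixtures: analytic test surfaces and a small prebuilt shape model.

Everything is generated at test time; heavy objects (the shape-model
populations) are session-scoped so the SSM, fitting and acceptance tests
share one build.
"""

import numpy as np
import pytest
import trimesh

from seg2fe import mesh_core as mc
from seg2fe import ssm as ssm_mod
from seg2fe import synthetic_data as sd


@pytest.fixture(scope="session")
def sphere5():
    """Icosphere of radius 5 mm (closed, genus 0)."""
    return mc.TriMesh.from_trimesh(trimesh.creation.icosphere(3, radius=5.0))


@pytest.fixture(scope="session")
def fine_sphere15():
    """Finely tessellated sphere of radius 15 mm (sub-mm facet sag)."""
    return mc.TriMesh.from_trimesh(trimesh.creation.icosphere(5, radius=15.0))


@pytest.fixture(scope="session")
def bone_mesh():
    """One distal-femur-like synthetic bone at the mean latent parameters."""
    return sd.synth_bone(11.0, 24.0, 9.0)


def flat_grid_mesh(n=6, extent=10.0, z=0.0):
    """Triangulated square plane mesh, n x n vertices."""
    xs, ys = np.meshgrid(np.linspace(0, extent, n), np.linspace(0, extent, n), indexing="ij")
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.full(n * n, z)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces += [[a, a + n, a + n + 1], [a, a + n + 1, a + 1]]
    return mc.TriMesh(verts, np.asarray(faces))


@pytest.fixture()
def flat_plane():
    return flat_grid_mesh()


@pytest.fixture(scope="session")
def small_population():
    """Small synthetic population (8 shapes, 2 active latent modes)."""
    spec = sd.PopulationSpec(n_shapes=8, seed=3)
    meshes, params = sd.synth_population(spec)
    return meshes, params


@pytest.fixture(scope="session")
def small_model(small_population):
    """Shape model built from the small population at a low point budget."""
    meshes, _ = small_population
    template = sd.synth_bone(11.0, 24.0, 9.0)
    cfg = ssm_mod.CorrespondenceConfig(n_points=300, seed=5, cpd_max_iter=80)
    model, aligned = ssm_mod.build_from_meshes(template, meshes, cfg, variance_fraction=0.95)
    return model, aligned


# --- study-condition population for the acceptance criteria -----------------

ACCEPT_POP_SEED = 7
ACCEPT_CORR_SEED = 11
ACCEPT_N_SHAPES = 30
ACCEPT_N_POINTS = 600


@pytest.fixture(scope="session")
def acceptance_population():
    spec = sd.PopulationSpec(n_shapes=ACCEPT_N_SHAPES, seed=ACCEPT_POP_SEED)
    meshes, params = sd.synth_population(spec)
    return meshes, params


@pytest.fixture(scope="session")
def acceptance_model(acceptance_population):
    """Models under the study conditions (30 shapes, 600 points).

    Returns (full-rank model, 95%-variance model, aligned sets); both models
    share one correspondence build.
    """
    meshes, _ = acceptance_population
    template = sd.synth_bone(11.0, 24.0, 9.0)
    cfg = ssm_mod.CorrespondenceConfig(n_points=ACCEPT_N_POINTS, seed=ACCEPT_CORR_SEED)
    model_full, aligned = ssm_mod.build_from_meshes(template, meshes, cfg, variance_fraction=1.0)
    model95 = ssm_mod.build_ssm(aligned, variance_fraction=0.95, template_mesh=template)
    return model_full, model95, aligned
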
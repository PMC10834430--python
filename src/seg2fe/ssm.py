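"""Statistical shape model: construction from corresponded surfaces,
instance generation (Shape = M + PC * b), and model-to-surface fitting.

The model is a point-distribution model: K landmark points per shape, a
mean M, orthonormal principal components PC and per-mode variances from PCA
of the training set after Procrustes alignment. A template triangle mesh in
correspondence with the model points carries the tessellation; instances
are meshed by warping that template with a thin-plate spline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from . import mesh_core
from .mesh_core import SurfacePointSet, TriMesh
from .registration import (
    CorrespondedSets,
    RegistrationWarning,
    SimilarityTransform,
    coarse_align,
    cpd_rigid,
    gpa,
    icp_refine,
    robust_initial_pose,
    tps_apply,
    tps_fit,
    umeyama,
)

__all__ = [
    "ShapeModel",
    "ShapeCoefficients",
    "FitResult",
    "CorrespondenceConfig",
    "correspond",
    "build_ssm",
    "build_from_meshes",
    "ssm_instance",
    "ssm_fit",
    "instance_mesh",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class ShapeModel:
    """Point-distribution model with a tessellated template.

    mean : (K, 3) mm — M
    components : (n_modes, K, 3), each flattened component has unit norm — PC
    variances : (n_modes,) mm^2, descending
    template_mesh : TriMesh warped into the mean frame, in correspondence
        with the model points; carries connectivity to every instance
    n_training : size of the training population
    """

    mean: np.ndarray
    components: np.ndarray
    variances: np.ndarray
    template_mesh: TriMesh
    n_training: int
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64).reshape(-1, 3)
        self.components = np.asarray(self.components, dtype=np.float64)
        self.variances = np.asarray(self.variances, dtype=np.float64).reshape(-1)
        if self.components.ndim != 3 or self.components.shape[1:] != self.mean.shape:
            raise ValueError("components must be (n_modes, K, 3) matching the mean")
        if len(self.components) != len(self.variances):
            raise ValueError("one variance per component required")
        if np.any(np.diff(self.variances) > 1e-12):
            raise ValueError("variances must be sorted descending")
        flat = self.components.reshape(len(self.components), -1)
        gram = flat @ flat.T
        if len(flat) and np.abs(gram - np.eye(len(flat))).max() > 1e-8:
            raise ValueError("components must be mutually orthonormal")

    @property
    def n_modes(self) -> int:
        return len(self.variances)

    @property
    def n_points(self) -> int:
        return len(self.mean)

    @property
    def sigmas(self) -> np.ndarray:
        return np.sqrt(self.variances)

    @property
    def scale(self) -> float:
        """RMS extent of the mean shape about its centroid (mm)."""
        c = self.mean - self.mean.mean(axis=0)
        return float(np.sqrt(np.mean(np.sum(c**2, axis=1))))


@dataclass
class ShapeCoefficients:
    """Per-mode weights b of an SSM instance (mm units along each mode)."""

    b: np.ndarray

    def __post_init__(self):
        self.b = np.asarray(self.b, dtype=np.float64).reshape(-1)

    def in_sigma_units(self, model: ShapeModel) -> np.ndarray:
        return self.b / model.sigmas[: len(self.b)]

    def __len__(self):
        return len(self.b)


@dataclass
class FitResult:
    """Outcome of fitting an SSM to a target surface."""

    b: ShapeCoefficients
    pose: SimilarityTransform
    fitted_points: np.ndarray
    fitted_mesh: TriMesh
    residual_rms: float
    iterations: int
    converged: bool = True


@dataclass
class CorrespondenceConfig:
    """Knobs for dense correspondence (template -> each sample).

    The non-rigid stage is a multiscale coherent closest-point transport:
    at each level the template points move by a Gaussian-smoothed (over the
    template's own neighborhood graph) closest-point displacement field,
    with the kernel width shrinking level by level. `transport_levels` are
    (kernel width in median point spacings, neighborhood size) pairs.
    """

    n_points: int = 5000
    seed: int = 0
    uniformize_iterations: int = 10
    cpd_w: float = 0.1
    cpd_tol: float = 1e-6
    cpd_max_iter: int = 120
    rigid_with_scale: bool = True
    transport_levels: tuple = ((8.0, 64), (4.0, 48), (2.0, 24), (1.0, 12))
    transport_iterations: int = 6
    transport_step: float = 0.7


# ---------------------------------------------------------------------------
# correspondence
# ---------------------------------------------------------------------------


def _sampled_points(mesh: TriMesh, cfg: CorrespondenceConfig, seed: int, mesh_id: str) -> SurfacePointSet:
    pts = mesh_core.poisson_disk_sample(mesh, cfg.n_points, seed=seed, mesh_id=mesh_id)
    return mesh_core.uniformize_points(pts, mesh, iterations=cfg.uniformize_iterations)


def _deterministic_template_points(mesh: TriMesh, cfg: CorrespondenceConfig) -> SurfacePointSet:
    """Well-spread template points without randomness.

    Farthest-point selection over the mesh's own vertices and face centroids
    (start: the point farthest from the centroid), then on-surface
    uniformization. Keeping the template landmarks a pure function of the
    template geometry makes the whole correspondence deterministic.
    """
    pool = np.vstack([mesh.vertices, mesh.triangles.mean(axis=1)])
    start = int(np.argmax(np.linalg.norm(pool - pool.mean(axis=0), axis=1)))
    chosen = np.empty(cfg.n_points, dtype=np.int64)
    chosen[0] = start
    dist = np.linalg.norm(pool - pool[start], axis=1)
    for k in range(1, cfg.n_points):
        chosen[k] = int(np.argmax(dist))
        np.minimum(dist, np.linalg.norm(pool - pool[chosen[k]], axis=1), out=dist)
    pts = SurfacePointSet(pool[chosen], "template")
    return mesh_core.uniformize_points(pts, mesh, iterations=cfg.uniformize_iterations)


def _transport_smoothers(points: np.ndarray, cfg: CorrespondenceConfig):
    """Precompute the Gaussian displacement smoothers on the template points."""
    from scipy.spatial import cKDTree

    tree = cKDTree(points)
    nn_d, _ = tree.query(points, k=2)
    spacing = float(np.median(nn_d[:, 1]))
    smoothers = []
    for width_factor, k in cfg.transport_levels:
        k_eff = min(int(k), len(points))
        dist, neigh = tree.query(points, k=k_eff)
        weights = np.exp(-((dist / (width_factor * spacing)) ** 2))
        weights /= weights.sum(axis=1, keepdims=True)
        smoothers.append((weights, neigh))
    return smoothers


def correspond(template: TriMesh, samples, config: CorrespondenceConfig | None = None) -> CorrespondedSets:
    """Establish template-indexed dense correspondence across sample surfaces.

    For each sample: uniform blue-noise sampling of both surfaces; coarse
    similarity alignment of the sample onto the template (centroid, centroid
    size, principal axes); CPD rigid/similarity registration of the template
    point set onto the sample; non-rigid multiscale coherent closest-point
    transport of the template points onto the exact sample surface; final
    per-point projection; map back to the sample's own frame. Point i of
    every returned set is anatomically corresponding.

    The non-rigid stage deliberately moves points only by *smoothed normal*
    displacement fields: tangential coordinates are transported from the
    template rather than re-assigned by point-density matching, which keeps
    the correspondence consistent across the population (low-dimensional
    populations stay low-dimensional after PCA).
    """
    cfg = config or CorrespondenceConfig()
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to build correspondence")
    tpl_pts = _deterministic_template_points(template, cfg)
    T = tpl_pts.points
    smoothers = _transport_smoothers(T, cfg)
    template_query = template.surface_query()

    sets = []
    for idx, sample in enumerate(samples):
        try:
            # the rigid chain runs on deterministic vertex subsets: any
            # sampling noise in the pose estimate would be absorbed by the
            # non-rigid stage as spurious deformation
            smp_verts = _subsample(np.asarray(sample.vertices), max(cfg.n_points, 800))
            # moment alignment is ambiguous for near-degenerate covariances;
            # disambiguate against the template surface before CPD
            to_template = robust_initial_pose(
                smp_verts,
                template_query,
                coarse_align(smp_verts, tpl_pts),
                with_scale=cfg.rigid_with_scale,
            )

            rigid = cpd_rigid(
                T,
                to_template.apply(smp_verts),
                w=cfg.cpd_w,
                tol=cfg.cpd_tol,
                max_iter=cfg.cpd_max_iter,
                with_scale=cfg.rigid_with_scale,
            )
            sample_in_tpl = TriMesh(to_template.apply(sample.vertices), sample.faces)
            query = sample_in_tpl.surface_query()
            current = rigid.apply(T)
            # exact-surface rigid polish: the CPD estimate carries the blue-
            # noise sampling error, which the transport would otherwise
            # absorb as spurious deformation
            polish = icp_refine(current, query, iterations=5, with_scale=cfg.rigid_with_scale)
            current = polish.apply(current)
            base = current.copy()
            # diffusion-style transport: the *accumulated* displacement from
            # the rigid-posed template is smoothed each step, so tangential
            # stretch is redistributed elastically and consistently
            for weights, neigh in smoothers:
                for _ in range(cfg.transport_iterations):
                    disp = query.project(current) - current
                    u = current + cfg.transport_step * disp - base
                    current = base + np.einsum("ik,ikj->ij", weights, u[neigh])
            projected_tpl = query.project(current)
            projected = to_template.inverse().apply(projected_tpl)
        except Exception as exc:
            raise RuntimeError(f"correspondence failed for sample {idx}: {exc}") from exc
        sets.append(projected)
    return CorrespondedSets(sets, template_points=T)


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------


def build_ssm(
    corr: CorrespondedSets,
    variance_fraction: float = 0.95,
    template_mesh: TriMesh | None = None,
) -> ShapeModel:
    """PCA of Procrustes-aligned corresponded sets -> point-distribution model.

    Modes are retained (in descending variance order) until
    `variance_fraction` of the total variance is covered; tied trailing
    eigenvalues are kept together. `template_mesh` must be in the original
    template frame: it is TPS-warped onto the mean via the stored template
    point set so the model's tessellation is in correspondence (passing an
    already-warped mesh would warp it twice).
    """
    if not 0 < variance_fraction <= 1:
        raise ValueError("variance_fraction must be in (0, 1]")
    if corr.n_sets < 2:
        raise ValueError("need at least 2 corresponded sets")
    data = np.stack(corr.sets)  # (n, K, 3)
    n = len(data)
    mean = data.mean(axis=0)
    X = (data - mean).reshape(n, -1)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    variances = S**2 / (n - 1)
    keep = min(n - 1, len(variances))
    variances = variances[:keep]
    Vt = Vt[:keep]

    total = variances.sum()
    if total <= 0:
        raise ValueError("no shape variance in the training set")
    cum = np.cumsum(variances) / total
    n_modes = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
    # keep ties with the last retained eigenvalue
    while n_modes < keep and np.isclose(variances[n_modes], variances[n_modes - 1], rtol=1e-9):
        n_modes += 1
    components = Vt[:n_modes].reshape(n_modes, -1, 3)

    if template_mesh is None:
        raise ValueError("template_mesh is required to tessellate model instances")
    if corr.template_points is not None:
        warp = tps_fit(corr.template_points, mean)
        tpl = TriMesh(tps_apply(warp, template_mesh.vertices), template_mesh.faces.copy())
    else:
        tpl = template_mesh.copy()
    return ShapeModel(
        mean=mean,
        components=components,
        variances=variances[:n_modes],
        template_mesh=tpl,
        n_training=n,
        metadata={"variance_fraction": variance_fraction, "total_variance": float(total)},
    )


def build_from_meshes(
    template: TriMesh,
    samples,
    config: CorrespondenceConfig | None = None,
    variance_fraction: float = 0.95,
):
    """Full SSM construction: correspond -> GPA -> PCA.

    Returns (model, aligned_sets). The template mesh is warped into the mean
    frame and stored on the model.
    """
    cfg = config or CorrespondenceConfig()
    corr = correspond(template, samples, cfg)
    aligned = gpa(corr.sets)
    aligned.template_points = corr.template_points
    model = build_ssm(aligned, variance_fraction=variance_fraction, template_mesh=template)
    model.metadata.update({"n_points": cfg.n_points, "seed": cfg.seed})
    return model, aligned


# ---------------------------------------------------------------------------
# instances and fitting
# ---------------------------------------------------------------------------


def ssm_instance(model: ShapeModel, b) -> np.ndarray:
    """Shape = M + PC * b (b may address a leading subset of modes)."""
    if isinstance(b, ShapeCoefficients):
        b = b.b
    b = np.asarray(b, dtype=np.float64).reshape(-1)
    if len(b) > model.n_modes:
        raise ValueError(f"{len(b)} coefficients for a {model.n_modes}-mode model")
    if len(b) == 0:
        return model.mean.copy()
    return model.mean + np.tensordot(b, model.components[: len(b)], axes=1)


def instance_mesh(model: ShapeModel, instance_points: np.ndarray) -> TriMesh:
    """Tessellate an SSM instance by TPS-warping the template mesh.

    The warp is fitted from the model's mean points to the instance points
    and applied to the template vertices, so every instance shares the
    template connectivity. A TPS fitted between identical point sets is the
    identity, hence the mean instance reproduces the template exactly.
    """
    instance_points = np.asarray(instance_points, dtype=np.float64).reshape(-1, 3)
    if len(instance_points) != model.n_points:
        raise ValueError("instance point count does not match the model")
    warp = tps_fit(model.mean, instance_points)
    return TriMesh(tps_apply(warp, model.template_mesh.vertices), model.template_mesh.faces.copy())


def _subsample(points: np.ndarray, n: int) -> np.ndarray:
    if len(points) <= n:
        return points
    idx = np.linspace(0, len(points) - 1, n).astype(np.int64)
    return points[idx]


def _alternating_fit(model, query, pose, clamp_sigma, lam_b, tol, max_iter, fit_scale):
    """Core active-shape alternation from a given starting pose."""
    b = np.zeros(model.n_modes)
    sigma2 = model.variances
    posed = pose.apply(model.mean)
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        _, closest, _ = query.query(posed)
        # shape update in the model frame
        y_model = pose.inverse().apply(closest)
        r = (y_model - model.mean).ravel()
        proj = model.components.reshape(model.n_modes, -1) @ r
        b = proj / (1.0 + lam_b / sigma2)
        b = np.clip(b, -clamp_sigma * model.sigmas, clamp_sigma * model.sigmas)
        instance = ssm_instance(model, b)
        # pose update on the fresh correspondences
        pose = umeyama(instance, closest, with_scale=fit_scale)
        new_posed = pose.apply(instance)
        movement = float(np.mean(np.linalg.norm(new_posed - posed, axis=1)))
        posed = new_posed
        if movement < tol:
            converged = True
            break
    residual = float(np.sqrt(np.mean(query.distance(posed) ** 2)))
    return b, pose, posed, residual, iteration, converged


def ssm_fit(
    model: ShapeModel,
    target: TriMesh,
    clamp_sigma: float = 3.0,
    lam_b: float = 1.0,
    tol: float = 1e-3,
    max_iter: int = 50,
    fit_scale: bool = True,
    make_mesh: bool = True,
    n_pose_starts: int = 4,
) -> FitResult:
    """Fit the shape model to a target surface (active-shape style).

    Alternates: (1) pose update — CPD rigid/similarity at initialization,
    then closed-form similarity refits on the running closest-point
    correspondences; (2) closest-point targets on the target surface for
    every model point; (3) regularized linear solve for b with Tikhonov
    weight `lam_b` in sigma-normalized units and a hard +/- `clamp_sigma`
    plausibility clamp per mode. Stops when the mean point movement drops
    below `tol` (mm). The clamp is what enforces anatomical plausibility:
    holes and speckle noise on the target pull the closest-point targets,
    but the solution stays inside the model's plausible shape space.

    Because moment-based initialization can land in a mirrored/rotated
    basin on near-symmetric bones — and the basins only separate once the
    shape is allowed to deform — short triage fits are run from the
    `n_pose_starts` best-scoring distinct pose candidates and the winner
    (smallest triage residual) is fitted to convergence.
    """
    query = target.surface_query()
    target_samples = _subsample(np.asarray(target.vertices), 600)

    candidates = robust_initial_pose(
        model.mean,
        query,
        coarse_align(model.mean, target_samples),
        with_scale=fit_scale,
        return_top=max(1, n_pose_starts),
    )
    if not isinstance(candidates, list):
        candidates = [candidates]

    triage_iters = min(12, max_iter)
    best = None
    for start in candidates:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RegistrationWarning)
            refine = cpd_rigid(
                _subsample(start.apply(model.mean), 600),
                target_samples,
                with_scale=fit_scale,
                max_iter=80,
            )
        pose0 = refine.compose(start)
        result = _alternating_fit(model, query, pose0, clamp_sigma, lam_b, tol, triage_iters, fit_scale)
        if best is None or result[3] < best[3]:
            best = result
    if not best[5] and max_iter > triage_iters:  # triage winner not yet converged
        cont = _alternating_fit(
            model, query, best[1], clamp_sigma, lam_b, tol, max_iter - triage_iters, fit_scale
        )
        best = cont[:4] + (triage_iters + cont[4], cont[5])
    b, pose, posed, residual, iteration, converged = best
    if not converged:
        warnings.warn("ssm_fit stopped at max_iter without convergence", RegistrationWarning, stacklevel=2)

    if make_mesh:
        inst_mesh = instance_mesh(model, ssm_instance(model, b))
        fitted_mesh = TriMesh(pose.apply(inst_mesh.vertices), inst_mesh.faces)
    else:
        fitted_mesh = None
    return FitResult(
        b=ShapeCoefficients(b),
        pose=pose,
        fitted_points=posed,
        fitted_mesh=fitted_mesh,
        residual_rms=residual,
        iterations=iteration,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_model(model: ShapeModel, path) -> None:
    with h5py.File(path, "w") as fh:
        fh["mean"] = model.mean
        fh["components"] = model.components
        fh["variances"] = model.variances
        fh["template_vertices"] = model.template_mesh.vertices
        fh["template_faces"] = model.template_mesh.faces
        fh.attrs["n_training"] = model.n_training
        for key, val in model.metadata.items():
            fh.attrs[f"meta_{key}"] = val


def load_model(path) -> ShapeModel:
    with h5py.File(path, "r") as fh:
        meta = {
            key[5:]: (val.item() if hasattr(val, "item") else val)
            for key, val in fh.attrs.items()
            if key.startswith("meta_")
        }
        return ShapeModel(
            mean=fh["mean"][()],
            components=fh["components"][()],
            variances=fh["variances"][()],
            template_mesh=TriMesh(fh["template_vertices"][()], fh["template_faces"][()]),
            n_training=int(fh.attrs["n_training"]),
            metadata=meta,
        )
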
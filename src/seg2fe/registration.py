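"""Point-set registration: coarse similarity alignment, coherent point
drift (rigid/similarity and non-rigid), generalized Procrustes analysis,
and thin-plate-spline transforms.

Conventions: transforms map *moving/source* coordinates into the
*reference/target* frame; all lengths in mm. Every routine here is
deterministic given its inputs (no internal randomness).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from .mesh_core import SurfacePointSet

__all__ = [
    "SimilarityTransform",
    "TPSTransform",
    "CorrespondedSets",
    "RegistrationWarning",
    "coarse_align",
    "cpd_rigid",
    "cpd_nonrigid",
    "gpa",
    "tps_fit",
    "tps_apply",
    "kabsch",
    "umeyama",
    "save_transform",
    "load_transform",
    "save_points_csv",
    "load_points_csv",
]


class RegistrationWarning(UserWarning):
    """Emitted when an iterative registration stops at max_iter."""


def _as_points(obj) -> np.ndarray:
    if isinstance(obj, SurfacePointSet):
        return obj.points
    return np.ascontiguousarray(obj, dtype=np.float64).reshape(-1, 3)


# ---------------------------------------------------------------------------
# transform types
# ---------------------------------------------------------------------------


@dataclass
class SimilarityTransform:
    """x -> scale * rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0
    converged: bool = field(default=True, compare=False)

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        self.scale = float(self.scale)
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be a proper rotation (det=+1)")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(np.eye(3), np.zeros(3), 1.0)

    def apply(self, points) -> np.ndarray:
        p = _as_points(points)
        return self.scale * (p @ self.rotation.T) + self.translation

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """self o other: apply `other` first, then `self`."""
        return SimilarityTransform(
            self.rotation @ other.rotation,
            self.scale * (other.translation @ self.rotation.T) + self.translation,
            self.scale * other.scale,
        )

    def inverse(self) -> "SimilarityTransform":
        rot = self.rotation.T
        return SimilarityTransform(rot, -(self.translation @ self.rotation) / self.scale, 1.0 / self.scale)


@dataclass
class TPSTransform:
    """Thin-plate spline in 3-D with kernel U(r) = r.

    f(x) = affine_matrix @ x + affine_offset + sum_k weights[k] * |x - c_k|

    The weights satisfy the TPS side conditions (orthogonality to constants
    and to the control-point coordinates), which makes the affine/non-rigid
    decomposition unique.
    """

    control_points: np.ndarray
    affine_matrix: np.ndarray
    affine_offset: np.ndarray
    weights: np.ndarray
    regularization: float = 0.0

    def __post_init__(self):
        self.control_points = np.asarray(self.control_points, dtype=np.float64).reshape(-1, 3)
        self.affine_matrix = np.asarray(self.affine_matrix, dtype=np.float64).reshape(3, 3)
        self.affine_offset = np.asarray(self.affine_offset, dtype=np.float64).reshape(3)
        self.weights = np.asarray(self.weights, dtype=np.float64).reshape(-1, 3)
        if len(self.weights) != len(self.control_points):
            raise ValueError("one weight row per control point required")
        if self.regularization < 0:
            raise ValueError("regularization must be >= 0")

    def side_condition_residual(self) -> float:
        P = np.column_stack([np.ones(len(self.control_points)), self.control_points])
        return float(np.abs(P.T @ self.weights).max())


@dataclass
class CorrespondedSets:
    """Point sets in dense correspondence: row i matches across all sets."""

    sets: list
    mean: np.ndarray = None
    template_points: np.ndarray = None

    def __post_init__(self):
        self.sets = [np.ascontiguousarray(s, dtype=np.float64).reshape(-1, 3) for s in self.sets]
        k = {len(s) for s in self.sets}
        if len(k) != 1:
            raise ValueError(f"all corresponded sets must share one K, got {sorted(k)}")
        if self.mean is None:
            self.mean = np.mean(self.sets, axis=0)
        else:
            self.mean = np.asarray(self.mean, dtype=np.float64).reshape(-1, 3)

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    @property
    def n_points(self) -> int:
        return len(self.sets[0])


# ---------------------------------------------------------------------------
# closed-form alignments
# ---------------------------------------------------------------------------


def kabsch(source: np.ndarray, target: np.ndarray):
    """Optimal rotation + translation mapping source onto target (LSQ)."""
    sc, tc = source.mean(axis=0), target.mean(axis=0)
    H = (source - sc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = tc - R @ sc
    return R, t


def umeyama(source: np.ndarray, target: np.ndarray, with_scale: bool = True) -> SimilarityTransform:
    """Optimal similarity (or rigid) transform source -> target (LSQ)."""
    sc, tc = source.mean(axis=0), target.mean(axis=0)
    src, tgt = source - sc, target - tc
    H = src.T @ tgt / len(source)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    if with_scale:
        var_src = (src**2).sum() / len(source)
        s = float((S * np.diag(D)).sum() / var_src)
    else:
        s = 1.0
    return SimilarityTransform(R, tc - s * R @ sc, s)


def octahedral_rotations() -> np.ndarray:
    """The 24 proper rotations of the axis-aligned octahedral group."""
    mats = []
    for perm in ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)):
        for sx in (1.0, -1.0):
            for sy in (1.0, -1.0):
                for sz in (1.0, -1.0):
                    R = np.zeros((3, 3))
                    for row, (col, s) in enumerate(zip(perm, (sx, sy, sz))):
                        R[row, col] = s
                    if np.linalg.det(R) > 0:
                        mats.append(R)
    return np.array(mats)


_OCTAHEDRAL = octahedral_rotations()


def icp_refine(points: np.ndarray, target_query, iterations: int = 5, with_scale: bool = False) -> SimilarityTransform:
    """Closed-form rigid/similarity ICP of points onto a surface.

    `target_query` provides exact closest points (SurfaceQuery). Returns the
    accumulated transform mapping the input points onto the target.
    """
    total = SimilarityTransform.identity()
    current = np.asarray(points, dtype=np.float64)
    for _ in range(iterations):
        closest = target_query.project(current)
        step = umeyama(current, closest, with_scale=with_scale)
        current = step.apply(current)
        total = step.compose(total)
    return total


def _icp_refine_points(points, target_tree, target_points, iterations, with_scale):
    """Point-to-point ICP against a KD-tree of target samples (fast path)."""
    total = SimilarityTransform.identity()
    current = np.asarray(points, dtype=np.float64)
    for _ in range(iterations):
        _, idx = target_tree.query(current)
        step = umeyama(current, target_points[idx], with_scale=with_scale)
        current = step.apply(current)
        total = step.compose(total)
    return total, current


def robust_initial_pose(
    points: np.ndarray,
    target_query,
    base: SimilarityTransform,
    with_scale: bool = False,
    refine_iterations: int = 12,
    return_top: int = 1,
):
    """Disambiguate a moment-based alignment by multi-candidate ICP scoring.

    Principal-axes alignment is ambiguous up to the octahedral group when
    covariance eigenvalues are close (axis swaps) or third moments are weak
    (sign flips). Every candidate base ∘ octahedral rotation (about the
    moving centroid) is ICP-refined and candidates are ranked by *median*
    surface distance — the median is robust to segmentation artifacts such
    as holes and craters that would dominate an RMS score. Deterministic.

    With ``return_top == 1`` returns the single best pose; otherwise a list
    of up to `return_top` well-separated candidates (rotations at least 30
    degrees apart), best first — callers fitting a deformable model can
    restart from each and keep the best final fit.

    Candidate refinement and scoring run point-to-point against a
    subsampled target (fast); callers are expected to polish the winning
    pose with an exact method.
    """
    from scipy.spatial import cKDTree

    pts = np.asarray(points, dtype=np.float64)
    if len(pts) > 300:
        pts = pts[np.linspace(0, len(pts) - 1, 300).astype(np.int64)]
    target_points = target_query.vertices
    if len(target_points) > 1200:
        target_points = target_points[np.linspace(0, len(target_points) - 1, 1200).astype(np.int64)]
    target_tree = cKDTree(target_points)
    centroid = pts.mean(axis=0)
    moved_centroid = base.apply(centroid[None, :])[0]
    scored = []
    for R in _OCTAHEDRAL:
        spin = SimilarityTransform(R, moved_centroid - R @ moved_centroid, 1.0)
        candidate = spin.compose(base)
        step, moved = _icp_refine_points(
            candidate.apply(pts), target_tree, target_points, refine_iterations, with_scale
        )
        refined = step.compose(candidate)
        d, _ = target_tree.query(moved)
        scored.append((float(np.median(d)), refined))
    scored.sort(key=lambda item: item[0])
    # exact-surface rescoring of the leading candidates: the point-to-point
    # score blurs nearby basins, the true surface distance separates them
    rescored = [
        (float(np.median(target_query.distance(pose.apply(pts)))), pose)
        for _, pose in scored[:8]
    ]
    rescored.sort(key=lambda item: item[0])
    scored = rescored + scored[8:]
    if return_top == 1:
        return scored[0][1]
    picked = []
    for rms, pose in scored:
        distinct = all(
            np.arccos(np.clip((np.trace(pose.rotation @ other.rotation.T) - 1) / 2, -1, 1)) > np.pi / 6
            for other in picked
        )
        if distinct:
            picked.append(pose)
        if len(picked) == return_top:
            break
    return picked


def _principal_axes(points: np.ndarray):
    c = points.mean(axis=0)
    centered = points - c
    cov = centered.T @ centered / len(points)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return c, evals[order], evecs[:, order], centered


def coarse_align(moving, reference) -> SimilarityTransform:
    """Similarity transform matching centroid, centroid size and principal axes.

    Axis sign ambiguity is resolved by matching the sign of the third moment
    along each axis between the two clouds; the axis with the weakest third
    moment is flipped if needed so the rotation is proper (det = +1, no
    reflection).
    """
    mov, ref = _as_points(moving), _as_points(reference)
    if len(mov) < 4 or len(ref) < 4:
        raise ValueError("need at least 4 points per cloud")
    cm, evm, Em, cen_m = _principal_axes(mov)
    cr, evr, Er, cen_r = _principal_axes(ref)
    for ev, who in ((evm, "moving"), (evr, "reference")):
        if ev[2] < 1e-12 * ev[0]:
            raise ValueError(f"{who} points are coplanar (rank-deficient covariance)")

    def third_moments(centered, axes):
        return np.array([np.mean((centered @ axes[:, k]) ** 3) for k in range(3)])

    m3_r = third_moments(cen_r, Er)
    m3_m = third_moments(cen_m, Em)
    signs = np.where(m3_r * m3_m < 0, -1.0, 1.0)
    Em = Em * signs
    if np.linalg.det(Er @ Em.T) < 0:
        weakest = int(np.argmin(np.abs(m3_m)))
        Em[:, weakest] *= -1.0

    size_m = float(np.sqrt(np.mean(np.sum(cen_m**2, axis=1))))
    size_r = float(np.sqrt(np.mean(np.sum(cen_r**2, axis=1))))
    s = size_r / size_m
    R = Er @ Em.T
    t = cr - s * R @ cm
    return SimilarityTransform(R, t, s)


# ---------------------------------------------------------------------------
# coherent point drift
# ---------------------------------------------------------------------------


def _normalize_clouds(*clouds):
    """Center each cloud; scale all by one common RMS so sizes stay relative."""
    centers = [c.mean(axis=0) for c in clouds]
    centered = [c - m for c, m in zip(clouds, centers)]
    scale = float(np.sqrt(np.mean(np.concatenate(centered) ** 2) * 3.0))
    return [c / scale for c in centered], centers, scale


def _cpd_estep(X, TY, sigma2, w):
    """CPD posterior P (M x N) and its row/column sums."""
    M, N = len(TY), len(X)
    diff2 = np.sum((X[None, :, :] - TY[:, None, :]) ** 2, axis=2)
    num = np.exp(-diff2 / (2.0 * sigma2))
    c = (2.0 * np.pi * sigma2) ** 1.5 * w / (1.0 - w) * M / N
    denom = num.sum(axis=0) + max(c, 1e-300)
    P = num / denom[None, :]
    return P


def cpd_rigid(
    source,
    target,
    w: float = 0.1,
    tol: float = 1e-6,
    max_iter: int = 150,
    with_scale: bool = True,
) -> SimilarityTransform:
    """Coherent point drift rigid/similarity registration (EM on a GMM).

    The source points are GMM centroids moved by a similarity transform onto
    the target; `w` is the uniform outlier weight. Returns the transform in
    the original (unnormalized) coordinates, with ``converged=False`` and a
    RegistrationWarning when EM hits max_iter.
    """
    Y0, X0 = _as_points(source), _as_points(target)
    if len(Y0) < 4 or len(X0) < 4:
        raise ValueError("need at least 4 points per cloud")
    (Yn, Xn), (cy, cx), scale = _normalize_clouds(Y0, X0)
    M, N = len(Yn), len(Xn)

    R, t, s = np.eye(3), np.zeros(3), 1.0
    sigma2 = np.sum((Xn[None, :, :] - Yn[:, None, :]) ** 2) / (3.0 * M * N)
    prev_sigma2 = np.inf
    converged = False
    for _ in range(max_iter):
        TY = s * Yn @ R.T + t
        P = _cpd_estep(Xn, TY, sigma2, w)
        P1 = P.sum(axis=1)
        Pt1 = P.sum(axis=0)
        Np = P1.sum()
        if not np.isfinite(Np) or Np < 1e-12:
            converged = True  # posterior mass vanished: alignment is as good as it gets
            break
        mu_x = (Xn.T @ Pt1) / Np
        mu_y = (Yn.T @ P1) / Np
        Xhat = Xn - mu_x
        Yhat = Yn - mu_y
        A = Xhat.T @ (P.T @ Yhat)
        U, S, Vt = np.linalg.svd(A)
        C = np.diag([1.0, 1.0, np.sign(np.linalg.det(U) * np.linalg.det(Vt))])
        R = U @ C @ Vt
        trAR = float(np.trace(np.diag(S) @ C))
        yPy = float(np.sum(P1 * np.sum(Yhat**2, axis=1)))
        xPx = float(np.sum(Pt1 * np.sum(Xhat**2, axis=1)))
        s = trAR / yPy if with_scale else 1.0
        t = mu_x - s * R @ mu_y
        sigma2 = (xPx - s * trAR) / (3.0 * Np)
        sigma2 = max(sigma2, 1e-10)
        if abs(prev_sigma2 - sigma2) < tol * max(prev_sigma2, 1e-30):
            converged = True
            break
        prev_sigma2 = sigma2
    if not converged:
        warnings.warn("cpd_rigid stopped at max_iter without convergence", RegistrationWarning, stacklevel=2)

    # denormalize: x_world = scale * x_n + cx ; y_n = (y_world - cy)/scale
    R_w = R
    s_w = s
    t_w = scale * t + cx - s_w * R_w @ cy
    out = SimilarityTransform(R_w, t_w, s_w)
    out.converged = converged
    return out


def cpd_nonrigid(
    source,
    target,
    beta: float = 2.0,
    lam: float = 3.0,
    w: float = 0.1,
    tol: float = 1e-6,
    max_iter: int = 150,
) -> np.ndarray:
    """Coherent point drift non-rigid registration.

    The displacement field is v = G W with Gaussian kernel G of width `beta`
    (in unit-RMS normalized coordinates) and motion-coherence penalty
    ``lam * tr(W^T G W)``. Returns the displaced source points in the
    original units.
    """
    Y0, X0 = _as_points(source), _as_points(target)
    if len(Y0) < 4 or len(X0) < 4:
        raise ValueError("need at least 4 points per cloud")
    (Yn, Xn), (cy, cx), scale = _normalize_clouds(Y0, X0)
    M, N = len(Yn), len(Xn)

    G = np.exp(-np.sum((Yn[:, None, :] - Yn[None, :, :]) ** 2, axis=2) / (2.0 * beta**2))
    W = np.zeros((M, 3))
    sigma2 = np.sum((Xn[None, :, :] - Yn[:, None, :]) ** 2) / (3.0 * M * N)
    prev_sigma2 = np.inf
    converged = False
    for _ in range(max_iter):
        TY = Yn + G @ W
        P = _cpd_estep(Xn, TY, sigma2, w)
        P1 = P.sum(axis=1)
        Pt1 = P.sum(axis=0)
        Np = P1.sum()
        if not np.isfinite(Np) or Np < 1e-12:
            converged = True
            break
        A = (P1[:, None]) * G + lam * sigma2 * np.eye(M)
        rhs = P @ Xn - P1[:, None] * Yn
        W = np.linalg.solve(A, rhs)
        TY = Yn + G @ W
        xPx = float(np.sum(Pt1 * np.sum(Xn**2, axis=1)))
        trPXT = float(np.sum((P @ Xn) * TY))
        tPt = float(np.sum(P1 * np.sum(TY**2, axis=1)))
        sigma2 = (xPx - 2.0 * trPXT + tPt) / (3.0 * Np)
        sigma2 = max(sigma2, 1e-10)
        if abs(prev_sigma2 - sigma2) < tol * max(prev_sigma2, 1e-30):
            converged = True
            break
        prev_sigma2 = sigma2
    if not converged:
        warnings.warn("cpd_nonrigid stopped at max_iter without convergence", RegistrationWarning, stacklevel=2)
    return (Yn + G @ W) * scale + cx


# ---------------------------------------------------------------------------
# generalized Procrustes analysis
# ---------------------------------------------------------------------------


def gpa(sets, tol: float = 1e-8, max_iter: int = 100, return_history: bool = False):
    """Rigid generalized Procrustes alignment about the evolving mean.

    Rotation + translation only — no scale normalization, so absolute size
    is preserved (it matters mechanically downstream). The summed squared
    deviation from the mean is non-increasing across iterations; pass
    ``return_history=True`` to also get that objective per iteration.
    """
    arrs = [_as_points(s) for s in sets]
    if len(arrs) < 2:
        raise ValueError("need at least 2 sets")
    k = {len(a) for a in arrs}
    if len(k) != 1:
        raise ValueError(f"all sets must share one K, got {sorted(k)}")

    aligned = [a.copy() for a in arrs]
    mean = np.mean(aligned, axis=0)
    history = [float(sum(np.sum((a - mean) ** 2) for a in aligned))]
    for _ in range(max_iter):
        for i, a in enumerate(aligned):
            R, t = kabsch(a, mean)
            aligned[i] = a @ R.T + t
        new_mean = np.mean(aligned, axis=0)
        movement = float(np.abs(new_mean - mean).max())
        mean = new_mean
        history.append(float(sum(np.sum((a - mean) ** 2) for a in aligned)))
        if movement < tol:
            break
    result = CorrespondedSets(aligned, mean=mean)
    if return_history:
        return result, history
    return result


def gpa_objective(sets: CorrespondedSets) -> float:
    """Sum of squared deviations of each set from the mean."""
    return float(sum(np.sum((s - sets.mean) ** 2) for s in sets.sets))


# ---------------------------------------------------------------------------
# thin-plate splines
# ---------------------------------------------------------------------------


def tps_fit(source_landmarks, target_landmarks, lam_tps: float = 0.0) -> TPSTransform:
    """Fit a 3-D TPS mapping source landmarks to target landmarks.

    With ``lam_tps = 0`` the spline interpolates the landmarks exactly; for
    ``lam_tps -> inf`` the map tends to the best affine fit (the non-rigid
    weights vanish). Solved from the standard bordered linear system with
    kernel U(r) = r.
    """
    src = _as_points(source_landmarks)
    tgt = _as_points(target_landmarks)
    if len(src) != len(tgt):
        raise ValueError("source and target landmark counts differ")
    K = len(src)
    if K < 4:
        raise ValueError("need at least 4 landmarks")
    # solve in centered unit-RMS coordinates for conditioning; U(r) = r is
    # homogeneous, so the solution re-expresses exactly in mm afterwards
    mu = src.mean(axis=0)
    sigma = float(np.sqrt(np.mean(np.sum((src - mu) ** 2, axis=1))))
    if sigma == 0:
        raise ValueError("coincident source landmarks make the TPS system singular")
    src_n = (src - mu) / sigma

    diff = src_n[:, None, :] - src_n[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    if np.any((r + np.eye(K)) == 0):
        raise ValueError("coincident source landmarks make the TPS system singular")
    P = np.column_stack([np.ones(K), src_n])
    if np.linalg.matrix_rank(P) < 4:
        raise ValueError("source landmarks are coplanar; TPS system singular")
    A = np.zeros((K + 4, K + 4))
    A[:K, :K] = r + (lam_tps / sigma) * np.eye(K)
    A[:K, K:] = P
    A[K:, :K] = P.T
    b = np.zeros((K + 4, 3))
    b[:K] = tgt
    try:
        from scipy.linalg import lu_factor, lu_solve

        lu = lu_factor(A)
        sol = lu_solve(lu, b)
        # one step of iterative refinement: TPS systems are ill-conditioned
        # and the correction recovers interpolation to near machine epsilon
        sol += lu_solve(lu, b - A @ sol)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise ValueError(f"singular TPS system: {exc}") from exc
    weights_n = sol[:K]
    offset_n = sol[K]
    linear_n = sol[K + 1 :].T  # (3, 3) acting on normalized coords
    # f(x) = linear_n (x-mu)/sigma + offset_n + sum w_i |x-c_i|/sigma
    affine_matrix = linear_n / sigma
    affine_offset = offset_n - linear_n @ mu / sigma
    weights = weights_n / sigma
    return TPSTransform(src, affine_matrix, affine_offset, weights, lam_tps)


def tps_apply(transform: TPSTransform, points) -> np.ndarray:
    """Evaluate a TPS transform at arbitrary points."""
    p = _as_points(points)
    out = p @ transform.affine_matrix.T + transform.affine_offset
    # chunked kernel evaluation keeps memory bounded for large point sets
    cps = transform.control_points
    Wt = transform.weights
    chunk = max(1, int(2e6 // max(len(cps), 1)))
    for start in range(0, len(p), chunk):
        sl = slice(start, start + chunk)
        diff = p[sl, None, :] - cps[None, :, :]
        d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        out[sl] += d @ Wt
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_transform(transform, path) -> None:
    """Serialize a SimilarityTransform or TPSTransform to HDF5."""
    with h5py.File(path, "w") as fh:
        if isinstance(transform, SimilarityTransform):
            fh.attrs["kind"] = "similarity"
            fh["rotation"] = transform.rotation
            fh["translation"] = transform.translation
            fh["scale"] = transform.scale
        elif isinstance(transform, TPSTransform):
            fh.attrs["kind"] = "tps"
            fh["control_points"] = transform.control_points
            fh["affine_matrix"] = transform.affine_matrix
            fh["affine_offset"] = transform.affine_offset
            fh["weights"] = transform.weights
            fh["regularization"] = transform.regularization
        else:
            raise TypeError(f"cannot serialize {type(transform).__name__}")


def save_points_csv(points, path) -> None:
    """Write a point set as CSV with x,y,z columns (mm)."""
    pts = _as_points(points)
    with open(path, "w") as fh:
        fh.write("x,y,z\n")
        for x, y, z in pts:
            fh.write(f"{x:.17g},{y:.17g},{z:.17g}\n")


def load_points_csv(path) -> np.ndarray:
    data = np.genfromtxt(path, delimiter=",", names=True)
    return np.column_stack([data["x"], data["y"], data["z"]])


def load_transform(path):
    with h5py.File(path, "r") as fh:
        kind = fh.attrs["kind"]
        if kind == "similarity":
            return SimilarityTransform(fh["rotation"][()], fh["translation"][()], float(fh["scale"][()]))
        if kind == "tps":
            return TPSTransform(
                fh["control_points"][()],
                fh["affine_matrix"][()],
                fh["affine_offset"][()],
                fh["weights"][()],
                float(fh["regularization"][()]),
            )
    raise ValueError(f"unknown transform kind {kind!r}")
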
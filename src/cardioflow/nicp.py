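"""Optimal-step nonrigid ICP solver.

Each source vertex carries its own 4x3 affine transform; stacking them
gives the 4n x 3 unknown X.  One step minimizes the Frobenius cost

    || [ alpha M (x) G ;  W D ;  beta D_L ;  lambda D_Tar ] X
       - [ 0 ;  W U ;  beta U_L ;  lambda U_Tar ] ||_F^2

where M is the node-arc incidence matrix of the source edges,
G = diag(1, 1, 1, gamma), D holds the homogeneous source coordinates in a
block-diagonal layout (so D X are the transformed positions), W is a 0/1
per-vertex weight (0 at landmarks), D_L/U_L are landmark rows and
prescribed positions, and D_Tar/U_Tar come from reverse (target-to-source)
correspondences.  The registration loop alternates nearest-neighbor
correspondence with this exact linear least-squares solve while lowering
the stiffness weight alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .correspondence import (CorrespondenceSet, nearest_correspondences,
                             poisson_subsample, reverse_correspondences)
from .mesh_core import SurfaceMesh, build_incidence_matrix, vertex_normals

__all__ = [
    "TransformStack",
    "RegistrationConfig",
    "RegistrationSystem",
    "make_stiffness_schedule",
    "assemble_system",
    "optimal_step_solve",
    "register_surfaces",
]


@dataclass
class TransformStack:
    """Stack of n per-vertex 4x3 affine transforms, stored as (4n, 3)."""

    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != 3 or self.X.shape[0] % 4:
            raise ValueError("X must be (4n, 3)")

    @property
    def n_blocks(self) -> int:
        return self.X.shape[0] // 4

    def blocks(self) -> np.ndarray:
        return self.X.reshape(self.n_blocks, 4, 3)

    @classmethod
    def identity(cls, n: int) -> "TransformStack":
        block = np.vstack([np.eye(3), np.zeros(3)])
        return cls(np.tile(block, (n, 1)))

    def apply(self, positions: np.ndarray) -> np.ndarray:
        """Transformed positions (equals D @ X without forming D)."""
        homo = np.hstack([positions, np.ones((len(positions), 1))])
        return np.einsum("nk,nkj->nj", homo, self.blocks())


@dataclass
class RegistrationConfig:
    """Weights and schedules of the registration cost."""

    alpha_schedule: np.ndarray = field(
        default_factory=lambda: make_stiffness_schedule("chambers"))
    gamma: float = 1.0
    beta: float = 10.0
    lambda_bidir: float = 0.0          # 0.5 for LAA passes
    subsample_radius_fraction: float = 0.05
    epsilon: float = 1e-4              # on ||X_j - X_{j-1}||_F, unit-cube coords
    max_inner_iterations: int = 10
    # drop correspondences whose nearest target vertex lies on an open
    # target boundary (present in the ancestor algorithm; needed when the
    # target carries cut borders that would otherwise attract the source)
    prune_border_targets: bool = False
    # restrict matches to target vertices whose normal faces the same way
    # (ancestor-algorithm option; prevents thin structures from collapsing
    # onto their opposite wall)
    normal_compatible: bool = False

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha_schedule, dtype=float)
        if a.size == 0 or np.any(a <= 0):
            raise ValueError("alpha schedule must be positive")
        if np.any(np.diff(a) > 0):
            raise ValueError("alpha schedule must be non-increasing")
        self.alpha_schedule = a
        if self.beta < 0 or self.lambda_bidir < 0:
            raise ValueError("beta and lambda must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def make_stiffness_schedule(region: str, n_steps: int | None = None,
                            spacing: str = "linear") -> np.ndarray:
    """Stiffness schedules: chambers 100 -> 1 in 100 steps, LAA 100 -> 10 in
    20 steps.  ``n_steps`` overrides the count (reduced schedules for fast
    runs) while keeping the endpoints."""
    endpoints = {"chambers": (100.0, 1.0, 100), "laa": (100.0, 10.0, 20)}
    if region not in endpoints:
        raise ValueError(f"unknown region {region!r}; expected 'chambers' or 'laa'")
    hi, lo, default_steps = endpoints[region]
    k = default_steps if n_steps is None else int(n_steps)
    if k < 2:
        raise ValueError("schedule needs at least 2 steps")
    if spacing == "linear":
        return np.linspace(hi, lo, k)
    if spacing == "geometric":
        return np.geomspace(hi, lo, k)
    raise ValueError("spacing must be 'linear' or 'geometric'")


@dataclass
class RegistrationSystem:
    """Stacked sparse least-squares system A X = b with block bookkeeping."""

    A: sp.csr_matrix
    b: np.ndarray
    block_rows: dict[str, slice]

    def cost(self, X: TransformStack | np.ndarray) -> float:
        X = X.X if isinstance(X, TransformStack) else X
        r = self.A @ X - self.b
        return float((r * r).sum())

    def block_cost(self, X, name: str) -> float:
        X = X.X if isinstance(X, TransformStack) else X
        s = self.block_rows[name]
        r = self.A[s] @ X - self.b[s]
        return float((r * r).sum())


def _position_matrix(positions: np.ndarray) -> sp.csr_matrix:
    """Sparse D (n x 4n): row i holds (x_i, y_i, z_i, 1) in block i."""
    n = len(positions)
    homo = np.hstack([positions, np.ones((n, 1))])
    rows = np.repeat(np.arange(n), 4)
    cols = np.arange(4 * n)
    return sp.csr_matrix((homo.ravel(), (rows, cols)), shape=(n, 4 * n))


def _rows_of(full_D: sp.csr_matrix, indices: np.ndarray) -> sp.csr_matrix:
    return full_D[np.asarray(indices, dtype=np.int64)]


def assemble_system(source: SurfaceMesh | np.ndarray,
                    correspondences: CorrespondenceSet,
                    landmarks: tuple[np.ndarray, np.ndarray] | None,
                    alpha: float,
                    config: RegistrationConfig,
                    incidence: sp.csr_matrix | None = None,
                    source_positions: np.ndarray | None = None) -> RegistrationSystem:
    """Build the stacked system for one optimal step.

    ``source_positions`` (default: source vertices) are the coordinates the
    affine transforms act on; correspondences refer to the same vertices.
    ``landmarks`` is ``(vertex_indices, prescribed_positions)`` or None.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if not isinstance(source, SurfaceMesh):
        raise TypeError("source must be a SurfaceMesh")
    if incidence is None:
        incidence = build_incidence_matrix(source)
    pos = source.vertices if source_positions is None else np.asarray(source_positions)
    n = source.n_vertices
    if len(correspondences.forward_targets) != n:
        raise ValueError("correspondences must cover all source vertices")

    G = sp.diags([1.0, 1.0, 1.0, config.gamma])
    stiff = alpha * sp.kron(incidence, G, format="csr")

    D = _position_matrix(pos)
    W = sp.diags(correspondences.forward_weights)
    dist = W @ D
    rhs_dist = correspondences.forward_weights[:, None] * correspondences.forward_targets

    blocks_A = [stiff, dist]
    blocks_b = [np.zeros((stiff.shape[0], 3)), rhs_dist]
    block_rows = {}
    r0 = 0
    block_rows["stiffness"] = slice(r0, r0 + stiff.shape[0]); r0 += stiff.shape[0]
    block_rows["distance"] = slice(r0, r0 + n); r0 += n

    if landmarks is not None and len(landmarks[0]):
        lm_idx = np.asarray(landmarks[0], dtype=np.int64)
        lm_pos = np.asarray(landmarks[1], dtype=float)
        if lm_idx.min() < 0 or lm_idx.max() >= n:
            raise ValueError("landmark indices out of range")
        DL = config.beta * _rows_of(D, lm_idx)
        blocks_A.append(DL)
        blocks_b.append(config.beta * lm_pos)
        block_rows["landmark"] = slice(r0, r0 + len(lm_idx)); r0 += len(lm_idx)

    if len(correspondences.reverse_source_idx):
        DT = config.lambda_bidir * _rows_of(D, correspondences.reverse_source_idx)
        blocks_A.append(DT)
        blocks_b.append(config.lambda_bidir * correspondences.reverse_targets)
        k = len(correspondences.reverse_source_idx)
        block_rows["bidirectional"] = slice(r0, r0 + k); r0 += k

    A = sp.vstack(blocks_A, format="csr")
    b = np.vstack(blocks_b)
    return RegistrationSystem(A=A, b=b, block_rows=block_rows)


def optimal_step_solve(system: RegistrationSystem) -> TransformStack:
    """Exact linear least-squares minimizer via sparse normal equations."""
    A = system.A
    AtA = (A.T @ A).tocsc()
    Atb = A.T @ system.b
    try:
        lu = spla.splu(AtA)
    except RuntimeError as exc:  # singular factorization
        raise np.linalg.LinAlgError(
            "singular registration system; increase alpha or check mesh "
            "connectivity") from exc
    X = lu.solve(Atb)
    if not np.all(np.isfinite(X)):
        raise np.linalg.LinAlgError(
            "singular registration system; increase alpha or check mesh "
            "connectivity")
    return TransformStack(X)


class _NormalEquationCache:
    """Fast per-iteration assembly of the normal equations.

    All non-stiffness rows of the stacked system touch only the 4-column
    block of their own source vertex, so their Gram contribution is 4x4
    block-diagonal; the stiffness contribution is alpha^2 * kron(M^T M,
    G^T G), computed once per registration.  The resulting solve is
    algebraically identical to :func:`optimal_step_solve` on the stacked
    system (asserted in the test suite).
    """

    def __init__(self, source: SurfaceMesh, config: RegistrationConfig,
                 incidence: sp.csr_matrix):
        n = source.n_vertices
        self.n = n
        self.homo = np.hstack([source.vertices, np.ones((n, 1))])
        MtM = (incidence.T @ incidence).tocoo()
        GtG = np.diag([1.0, 1.0, 1.0, config.gamma ** 2])
        self.K = sp.kron(MtM, GtG, format="csc")
        self.config = config

    def solve(self, corr: CorrespondenceSet,
              landmarks: tuple[np.ndarray, np.ndarray] | None,
              alpha: float) -> TransformStack:
        cfg = self.config
        n, homo = self.n, self.homo
        coef = corr.forward_weights.astype(float).copy()   # W is 0/1 -> w^2 = w
        rhs_pts = (corr.forward_weights[:, None]
                   * corr.forward_targets).astype(float)
        if landmarks is not None and len(landmarks[0]):
            lm_idx = np.asarray(landmarks[0], dtype=np.int64)
            coef[lm_idx] += cfg.beta ** 2
            rhs_pts[lm_idx] += cfg.beta ** 2 * np.asarray(landmarks[1], float)
        if len(corr.reverse_source_idx):
            lam2 = cfg.lambda_bidir ** 2
            np.add.at(coef, corr.reverse_source_idx, lam2)
            np.add.at(rhs_pts, corr.reverse_source_idx,
                      lam2 * corr.reverse_targets)

        blocks = coef[:, None, None] * np.einsum("ni,nj->nij", homo, homo)
        B = sp.bsr_matrix(
            (blocks, np.arange(n), np.arange(n + 1)), shape=(4 * n, 4 * n))
        AtA = (alpha ** 2 * self.K + B).tocsc()
        Atb = (homo[:, :, None] * rhs_pts[:, None, :]).reshape(4 * n, 3)
        try:
            lu = spla.splu(AtA)
        except RuntimeError as exc:
            raise np.linalg.LinAlgError(
                "singular registration system; increase alpha or check mesh "
                "connectivity") from exc
        X = lu.solve(Atb)
        if not np.all(np.isfinite(X)):
            raise np.linalg.LinAlgError(
                "singular registration system; increase alpha or check mesh "
                "connectivity")
        return TransformStack(X)


@dataclass
class RegistrationResult:
    positions: np.ndarray
    transforms: TransformStack
    mean_distance: float
    initial_mean_distance: float
    n_solves: int = 0


def mean_nearest_distance(points: np.ndarray, target: SurfaceMesh | np.ndarray) -> float:
    from scipy.spatial import cKDTree
    tgt = target.vertices if isinstance(target, SurfaceMesh) else np.asarray(target)
    d, _ = cKDTree(tgt).query(points, k=1)
    return float(np.mean(d))


def register_surfaces(source: SurfaceMesh, target: SurfaceMesh,
                      landmarks: tuple[np.ndarray, np.ndarray] | None,
                      config: RegistrationConfig) -> RegistrationResult:
    """Run the full optimal-step loop over the stiffness schedule.

    Meshes are expected in normalized (unit-cube) coordinates.  Returns the
    deformed source positions and the final transform stack.
    """
    from scipy.spatial import cKDTree

    n = source.n_vertices
    incidence = build_incidence_matrix(source)
    lm_idx = (np.asarray(landmarks[0], dtype=np.int64)
              if landmarks is not None else np.empty(0, dtype=np.int64))

    subsample = None
    if config.lambda_bidir > 0:
        subsample = poisson_subsample(target, config.subsample_radius_fraction)
    tgt_pts = target.vertices
    tgt_tree = cKDTree(tgt_pts)
    sub_pts = tgt_pts[subsample] if subsample is not None else None

    cache = _NormalEquationCache(source, config, incidence)
    X = TransformStack.identity(n)
    positions = source.vertices.copy()
    initial_dist = mean_nearest_distance(positions, target)
    n_solves = 0

    w_template = np.ones(n)
    if lm_idx.size:
        w_template[lm_idx] = 0.0
    border_mask = None
    if config.prune_border_targets:
        from .mesh_core import _boundary_directed_edges
        bde = _boundary_directed_edges(target)
        if len(bde):
            border_mask = np.zeros(len(tgt_pts), dtype=bool)
            border_mask[np.unique(bde)] = True
    tgt_normals = (vertex_normals(target.faces, tgt_pts)
                   if config.normal_compatible else None)

    for alpha in config.alpha_schedule:
        for _ in range(config.max_inner_iterations):
            if tgt_normals is None:
                _, nn = tgt_tree.query(positions, k=1)
            else:
                # nearest target vertex with a same-facing normal (first of
                # the k nearest; plain nearest if none qualifies)
                src_n = vertex_normals(source.faces, positions)
                k = min(8, len(tgt_pts))
                _, cand = tgt_tree.query(positions, k=k)
                cand = np.atleast_2d(cand)
                dots = np.einsum("ij,ikj->ik", src_n, tgt_normals[cand])
                ok = dots > 0.0
                first = np.argmax(ok, axis=1)
                first[~ok.any(axis=1)] = 0
                nn = cand[np.arange(len(cand)), first]
            weights = w_template
            if border_mask is not None:
                weights = w_template.copy()
                weights[border_mask[nn]] = 0.0
            corr = CorrespondenceSet(forward_targets=tgt_pts[nn],
                                     forward_weights=weights)
            if sub_pts is not None and len(sub_pts):
                _, ridx = cKDTree(positions).query(sub_pts, k=1)
                corr.reverse_source_idx = ridx.astype(np.int64)
                corr.reverse_targets = sub_pts
            X_new = cache.solve(corr, landmarks, float(alpha))
            n_solves += 1
            delta = float(np.linalg.norm(X_new.X - X.X))
            X = X_new
            positions = X.apply(source.vertices)
            if delta < config.epsilon:
                break

    return RegistrationResult(
        positions=positions,
        transforms=X,
        mean_distance=mean_nearest_distance(positions, target),
        initial_mean_distance=initial_dist,
        n_solves=n_solves,
    )
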
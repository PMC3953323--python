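"""Differential geometry of the sub-loop chart.

A block with fixed end frames admits a (b-6)-dimensional manifold of closing
conformations in 3D (b-3 in 2D).  One IK branch provides a local chart
f: y -> x_B from the independent angles to the block's expanded coordinates
(independent angles, dependent angles, intervening frames).  The sampling
density of the block proposal with respect to the manifold volume measure is

    Q(x_B) = P(y) / (s * sqrt(det G(y))),      G = J_chart^T W J_chart,

where s is the IK solution count at y and W a diagonal weighting.  The chart
Jacobian is assembled from the implicit function theorem applied to the
closure constraint C(y, z) = 0:

    dz/dy = -(dC/dz)^{-1} dC/dy.

By default W weighs the angle rows and the frame-origin rows with 1 and the
frame-angular rows with 0, avoiding a mix of radians and length units in one
metric; it is fully configurable.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .closure import Block
from .kinematics import Chain, forward_kinematics

__all__ = [
    "ChartGeometry",
    "ConstraintSystem",
    "joint_screws",
    "constraint_jacobians",
    "implicit_chart_jacobian",
    "chart_jacobian",
    "metric_tensor",
    "log_det_g",
    "proposal_density",
    "log_proposal_density",
    "density_pushforward",
    "parallelotope_volume",
    "manifold_dimension",
]

#: planar constraints keep rows (x, y, rotation about z) of the full screw
_PLANAR_ROWS = np.array([0, 1, 5])


@dataclass
class ChartGeometry:
    """Jacobians and metric of one block chart at one conformation."""

    J_chart: np.ndarray
    W: np.ndarray  # diagonal weights, same length as J_chart rows
    G: np.ndarray
    s: int
    log_det: float

    @property
    def det_G(self) -> float:
        return float(np.exp(self.log_det))


@dataclass
class ConstraintSystem:
    """Closure residual map and its Jacobian blocks at a conformation."""

    residual: np.ndarray  # 6-vector (3 in 2D); zero on-manifold
    dC_dy: np.ndarray
    dC_dz: np.ndarray


def joint_screws(
    chain: Chain, frames: np.ndarray, base: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """World-frame rotation axes w_j and origins o_j for every joint."""
    w = np.einsum("jab,jb->ja", frames[:, :3, :3], chain.axes)
    o = frames[:, :3, 3]
    return w, o


def _closure_jacobian(
    chain: Chain, frames: np.ndarray, block: Block
) -> np.ndarray:
    """Full Jacobian of the block's terminal-frame screw w.r.t. its angles.

    Rows: 3 origin-velocity rows then 3 angular rows; columns: block angles.
    Planar callers select rows (x, y, w_z).
    """
    i, b = block.start, block.size
    sub = frames[i : i + b]
    w = np.einsum("jab,jb->ja", sub[:, :3, :3], chain.axes[i : i + b])
    o = sub[:, :3, 3]
    pT = frames[i + b - 1][:3, 3]
    J = np.zeros((6, b))
    J[:3, :] = np.cross(w, pT[None] - o).T
    J[3:, :] = w.T
    return J


def constraint_jacobians(
    chain: Chain, frames: np.ndarray, block: Block
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic screw-axis Jacobian blocks (dC/dy, dC/dz) of the closure
    residual with respect to the independent and dependent block angles."""
    J = _closure_jacobian(chain, frames, block)
    if block.n_dependent == 3:
        J = J[_PLANAR_ROWS]
    ni = block.n_independent
    return J[:, :ni], J[:, ni:]


def implicit_chart_jacobian(
    dC_dy: np.ndarray, dC_dz: np.ndarray, rcond_threshold: float = 1e-10
) -> np.ndarray:
    """dz/dy = -(dC/dz)^{-1} dC/dy, the sensitivity of the dependent angles
    to the independent ones along the solution manifold.

    Raises ``SingularChartError`` when dC/dz is ill-conditioned (singular
    conformation); callers treat this as a rejected move.
    """
    if dC_dy.shape[1] == 0:
        return np.zeros((dC_dz.shape[1], 0))
    # reciprocal condition via SVD (matrices are 6x6 at most)
    sv = np.linalg.svd(dC_dz, compute_uv=False)
    if sv[-1] <= rcond_threshold * sv[0] or sv[-1] == 0.0:
        raise SingularChartError("dependent-subchain Jacobian is singular")
    return -np.linalg.solve(dC_dz, dC_dy)


class SingularChartError(RuntimeError):
    """Raised at singular conformations where the chart breaks down."""


def chart_jacobian(
    chain: Chain, frames: np.ndarray, block: Block, dz_dy: np.ndarray
) -> np.ndarray:
    """Jacobian of the chart f(y) = [y; z(y); frames] stacked row-wise.

    The top (b-6) rows are the identity; then dz/dy; then, for each
    intervening frame of the block, 3 origin-velocity rows and 3
    angular-velocity rows obtained by the chain rule through dz/dy.
    """
    i, b = block.start, block.size
    ni = block.n_independent
    sub = frames[i : i + b]
    w = np.einsum("jab,jb->ja", sub[:, :3, :3], chain.axes[i : i + b])
    o = sub[:, :3, 3]
    dq_dy = np.vstack([np.eye(ni), dz_dy])  # (b, ni)
    rows = [np.eye(ni), dz_dy]
    # intervening frames: the first b-1 frames of the block (the terminal
    # frame is pinned by closure and contributes zero rows)
    for k in range(b - 1):
        p_k = o[k]
        Jp = np.zeros((3, b))
        Jw = np.zeros((3, b))
        for j in range(k + 1):
            Jp[:, j] = np.cross(w[j], p_k - o[j])
            Jw[:, j] = w[j]
        rows.append(Jp @ dq_dy)
        rows.append(Jw @ dq_dy)
    return np.vstack(rows)


def default_weights(block: Block) -> np.ndarray:
    """Diagonal W: 1 on angle rows and frame-origin rows, 0 on frame-angular
    rows (keeps radians and length units out of the same metric)."""
    b = block.size
    w = [np.ones(b)]
    for _ in range(b - 1):
        w.append(np.ones(3))
        w.append(np.zeros(3))
    return np.concatenate(w)


def metric_tensor(J_chart: np.ndarray, W: np.ndarray | None = None) -> np.ndarray:
    """G = J^T W J with diagonal weighting W (identity when omitted)."""
    if W is None:
        return J_chart.T @ J_chart
    W = np.asarray(W, dtype=float)
    return J_chart.T @ (W[:, None] * J_chart)


def log_det_g(G: np.ndarray, tol: float = 1e-12) -> float:
    """log det of the (PSD) metric tensor via Cholesky."""
    if G.shape[0] == 0:
        return 0.0
    try:
        L = np.linalg.cholesky(G)
    except np.linalg.LinAlgError as exc:
        raise SingularChartError("metric tensor not positive definite") from exc
    d = np.diag(L)
    if np.min(d) <= tol:
        raise SingularChartError("metric tensor numerically singular")
    return float(2.0 * np.sum(np.log(d)))


def block_chart_geometry(
    chain: Chain,
    frames: np.ndarray,
    block: Block,
    s: int,
    W: np.ndarray | None = None,
) -> ChartGeometry:
    """Assemble the full chart geometry of a block at one conformation."""
    dC_dy, dC_dz = constraint_jacobians(chain, frames, block)
    dz_dy = implicit_chart_jacobian(dC_dy, dC_dz)
    J = chart_jacobian(chain, frames, block, dz_dy)
    if W is None:
        W = default_weights(block)
    G = metric_tensor(J, W)
    return ChartGeometry(J_chart=J, W=W, G=G, s=s, log_det=log_det_g(G))


def log_proposal_density(log_p_y: float, s: int, log_det: float) -> float:
    """log Q = log P(y) - log s - 0.5 log det G."""
    if s < 1:
        raise ValueError("solution count must be >= 1 at a sampled point")
    return log_p_y - np.log(s) - 0.5 * log_det


def proposal_density(P_y: float, s: int, G: np.ndarray) -> float:
    """Exact sampling density of the block proposal w.r.t. the manifold
    volume measure: Q = P(y) / (s sqrt(det G))."""
    if s < 1:
        raise ValueError("solution count must be >= 1 at a sampled point")
    ld = log_det_g(np.atleast_2d(np.asarray(G, dtype=float)))
    return float(P_y / (s * np.exp(0.5 * ld)))


def density_pushforward(g_u, f, u, eps: float = 1e-6):
    """Density of v = f(u) on the image manifold w.r.t. the m-volume measure:
    g_v(f(u)) = g_u(u) / sqrt(det G(u)) with G the Gram matrix of the
    numerically differentiated Jacobian of f."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    f0 = np.asarray(f(u), dtype=float)
    m = u.shape[0]
    J = np.empty((f0.shape[0], m))
    for k in range(m):
        du = np.zeros(m)
        du[k] = eps
        J[:, k] = (np.asarray(f(u + du)) - np.asarray(f(u - du))) / (2 * eps)
    G = J.T @ J
    sign, ld = np.linalg.slogdet(G)
    if sign <= 0 or ld < np.log(1e-24):
        raise ValueError("Jacobian is rank deficient at u")
    return float(g_u(u) * np.exp(-0.5 * ld))


def parallelotope_volume(vectors) -> float:
    """m-volume of the parallelotope spanned by m vectors in R^n, via the
    Gram determinant sqrt(det(A^T A)); rank-deficient input gives 0."""
    A = np.atleast_2d(np.asarray(vectors, dtype=float)).T  # columns
    G = A.T @ A
    d = float(np.linalg.det(G))
    return float(np.sqrt(max(d, 0.0)))


def manifold_dimension(
    chain: Chain,
    angles: np.ndarray,
    block: Block | None = None,
    planar: bool | None = None,
    sv_tol: float = 1e-8,
) -> int:
    """Dimension of the fixed-endpoint closure solution set at a generic
    conformation: angle count minus the numerical rank of the closure
    Jacobian (singular values above ``sv_tol`` of the largest).

    Spatial blocks of b angles give b - 6 (b >= 7); planar blocks give b - 3
    (b >= 4); smaller blocks give dimension <= 0, reported as 0.
    """
    angles = np.asarray(angles, dtype=float)
    frames = forward_kinematics(chain, angles)
    if block is None:
        block = Block(
            0,
            chain.n_joints,
            n_dependent=3 if (planar if planar is not None else chain.is_planar) else 6,
        )
    J = _closure_jacobian(chain, frames, block)
    if block.n_dependent == 3:
        J = J[_PLANAR_ROWS]
    sv = np.linalg.svd(J, compute_uv=False)
    rank = int(np.sum(sv > sv_tol * sv[0]))
    return max(block.size - rank, 0)
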
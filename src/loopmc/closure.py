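"""Inverse-kinematics closure of dependent subchains.

A block of b consecutive angles splits into an independent subchain (the
first b-6 angles in 3D, b-3 in 2D) sampled freely, and a dependent subchain
(the last 6, resp. 3, angles) solved so that the block's terminal frame hits
its fixed anchor.  The planar 3-angle problem is solved in closed form
(two-circle intersection, at most two solutions).  The spatial 6-angle
problem is solved by batched damped Gauss-Newton iteration from a fixed bank
of seed configurations, with root verification and deduplication; a generic
6R problem has at most 16 isolated solutions, and every returned root is
verified to close the chain, so the returned set is a subset of that bound.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import Chain, ExpandedState, fk_batch, fk_batch_all, forward_kinematics
from .planar import solve_planar_3r
from .rigid import frame_error

__all__ = ["Block", "IKSolutionSet", "solve_planar", "solve_spatial_6", "sample_block"]

#: fixed bank of seed configurations for the multistart spatial solver;
#: deterministic by construction so repeated solves of the same problem
#: return identical solution sets.
_SEED_RNG = np.random.default_rng(0x5EED)
_SEED_BANK = _SEED_RNG.uniform(-np.pi, np.pi, size=(4096, 6))


@dataclass
class Block:
    """A window of b consecutive joint angles updated jointly.

    start : index of the first angle in the chain (0-based)
    size : b, the number of angles
    n_dependent : 6 for spatial chains, 3 for planar chains
    """

    start: int
    size: int
    n_dependent: int = 6

    def __post_init__(self) -> None:
        if self.n_dependent not in (3, 6):
            raise ValueError("n_dependent must be 3 (planar) or 6 (spatial)")

    @property
    def n_independent(self) -> int:
        """b - 6 (b - 3 planar); negative for overdetermined blocks, whose
        closure-constrained conditional is a Dirac at the current state."""
        return self.size - self.n_dependent

    @property
    def mixes(self) -> bool:
        """True when the block admits a continuous solution manifold."""
        return self.size > self.n_dependent

    @property
    def stop(self) -> int:
        return self.start + self.size

    @property
    def angle_indices(self) -> range:
        return range(self.start, self.stop)


@dataclass
class IKSolutionSet:
    """Discrete set of dependent-angle solutions closing a subchain."""

    solutions: np.ndarray  # (s, n_dependent)

    @property
    def count(self) -> int:
        return self.solutions.shape[0]

    def __len__(self) -> int:
        return self.count

    def __iter__(self):
        return iter(self.solutions)


def solve_planar(
    anchor_start: np.ndarray, anchor_end: np.ndarray, link_lengths
) -> IKSolutionSet:
    """All planar 3-angle closures between two fixed frames.

    ``anchor_start`` is the frame preceding the first dependent joint and
    ``anchor_end`` the required frame after the third dependent rotation
    (both 4x4 planar rigid transforms).  Generic reachable targets give
    exactly two solutions; unreachable targets give an empty set.
    """
    L1, L2, L3 = link_lengths
    a = _planar_pose(anchor_start)
    t = _planar_pose(anchor_end)
    sols = solve_planar_3r(a, L1, L2, L3, t)
    return IKSolutionSet(np.array(sols, dtype=float).reshape(len(sols), 3))


def _planar_pose(T: np.ndarray) -> tuple[float, float, float]:
    return (
        float(T[0, 3]),
        float(T[1, 3]),
        float(np.arctan2(T[1, 0], T[0, 0])),
    )


def solve_spatial_6(
    dependent_chain: Chain,
    start_frame: np.ndarray,
    goal_frame: np.ndarray,
    n_seeds: int = 2400,
    extra_seeds: np.ndarray | None = None,
    max_iter: int = 80,
    closure_tol: float = 1e-9,
    dedup_tol: float = 1e-4,
) -> IKSolutionSet:
    """Enumerate the 6-angle closures of a spatial subchain.

    The dependent chain's 6 joints are solved so that its terminal frame
    equals ``goal_frame`` when rooted at ``start_frame``.  Damped Gauss-Newton
    runs in parallel from a fixed seed bank (plus ``extra_seeds``, e.g. the
    currently known closing solution); converged iterates are verified to
    close within ``closure_tol`` (both position in length units and rotation
    in Frobenius norm) and deduplicated at ``dedup_tol`` radians.  Unreachable
    goals yield an empty set; no partial solution is ever returned.
    """
    if dependent_chain.n_joints != 6:
        raise ValueError("spatial closure requires exactly 6 dependent angles")
    goal = np.asarray(goal_frame, dtype=float)
    seeds = _SEED_BANK[:n_seeds]
    if extra_seeds is not None:
        seeds = np.vstack([np.atleast_2d(extra_seeds), seeds])
    z = seeds.copy()
    Rg = goal[:3, :3]
    pg = goal[:3, 3]
    scale = max(1.0, float(np.sum(np.abs(dependent_chain.rel_transforms[:, :3, 3]))))

    def _gn_sweep(
        z: np.ndarray, n_iter: int, stop_tol: float | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        err = np.full(z.shape[0], np.inf)
        for _ in range(n_iter):
            frames = fk_batch_all(dependent_chain, z, base=start_frame)
            T = frames[:, -1]
            e = np.empty((z.shape[0], 6))
            e[:, :3] = T[:, :3, 3] - pg[None]
            e[:, 3:] = _rotlog_batch(T[:, :3, :3] @ Rg.T) * scale
            err = np.linalg.norm(e, axis=1)
            if stop_tol is not None and np.all((err < stop_tol) | (err > 0.5)):
                break  # every promising seed has converged
            # geometric Jacobian columns [w x (p_T - o_j); w]
            w = np.einsum("kjab,jb->kja", frames[:, :, :3, :3], dependent_chain.axes)
            o = frames[:, :, :3, 3]
            pT = T[:, None, :3, 3]
            J = np.empty((z.shape[0], 6, 6))
            J[:, :3, :] = np.transpose(np.cross(w, pT - o), (0, 2, 1))
            J[:, 3:, :] = np.transpose(w, (0, 2, 1)) * scale
            JtJ = np.transpose(J, (0, 2, 1)) @ J + 1e-10 * np.eye(6)[None]
            Jte = np.einsum("kij,kj->ki", np.transpose(J, (0, 2, 1)), e)
            try:
                dz = np.linalg.solve(JtJ, Jte[..., None])[..., 0]
            except np.linalg.LinAlgError:  # pragma: no cover - regularized above
                break
            np.clip(dz, -0.6, 0.6, out=dz)
            z = z - dz
        return z, err

    # short full-bank sweep, then polish only the seeds that made progress;
    # when none look promising (typically an unreachable goal), polish just
    # the best few to confirm before reporting an empty set
    z, err = _gn_sweep(z, 16)
    keep = err < 0.5
    if not np.any(keep):
        keep = np.argsort(err)[:32]
    z, err = _gn_sweep(z[keep], max_iter, stop_tol=0.1 * closure_tol)
    # final verification
    T = fk_batch(dependent_chain, z, base=start_frame)
    perr = np.linalg.norm(T[:, :3, 3] - pg[None], axis=1)
    Rerr = np.linalg.norm(T[:, :3, :3] - Rg[None], axis=(1, 2))
    ok = (perr < closure_tol) & (Rerr < closure_tol)
    roots = np.arctan2(np.sin(z[ok]), np.cos(z[ok]))
    return IKSolutionSet(_dedup(roots, dedup_tol))


def _dedup(roots: np.ndarray, tol: float) -> np.ndarray:
    kept: list[np.ndarray] = []
    for r in roots:
        dup = False
        for k in kept:
            d = np.abs(np.arctan2(np.sin(r - k), np.cos(r - k)))
            if np.max(d) < tol:
                dup = True
                break
        if not dup:
            kept.append(r)
    return np.array(kept).reshape(len(kept), roots.shape[1] if roots.ndim > 1 else 6)


def _rotlog_batch(R: np.ndarray) -> np.ndarray:
    """Rotation vectors of a (K, 3, 3) batch of rotation matrices."""
    tr = np.trace(R, axis1=1, axis2=2)
    c = np.clip((tr - 1.0) / 2.0, -1.0, 1.0)
    w = np.stack(
        [
            R[:, 2, 1] - R[:, 1, 2],
            R[:, 0, 2] - R[:, 2, 0],
            R[:, 1, 0] - R[:, 0, 1],
        ],
        axis=1,
    )
    s = np.linalg.norm(w, axis=1)
    # atan2 avoids the arccos cancellation near the identity
    angle = np.arctan2(s / 2.0, c)
    out = 0.5 * w  # small-angle default
    gen = (angle > 1e-7) & (np.pi - angle > 1e-5)
    out[gen] = w[gen] * (angle[gen] / s[gen])[:, None]
    near_pi = np.pi - angle <= 1e-5
    if np.any(near_pi):
        for i in np.nonzero(near_pi)[0]:
            A = (R[i] + np.eye(3)) / 2.0
            d = np.sqrt(np.maximum(np.diag(A), 0.0))
            j = int(np.argmax(d))
            axis = A[:, j] / max(d[j], 1e-12)
            axis = axis / np.linalg.norm(axis)
            if np.dot(axis, w[i]) < 0:
                axis = -axis
            out[i] = axis * angle[i]
    return out


def sample_block(
    chain: Chain,
    state: ExpandedState,
    block: Block,
    prior_sampler,
    rng: np.random.Generator,
    n_seeds: int = 600,
):
    """One Sample-Block draw: sample the independent subchain from the prior,
    close the dependent subchain by IK, pick a branch uniformly.

    ``prior_sampler(rng, angle_index)`` draws one independent angle.  Returns
    ``(q_block, frames_block, s)`` on success or ``None`` on IK failure (a
    normal outcome counted as a rejected move by the caller).  With zero
    independent angles the candidate is restricted to the finite IK solution
    set of the anchors (non-mixing; disallowed by default in the sampler).
    """
    i = block.start
    b = block.size
    ni = block.n_independent
    anchor = chain.base_frame if i == 0 else state.frames[i - 1]
    target = state.frames[i + b - 1]
    y = np.array([prior_sampler(rng, i + m) for m in range(ni)])
    if ni > 0:
        indep = chain.subchain(i, i + ni, base_frame=anchor)
        frames_y = forward_kinematics(indep, y, base=anchor)
        A = frames_y[-1]
    else:
        frames_y = np.empty((0, 4, 4))
        A = anchor
    dep = chain.subchain(i + ni, i + b, base_frame=A)
    if block.n_dependent == 3:
        L = dep.rel_transforms[:, 0, 3]
        sols = solve_planar(A, target, L)
    else:
        sols = solve_spatial_6(dep, A, target, n_seeds=n_seeds)
    s = sols.count
    if s == 0:
        return None
    z = sols.solutions[int(rng.integers(s))]
    frames_z = forward_kinematics(dep, z, base=A)
    frames_block = np.concatenate([frames_y, frames_z], axis=0)
    frames_block[-1] = target  # snap to the exact anchor
    q_block = np.concatenate([y, z])
    return q_block, frames_block, s


def closure_residual(frame: np.ndarray, target: np.ndarray) -> tuple[float, float]:
    """Terminal-frame closure error (position, rotation Frobenius)."""
    return frame_error(frame, target)
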
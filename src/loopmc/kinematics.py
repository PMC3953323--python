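"""Articulated-chain representation and forward kinematics.

A chain is a sequence of N revolute joints.  Frame j is obtained from frame
j-1 by a fixed rigid transform followed by a rotation of q_j about the joint
axis expressed in the local frame:

    T_j = T_{j-1} @ T_rel_j @ R(a_j, q_j)

Each frame's origin lies on its joint axis, so rotating a joint leaves its own
frame origin fixed.  Planar chains are the specialization where every axis is
the out-of-plane +z axis and all translations are in-plane.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rigid import is_rigid, make_transform, rotation_about_axis

__all__ = ["Chain", "ExpandedState", "forward_kinematics", "planar_chain", "measure_dihedral"]


@dataclass
class Chain:
    """Topology and fixed geometry of a revolute chain.

    axes : (N, 3) unit rotation axes, expressed in each joint's local frame
    rel_transforms : (N, 4, 4) fixed rigid transforms T_rel_j
    base_frame : T_0
    end_frame_constraint : optional fixed target for T_N (loop closure)
    topology : 'linear' (closed loop when end constraint set) or 'free'
    """

    axes: np.ndarray
    rel_transforms: np.ndarray
    base_frame: np.ndarray = field(default_factory=lambda: np.eye(4))
    end_frame_constraint: np.ndarray | None = None
    topology: str = "linear"

    def __post_init__(self) -> None:
        self.axes = np.asarray(self.axes, dtype=float)
        self.rel_transforms = np.asarray(self.rel_transforms, dtype=float)
        if self.axes.ndim != 2 or self.axes.shape[1] != 3:
            raise ValueError("axes must have shape (N, 3)")
        if self.rel_transforms.shape != (self.n_joints, 4, 4):
            raise ValueError("rel_transforms must have shape (N, 4, 4)")
        norms = np.linalg.norm(self.axes, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("joint axes must be unit vectors")
        for T in self.rel_transforms:
            if not is_rigid(T, tol=1e-7):
                raise ValueError("rel_transforms must be rigid (orthonormal rotation, det +1)")
        if not is_rigid(self.base_frame, tol=1e-7):
            raise ValueError("base_frame must be rigid")
        if self.end_frame_constraint is not None and not is_rigid(
            np.asarray(self.end_frame_constraint), tol=1e-7
        ):
            raise ValueError("end_frame_constraint must be rigid")

    @property
    def n_joints(self) -> int:
        return self.axes.shape[0]

    @property
    def is_planar(self) -> bool:
        z = np.array([0.0, 0.0, 1.0])
        return bool(
            np.allclose(self.axes, z[None, :], atol=1e-10)
            and np.allclose(self.rel_transforms[:, 2, 3], 0.0, atol=1e-10)
        )

    def subchain(self, start: int, stop: int, base_frame: np.ndarray) -> "Chain":
        """Joints start..stop-1 as a stand-alone chain rooted at ``base_frame``."""
        return Chain(
            axes=self.axes[start:stop].copy(),
            rel_transforms=self.rel_transforms[start:stop].copy(),
            base_frame=base_frame,
            topology="free",
        )


@dataclass
class ExpandedState:
    """Joint angles together with the spatial variables they determine.

    angles : (N,) radians
    frames : (N, 4, 4) frames T_1..T_N (T_0 is the chain base)
    atom_positions : optional (M, 3) Cartesian coordinates derived from frames
    """

    angles: np.ndarray
    frames: np.ndarray
    atom_positions: np.ndarray | None = None

    def copy(self) -> "ExpandedState":
        return ExpandedState(
            self.angles.copy(),
            self.frames.copy(),
            None if self.atom_positions is None else self.atom_positions.copy(),
        )


def forward_kinematics(
    chain: Chain, angles: np.ndarray, base: np.ndarray | None = None
) -> np.ndarray:
    """Frames T_1..T_N of ``chain`` at the given joint angles.

    Purely functional: identical inputs give bitwise-identical output.
    """
    q = np.asarray(angles, dtype=float)
    if q.shape != (chain.n_joints,):
        raise ValueError(f"expected {chain.n_joints} angles, got {q.shape}")
    T = chain.base_frame if base is None else np.asarray(base, dtype=float)
    frames = np.empty((chain.n_joints, 4, 4))
    for j in range(chain.n_joints):
        T = T @ chain.rel_transforms[j] @ make_transform(
            R=rotation_about_axis(chain.axes[j], q[j])
        )
        frames[j] = T
    return frames


def fk_batch(chain: Chain, angles: np.ndarray, base: np.ndarray | None = None) -> np.ndarray:
    """Vectorized terminal frames for a (K, N) batch of angle vectors.

    Returns a (K, 4, 4) array of T_N only (used by the multistart IK solver).
    """
    q = np.asarray(angles, dtype=float)
    K, N = q.shape
    T0 = chain.base_frame if base is None else np.asarray(base, dtype=float)
    T = np.broadcast_to(T0, (K, 4, 4)).copy()
    for j in range(N):
        R = _rotation_batch(chain.axes[j], q[:, j])
        M = np.zeros((K, 4, 4))
        M[:, :3, :3] = R
        M[:, 3, 3] = 1.0
        T = T @ chain.rel_transforms[j][None] @ M
    return T


def fk_batch_all(chain: Chain, angles: np.ndarray, base: np.ndarray | None = None) -> np.ndarray:
    """Vectorized frames (K, N, 4, 4) for a (K, N) batch of angle vectors."""
    q = np.asarray(angles, dtype=float)
    K, N = q.shape
    T0 = chain.base_frame if base is None else np.asarray(base, dtype=float)
    T = np.broadcast_to(T0, (K, 4, 4)).copy()
    out = np.empty((K, N, 4, 4))
    for j in range(N):
        R = _rotation_batch(chain.axes[j], q[:, j])
        M = np.zeros((K, 4, 4))
        M[:, :3, :3] = R
        M[:, 3, 3] = 1.0
        T = T @ chain.rel_transforms[j][None] @ M
        out[:, j] = T
    return out


def _rotation_batch(axis: np.ndarray, angles: np.ndarray) -> np.ndarray:
    a = axis / np.linalg.norm(axis)
    K = np.array([[0.0, -a[2], a[1]], [a[2], 0.0, -a[0]], [-a[1], a[0], 0.0]])
    s = np.sin(angles)[:, None, None]
    c = (1.0 - np.cos(angles))[:, None, None]
    return np.eye(3)[None] + s * K[None] + c * (K @ K)[None]


def planar_chain(
    link_lengths,
    base_pose=(0.0, 0.0, 0.0),
    end_pose=None,
) -> Chain:
    """Planar revolute chain: joint j translates by L_j along local x, then
    rotates about +z.  Poses are (x, y, theta)."""
    L = np.asarray(link_lengths, dtype=float)
    n = L.shape[0]
    axes = np.tile(np.array([0.0, 0.0, 1.0]), (n, 1))
    rel = np.tile(np.eye(4), (n, 1, 1))
    rel[:, 0, 3] = L
    base = _pose_to_transform(base_pose)
    end = None if end_pose is None else _pose_to_transform(end_pose)
    return Chain(axes=axes, rel_transforms=rel, base_frame=base,
                 end_frame_constraint=end, topology="linear")


def _pose_to_transform(pose) -> np.ndarray:
    x, y, th = pose
    return make_transform(R=rotation_about_axis([0, 0, 1], th), t=np.array([x, y, 0.0]))


def measure_dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (radians, IUPAC convention) of four points."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1n)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return float(-np.arctan2(y, x))
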
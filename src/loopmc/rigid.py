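"""Rigid-body transform utilities on 4x4 homogeneous matrices.

All rotations are proper (det +1); translations are in Angstrom for molecular
chains and in arbitrary length units for planar test chains.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "rotation_about_axis",
    "make_transform",
    "inverse_transform",
    "rotation_log",
    "frame_from_zx",
    "is_rigid",
    "frame_error",
    "apply_transform",
]


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix for a unit ``axis`` and ``angle`` in radians."""
    a = np.asarray(axis, dtype=float)
    n = np.linalg.norm(a)
    if not np.isfinite(n) or n == 0.0:
        raise ValueError("rotation axis must be a nonzero vector")
    a = a / n
    K = np.array([[0.0, -a[2], a[1]], [a[2], 0.0, -a[0]], [-a[1], a[0], 0.0]])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def make_transform(R: np.ndarray | None = None, t: np.ndarray | None = None) -> np.ndarray:
    T = np.eye(4)
    if R is not None:
        T[:3, :3] = R
    if t is not None:
        T[:3, 3] = t
    return T


def inverse_transform(T: np.ndarray) -> np.ndarray:
    """Inverse of a rigid transform (uses orthonormality of the rotation block)."""
    R = T[:3, :3]
    out = np.eye(4)
    out[:3, :3] = R.T
    out[:3, 3] = -R.T @ T[:3, 3]
    return out


def apply_transform(T: np.ndarray, p: np.ndarray) -> np.ndarray:
    return T[:3, :3] @ np.asarray(p, dtype=float) + T[:3, 3]


def rotation_log(R: np.ndarray) -> np.ndarray:
    """Rotation vector (axis * angle) of a rotation matrix.

    Stable for small angles; for angles near pi the axis is recovered from the
    symmetric part of R.
    """
    c = (np.trace(R) - 1.0) / 2.0
    c = min(1.0, max(-1.0, c))
    w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    s = np.linalg.norm(w)
    # atan2 avoids the arccos cancellation near the identity
    angle = np.arctan2(s / 2.0, c)
    if angle < 1e-8:
        return 0.5 * w
    if np.pi - angle < 1e-6:
        # near pi: R ~ 2 a a^T - I
        A = (R + np.eye(3)) / 2.0
        axis = np.sqrt(np.maximum(np.diag(A), 0.0))
        # fix signs from off-diagonals
        i = int(np.argmax(axis))
        axis = A[:, i] / axis[i]
        axis = axis / np.linalg.norm(axis)
        # choose sign consistent with w when it is not vanishing
        if s > 1e-12 and np.dot(axis, w) < 0:
            axis = -axis
        return axis * angle
    return w * (angle / s)


def frame_from_zx(origin: np.ndarray, z_dir: np.ndarray, x_ref: np.ndarray) -> np.ndarray:
    """Right-handed frame with given origin, z along ``z_dir`` and x toward the
    component of ``x_ref - origin`` orthogonal to z."""
    z = np.asarray(z_dir, dtype=float)
    z = z / np.linalg.norm(z)
    v = np.asarray(x_ref, dtype=float) - np.asarray(origin, dtype=float)
    x = v - np.dot(v, z) * z
    n = np.linalg.norm(x)
    if n < 1e-10:
        # reference collinear with z: pick any orthogonal direction
        x = np.cross(z, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(x) < 1e-6:
            x = np.cross(z, np.array([0.0, 1.0, 0.0]))
        n = np.linalg.norm(x)
    x = x / n
    y = np.cross(z, x)
    T = np.eye(4)
    T[:3, 0] = x
    T[:3, 1] = y
    T[:3, 2] = z
    T[:3, 3] = origin
    return T


def is_rigid(T: np.ndarray, tol: float = 1e-8) -> bool:
    R = T[:3, :3]
    return (
        T.shape == (4, 4)
        and np.allclose(R.T @ R, np.eye(3), atol=tol)
        and abs(np.linalg.det(R) - 1.0) < max(tol, 1e-8)
        and np.allclose(T[3], [0, 0, 0, 1], atol=tol)
    )


def frame_error(T: np.ndarray, T_target: np.ndarray) -> tuple[float, float]:
    """(position error, rotation Frobenius error) between two frames."""
    dp = float(np.linalg.norm(T[:3, 3] - T_target[:3, 3]))
    dR = float(np.linalg.norm(T[:3, :3] - T_target[:3, :3]))
    return dp, dR
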
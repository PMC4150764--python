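"""Small rotation/superposition helpers shared by the geometry modules."""

from __future__ import annotations

import numpy as np


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about a (not necessarily unit) axis."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be non-zero")
    x, y, z = axis / n
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    C = 1.0 - c
    return np.array(
        [
            [x * x * C + c, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, y * y * C + c, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, z * z * C + c],
        ]
    )


def rot_x(angle_deg: float) -> np.ndarray:
    return rotation_about_axis(np.array([1.0, 0.0, 0.0]), angle_deg)


def rot_y(angle_deg: float) -> np.ndarray:
    return rotation_about_axis(np.array([0.0, 1.0, 0.0]), angle_deg)


def rot_z(angle_deg: float) -> np.ndarray:
    return rotation_about_axis(np.array([0.0, 0.0, 1.0]), angle_deg)


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in degrees, numerically safe at 0/180."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    cross = np.linalg.norm(np.cross(u, v))
    dot = float(np.dot(u, v))
    return float(np.degrees(np.arctan2(cross, dot)))


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, IUPAC sign convention,
    in (-180, 180]."""
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b3 = np.asarray(p4, float) - np.asarray(p3, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares superposition of `mobile` onto `target` (both (n,3)).

    Returns (R, t, rmsd) with target ≈ mobile @ R.T + t and R a proper
    rotation (det +1).
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    H = (mobile - cm).T @ (target - ct)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return R, t, rmsd


def orthonormal_midframe(r1: np.ndarray, r2: np.ndarray) -> np.ndarray:
    """Exact halfway rotation between two frames: r1 rotated by half the
    angle of r1->r2 about their common hinge axis."""
    rel = r1.T @ r2
    angle, axis = rotation_angle_axis(rel)
    if angle < 1e-12:
        return r1.copy()
    half = rotation_about_axis(axis, angle / 2.0)
    return r1 @ half


def rotation_angle_axis(R: np.ndarray) -> tuple[float, np.ndarray]:
    """Angle (degrees, >= 0) and unit axis of a rotation matrix."""
    tr = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = float(np.degrees(np.arccos(tr)))
    ax = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    n = np.linalg.norm(ax)
    if n < 1e-12:
        if angle < 90.0:  # identity
            return 0.0, np.array([0.0, 0.0, 1.0])
        # 180 degree rotation: axis from R + I columns
        M = R + np.eye(3)
        col = M[:, np.argmax(np.linalg.norm(M, axis=0))]
        return 180.0, col / np.linalg.norm(col)
    return angle, ax / n


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )
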
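"""Rotation, quaternion and chain-geometry helpers.

Quaternions are stored as (w, x, y, z) with unit norm; q and -q denote the
same rotation (double cover of SO(3)).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "quat_to_matrix",
    "matrix_to_quat",
    "quat_multiply",
    "random_quat",
    "rotation_about_axis",
    "kabsch",
    "slerp",
    "place_atom_nerf",
]


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a unit quaternion (w, x, y, z)."""
    w, x, y, z = np.asarray(q, dtype=float)
    n = w * w + x * x + y * y + z * z
    if n <= 0:
        raise ValueError("zero quaternion")
    s = 2.0 / n
    return np.array(
        [
            [1 - s * (y * y + z * z), s * (x * y - w * z), s * (x * z + w * y)],
            [s * (x * y + w * z), 1 - s * (x * x + z * z), s * (y * z - w * x)],
            [s * (x * z - w * y), s * (y * z + w * x), 1 - s * (x * x + y * y)],
        ]
    )


def matrix_to_quat(R: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) of a proper rotation matrix.

    Returns the representative with w >= 0.
    """
    R = np.asarray(R, dtype=float)
    # Shepperd's method: pick the largest diagonal combination for stability.
    t = np.trace(R)
    if t > 0:
        r = np.sqrt(1.0 + t)
        w = 0.5 * r
        x = (R[2, 1] - R[1, 2]) / (2 * r)
        y = (R[0, 2] - R[2, 0]) / (2 * r)
        z = (R[1, 0] - R[0, 1]) / (2 * r)
    else:
        i = int(np.argmax(np.diag(R)))
        j, k = (i + 1) % 3, (i + 2) % 3
        r = np.sqrt(1.0 + R[i, i] - R[j, j] - R[k, k])
        q = np.empty(4)
        q[1 + i] = 0.5 * r
        q[0] = (R[k, j] - R[j, k]) / (2 * r)
        q[1 + j] = (R[j, i] + R[i, j]) / (2 * r)
        q[1 + k] = (R[k, i] + R[i, k]) / (2 * r)
        w, x, y, z = q
    q = np.array([w, x, y, z])
    q /= np.linalg.norm(q)
    if q[0] < 0:
        q = -q
    return q


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return np.array(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ]
    )


def random_quat(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation (Shoemake / marsaglia via normal deviates)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    if q[0] < 0:
        q = -q
    return q


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (not necessarily unit) axis."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("zero axis")
    u = axis / n
    c, s = np.cos(angle), np.sin(angle)
    ux, uy, uz = u
    K = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(u, u)


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of P onto Q (same atom order).

    Returns (R, t, rmsd) such that P @ R.T + t approximates Q.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return R, t, rmsd


def slerp(a: np.ndarray, b: np.ndarray, frac: float) -> np.ndarray:
    """Spherical interpolation from quaternion a toward b by fraction frac.

    b is sign-aligned to a first (shortest arc on the double cover).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    dot = float(np.dot(a, b))
    if dot < 0:
        b = -b
        dot = -dot
    dot = min(dot, 1.0)
    if dot > 1.0 - 1e-12:
        out = a + frac * (b - a)
    else:
        theta = np.arccos(dot)
        out = (np.sin((1 - frac) * theta) * a + np.sin(frac * theta) * b) / np.sin(theta)
    out = out / np.linalg.norm(out)
    return out


def place_atom_nerf(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, torsion: float
) -> np.ndarray:
    """Place atom D given atoms A-B-C, the C-D bond length, the B-C-D angle
    and the A-B-C-D torsion (natural extension reference frame)."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        # Colinear predecessor frame: pick any perpendicular.
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(bc, helper)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
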
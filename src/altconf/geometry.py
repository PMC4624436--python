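"""Small 3-D geometry toolbox shared across the package.

All positions are Cartesian angstroms in plain ``numpy`` arrays; rotations
are proper 3x3 matrices.  Angles are degrees at the API surface (the field's
convention for dihedrals) and radians internally.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "normalize",
    "rotation_about_axis",
    "kabsch",
    "rigid_transform",
    "apply_rigid",
    "dihedral",
    "bond_angle",
    "place_atom",
    "signed_angle_about_axis",
]


def normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalize zero-length vector")
    return v / n


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` (need not be unit length)."""
    return rotation_about_axis_rad(axis, float(np.deg2rad(angle_deg)))


def rotation_about_axis_rad(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix, radians input, scalar-assembled (fast
    path for kinematics inner loops)."""
    x, y, z = (float(v) for v in axis)
    n = (x * x + y * y + z * z) ** 0.5
    if n < 1e-12:
        raise ValueError("cannot normalize zero-length vector")
    x, y, z = x / n, y / n, z / n
    c = np.cos(angle_rad)
    s = np.sin(angle_rad)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares proper rotation ``R`` and translation ``t`` with
    ``R @ mobile.T + t`` closest to ``target`` (Kabsch algorithm)."""
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def rigid_transform(R: np.ndarray, t: np.ndarray, coords: np.ndarray) -> np.ndarray:
    return coords @ R.T + t


apply_rigid = rigid_transform


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = normalize(np.asarray(a, float) - b)
    v = normalize(np.asarray(c, float) - b)
    return float(np.rad2deg(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.rad2deg(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position of atom d bonded to c with the given
    internal coordinates relative to the a-b-c frame."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    bc = normalize(c - b)
    n = normalize(np.cross(b - a, bc))
    m = np.cross(n, bc)
    ang = np.deg2rad(180.0 - angle_deg)
    tor = np.deg2rad(-torsion_deg)  # so that dihedral(a, b, c, d) == torsion_deg
    d_local = bond * np.array(
        [np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def signed_angle_about_axis(v1: np.ndarray, v2: np.ndarray, axis: np.ndarray) -> float:
    """Signed angle (deg) from v1 to v2 measured in the plane normal to axis."""
    u = normalize(np.asarray(axis, float))
    a = np.asarray(v1, float) - np.dot(v1, u) * u
    b = np.asarray(v2, float) - np.dot(v2, u) * u
    if np.linalg.norm(a) < 1e-9 or np.linalg.norm(b) < 1e-9:
        return 0.0
    x = np.dot(a, b)
    y = np.dot(np.cross(a, b), u)
    return float(np.rad2deg(np.arctan2(y, x)))
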
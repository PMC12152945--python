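"""Low-level 3D geometry: internal-coordinate placement, torsions, superposition.

All coordinates are Cartesian angstroms, angles in degrees unless noted.
"""
from __future__ import annotations

import numpy as np


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               distance: float, angle: float, dihedral: float) -> np.ndarray:
    """Place a new atom D bonded to ``c`` using internal coordinates.

    ``distance`` is |D-c|, ``angle`` is the b-c-D angle and ``dihedral`` the
    a-b-c-D torsion (degrees).  Standard NeRF construction.
    """
    ang = np.deg2rad(angle)
    dih = np.deg2rad(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        # colinear reference frame: pick any perpendicular
        n = np.cross(bc, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(n) < 1e-10:
            n = np.cross(bc, np.array([0.0, 1.0, 0.0]))
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -distance * np.cos(ang),
        distance * np.sin(ang) * np.cos(dih),
        -distance * np.sin(ang) * np.sin(dih),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def place_atom_batch(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                     distance: float, angle: float,
                     dihedral: np.ndarray) -> np.ndarray:
    """Vectorized ``place_atom``: a, b, c are (K, 3); dihedral is (K,) deg."""
    ang = np.deg2rad(angle)
    dih = np.deg2rad(np.asarray(dihedral, dtype=float))
    bc = c - b
    bc /= np.linalg.norm(bc, axis=1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    m = np.cross(n, bc)
    d0 = -distance * np.cos(ang)
    d1 = distance * np.sin(ang) * np.cos(dih)
    d2 = -distance * np.sin(ang) * np.sin(dih)
    return c + d0 * bc + d1[:, None] * m + d2[:, None] * n


def distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a - b))


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                   d: np.ndarray) -> float:
    """Torsion a-b-c-d in degrees, in (-180, 180]."""
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.rad2deg(np.arctan2(y, x)))


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation about ``axis`` (need not be normalized)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.deg2rad(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def random_rotation(rng: np.random.Generator, max_angle_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    angle = rng.uniform(-max_angle_deg, max_angle_deg)
    return rotation_matrix(axis, angle)


def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Optimal rotation R and translation t minimizing |R@mobile.T+t - target|.

    Returns (R, t) such that mobile @ R.T + t approximates target.
    Utility only: the selection metrics of this package are in-place and never
    use superposition.
    """
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    return R, t


def rmsd_inplace(a: np.ndarray, b: np.ndarray) -> float:
    """In-place (no superposition) RMSD between matched coordinate arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
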
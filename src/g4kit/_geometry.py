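"""Low-level vector geometry shared by all modules.

All angles are in degrees, all distances in Angstrom.  Dihedral signs
follow the IUPAC convention (clockwise rotation of the far bond viewed
along the central bond is positive).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "dihedral",
    "bond_angle",
    "place_atom",
    "tetrahedral_directions",
    "fit_plane",
    "kabsch",
    "rotation_about_axis",
]


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = -np.degrees(np.arctan2(y, x))
    # map -180 -> +180 so the range is (-180, 180]
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def bond_angle(p0, p1, p2) -> float:
    """Angle p0-p1-p2 at vertex p1, degrees in [0, 180]."""
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    v1 = p0 - p1
    v2 = p2 - p1
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d with |c-d| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (NeRF construction)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.radians(angle)
    tor = np.radians(torsion)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def tetrahedral_directions(center, nb1, nb2):
    """Unit vectors of the two free tetrahedral slots of ``center`` whose
    occupied slots point to ``nb1`` and ``nb2``.

    Returns ``(d_plus, d_minus)`` where ``d_plus`` lies on the side of the
    nb1/nb2/center plane toward ``cross(nb1-center, nb2-center)``.
    """
    center, nb1, nb2 = (np.asarray(p, dtype=float) for p in (center, nb1, nb2))
    u1 = nb1 - center
    u1 /= np.linalg.norm(u1)
    u2 = nb2 - center
    u2 /= np.linalg.norm(u2)
    bis = -(u1 + u2)
    bis /= np.linalg.norm(bis)
    n = np.cross(u1, u2)
    n /= np.linalg.norm(n)
    # angle between the two remaining slots ~ 109.47 deg, symmetric about bis
    half = np.radians(109.47 / 2.0)
    d_plus = bis * np.cos(half) + n * np.sin(half)
    d_minus = bis * np.cos(half) - n * np.sin(half)
    return d_plus / np.linalg.norm(d_plus), d_minus / np.linalg.norm(d_minus)


def fit_plane(points):
    """Least-squares plane through ``points``.

    Returns ``(centroid, normal, residuals)``; the normal sign follows the
    right-hand rule of the point ordering (cross products of consecutive
    centered points), so planar rings keep a reproducible orientation.
    """
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    # orient by the ring winding sense
    winding = np.zeros(3)
    for i in range(len(centered)):
        winding += np.cross(centered[i - 1], centered[i])
    if np.dot(normal, winding) < 0:
        normal = -normal
    residuals = centered @ normal
    return centroid, normal, residuals


def kabsch(mobile, target):
    """Optimal rotation/translation superposing ``mobile`` onto ``target``.

    Returns ``(R, t, rmsd)`` with reflections excluded (det(R) = +1);
    apply as ``coords @ R.T + t``.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.shape[0] < 3:
        raise ValueError("need two equal coordinate sets with >= 3 atoms")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    # degenerate (e.g. collinear) selections have no unique rotation
    if S[1] < 1e-8 * max(S[0], 1.0):
        raise ValueError("degenerate coordinate set (collinear or coincident points)")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(((moved - Q) ** 2).sum() / P.shape[0]))
    return R, t, rmsd


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(a) * K + (1.0 - np.cos(a)) * (K @ K)
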
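"""Small linear-algebra helpers: rotations, plane fits, superposition."""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def rot_x(deg: float) -> np.ndarray:
    return Rotation.from_euler("x", deg, degrees=True).as_matrix()


def rot_y(deg: float) -> np.ndarray:
    return Rotation.from_euler("y", deg, degrees=True).as_matrix()


def rot_z(deg: float) -> np.ndarray:
    return Rotation.from_euler("z", deg, degrees=True).as_matrix()


def rotation_about_axis(axis: np.ndarray, deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(np.radians(deg) * axis).as_matrix()


def plane_normal(coords: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane through >= 3 points.

    The sign is canonicalized so the component of largest magnitude is
    positive; callers that need an oriented normal fold angles into
    [0, 90] degrees anyway.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 3:
        raise ValueError("plane fit needs at least 3 points")
    centred = coords - coords.mean(axis=0)
    # normal = singular vector of the smallest singular value
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    n = vt[-1]
    k = int(np.argmax(np.abs(n)))
    if n[k] < 0:
        n = -n
    return n / np.linalg.norm(n)


def angle_between(u: np.ndarray, v: np.ndarray, fold: bool = False) -> float:
    """Angle between two vectors in degrees; ``fold`` maps into [0, 90]."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    c = min(1.0, max(-1.0, c))
    ang = float(np.degrees(np.arccos(c)))
    if fold and ang > 90.0:
        ang = 180.0 - ang
    return ang


def superpose(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns ``(R, t, rmsd)`` with ``moved = mobile @ R.T + t``.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape:
        raise ValueError("superpose needs equally sized coordinate sets")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    R = rot.as_matrix()
    t = tc - mc @ R.T
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return R, t, rmsd


def torsion(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def place_by_torsion(a, b, c, bond: float, angle_deg: float,
                     torsion_deg: float) -> np.ndarray:
    """Place atom D given A, B, C with |CD|, angle BCD and torsion ABCD."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d_local = bond * np.array([
        -np.cos(ang),
        -np.sin(ang) * np.cos(tor),
        -np.sin(ang) * np.sin(tor),
    ])
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local
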
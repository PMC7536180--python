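"""Low-level vector geometry shared across the package.

All angles are in degrees unless a function name says otherwise; coordinates
are plain ``(3,)`` / ``(n, 3)`` float64 arrays in Angstrom.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "angle",
    "dihedral",
    "rotation_about_axis",
    "rotation_angle",
    "twist_about_axis",
    "place_atom",
    "fit_line",
    "fibonacci_sphere",
]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("zero-length vector")
    return v / n


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees, in [0, 180]."""
    u = _unit(np.asarray(a, float) - b)
    w = _unit(np.asarray(c, float) - b)
    return float(np.degrees(np.arccos(np.clip(u @ w, -1.0, 1.0))))


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle p1-p2-p3-p4, IUPAC sign convention, range (-180, 180].

    Positive when, looking from p2 towards p3, the far bond p3-p4 rotates
    clockwise relative to the near bond p2-p1.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = n1 @ n2
    y = m1 @ n2
    ang = float(np.degrees(np.arctan2(-y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Proper rotation matrix for a right-handed rotation about ``axis``."""
    a = _unit(np.asarray(axis, float))
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    x, y, z = a
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) * c + s * K + (1.0 - c) * np.outer(a, a)


def rotation_angle(R: np.ndarray) -> float:
    """Magnitude in degrees of the rotation encoded by a 3x3 matrix."""
    tr = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.degrees(np.arccos(tr)))


def twist_about_axis(R: np.ndarray, axis: np.ndarray) -> float:
    """Signed twist component (degrees) of rotation ``R`` about ``axis``.

    Uses the quaternion swing-twist decomposition; the sign follows the
    right-hand rule about the oriented axis.
    """
    a = _unit(np.asarray(axis, float))
    # quaternion from rotation matrix (w, x, y, z)
    tr = np.trace(R)
    if tr > 0:
        w = np.sqrt(1.0 + tr) / 2.0
        v = np.array(
            [R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]]
        ) / (4.0 * w)
    else:
        i = int(np.argmax(np.diag(R)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(1.0 + R[i, i] - R[j, j] - R[k, k]) * 2.0
        v = np.zeros(3)
        v[i] = s / 4.0
        v[j] = (R[j, i] + R[i, j]) / s
        v[k] = (R[k, i] + R[i, k]) / s
        w = (R[k, j] - R[j, k]) / s
    proj = v @ a
    twist = 2.0 * np.degrees(np.arctan2(proj, w))
    # normalise to (-180, 180]
    while twist <= -180.0:
        twist += 360.0
    while twist > 180.0:
        twist -= 360.0
    return float(twist)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, ang: float, tors: float) -> np.ndarray:
    """Place atom D given three reference atoms using internal coordinates.

    D is at distance ``bond`` from ``c``, with angle(b, c, D) = ``ang`` and
    dihedral(a, b, c, D) = ``tors`` (degrees).
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    t = np.radians(tors)
    th = np.radians(ang)
    d_local = np.array(
        [
            -bond * np.cos(th),
            bond * np.sin(th) * np.cos(t),
            bond * np.sin(th) * np.sin(t),
        ]
    )
    M = np.column_stack([bc, m, n])
    return c + M @ d_local


def fit_line(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component line fit: returns (centroid, unit direction).

    The direction is oriented from the first point towards the last so that
    successive calls on the same ordered set are reproducible.
    """
    pts = np.asarray(points, float)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    d = vt[0]
    if (pts[-1] - pts[0]) @ d < 0:
        d = -d
    return centroid, d


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )
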
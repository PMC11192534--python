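"""Small vector-geometry helpers shared by the sampling and fixture modules.

All angles are in degrees, all lengths in Angstrom.  Coordinates are plain
``(3,)`` or ``(n, 3)`` float64 numpy arrays; nothing here knows about atoms.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "bond_angle",
    "dihedral",
    "place_atom",
    "rotation_about_axis",
    "rotate_about_bond",
]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = _unit(np.asarray(a, float) - b)
    w = _unit(np.asarray(c, float) - b)
    return float(np.degrees(np.arccos(np.clip(u @ w, -1.0, 1.0))))


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed torsion a-b-c-d in degrees, IUPAC convention (-180, 180]."""
    b0 = np.asarray(a, float) - b
    b1 = np.asarray(c, float) - b
    b2 = np.asarray(d, float) - c
    n1 = np.cross(b0, b1)
    n2 = np.cross(b2, b1)
    m1 = np.cross(n1, _unit(b1))
    x = n1 @ n2
    y = m1 @ n2
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 else ang


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    r: float,
    theta: float,
    tau: float,
) -> np.ndarray:
    """Place atom x so that |x-c| = r, angle(x,c,b) = theta, dihedral(x,c,b,a) = tau.

    The standard NeRF (natural extension reference frame) construction used by
    internal-coordinate model builders.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    th = np.radians(theta)
    ta = np.radians(tau)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -r * np.cos(th),
            r * np.sin(th) * np.cos(ta),
            -r * np.sin(th) * np.sin(ta),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """3x3 rotation matrix for a right-handed rotation about *axis*."""
    u = _unit(np.asarray(axis, float))
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    ux, uy, uz = u
    cross = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return c * np.eye(3) + s * cross + (1 - c) * np.outer(u, u)


def rotate_about_bond(
    coords: np.ndarray,
    p1: np.ndarray,
    p2: np.ndarray,
    angle_deg: float,
) -> np.ndarray:
    """Rotate *coords* about the axis p1->p2 by *angle_deg* (right-handed).

    Used to drive dihedral changes: rotating the atoms downstream of bond
    p1-p2 by delta increases the torsion (a, p1, p2, x) by delta for every
    downstream atom x.
    """
    R = rotation_about_axis(np.asarray(p2, float) - p1, -angle_deg)
    return (np.asarray(coords, float) - p2) @ R.T + p2
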
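"""Small 3-D geometry helpers: internal-coordinate atom placement, angles,
dihedrals and axis rotations.

All positions are numpy float64 arrays of shape (3,), units are Angstrom,
angles are degrees at the public surface (radians internally).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "unit",
    "angle_deg",
    "dihedral_deg",
    "place_atom",
    "rotate_about_axis",
]


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("zero-length vector")
    return v / n


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, in degrees."""
    u = unit(a - b)
    v = unit(c - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def dihedral_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed dihedral a-b-c-d in degrees, range (-180, 180]."""
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, unit(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle: float,
    dihedral: float,
) -> np.ndarray:
    """Place atom D bonded to c with |D-c| = bond, angle(D, c, b) = angle
    and dihedral(D, c, b, a) = dihedral (degrees). Standard NeRF-style
    internal-to-Cartesian conversion.
    """
    ang = np.radians(angle)
    dih = -np.radians(dihedral)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [
            -np.cos(ang),
            np.sin(ang) * np.cos(dih),
            np.sin(ang) * np.sin(dih),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotate_about_axis(
    points: np.ndarray,
    origin: np.ndarray,
    axis: np.ndarray,
    angle: float,
) -> np.ndarray:
    """Rotate point(s) about the axis through `origin` with direction
    `axis` by `angle` degrees (right-handed). Accepts shape (3,) or (n, 3).
    """
    u = unit(axis)
    t = np.radians(angle)
    c, s = np.cos(t), np.sin(t)
    # Rodrigues rotation matrix
    ux, uy, uz = u
    k = np.array([[0.0, -uz, uy], [uz, 0.0, -ux], [-uy, ux, 0.0]])
    rot = np.eye(3) * c + s * k + (1.0 - c) * np.outer(u, u)
    p = np.atleast_2d(points) - origin
    out = p @ rot.T + origin
    return out[0] if np.ndim(points) == 1 else out
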
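"""Small 3-D geometry helpers shared by structure building and h-bond detection.

All coordinates are Cartesian, in Angstroms; all angles are in degrees
unless a name says otherwise. Dihedral sign follows the IUPAC convention
(clockwise positive when viewed from atom b toward atom c).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "angle_deg",
    "dihedral_deg",
    "place_atom",
    "rotate_about_axis",
    "kabsch_transform",
]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("zero-length vector")
    return v / n


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b."""
    u = _unit(np.asarray(a, float) - np.asarray(b, float))
    v = _unit(np.asarray(c, float) - np.asarray(b, float))
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def dihedral_deg(a, b, c, d) -> float:
    """Torsion angle of the chain a-b-c-d in (-180, 180]."""
    a, b, c, d = (np.asarray(x, float) for x in (a, b, c, d))
    b0 = a - b
    b1 = _unit(c - b)
    b2 = d - c
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond_length: float, bond_angle: float,
               torsion: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom d.

    Returns the point at ``bond_length`` from c, with angle b-c-d equal to
    ``bond_angle`` and dihedral a-b-c-d equal to ``torsion``.
    """
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    theta = np.radians(bond_angle)
    chi = np.radians(torsion)
    d_local = bond_length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.stack([bc, np.cross(n, bc), n], axis=1)
    return c + m @ d_local


def rotate_about_axis(points: np.ndarray, origin: np.ndarray,
                      axis: np.ndarray, angle_degrees: float) -> np.ndarray:
    """Rodrigues rotation of points about the line (origin, axis)."""
    points = np.atleast_2d(np.asarray(points, float))
    k = _unit(np.asarray(axis, float))
    theta = np.radians(angle_degrees)
    p = points - origin
    rotated = (p * np.cos(theta)
               + np.cross(k, p) * np.sin(theta)
               + np.outer(p @ k, k) * (1.0 - np.cos(theta)))
    return rotated + origin


def kabsch_transform(mobile: np.ndarray, target: np.ndarray):
    """Rigid transform (R, t) minimizing ||R @ mobile.T + t - target||.

    Returns (rotation 3x3, translation 3-vector); apply as ``x @ R.T + t``.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    return rot, tc - rot @ mc
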
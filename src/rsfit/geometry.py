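"""Small 3-D geometry helpers shared across the package.

All angles are in degrees unless a name says otherwise; all lengths in
angstroms.  Vectors are numpy arrays of shape (3,) (or (n, 3) for the
vectorised variants).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "angle_deg",
    "dihedral_deg",
    "place_atom",
    "rotation_about_axis",
    "wrap_degrees",
]


def wrap_degrees(a):
    """Map an angle (or array of angles) into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    w = -((-a + 180.0) % 360.0 - 180.0)
    return float(w) if w.ndim == 0 else w


def angle_deg(a, b, c) -> float:
    """Angle a-b-c at vertex b."""
    u = np.asarray(a, float) - b
    v = np.asarray(c, float) - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral_deg(a, b, c, d) -> float:
    """Signed dihedral a-b-c-d, IUPAC convention, in (-180, 180]."""
    b0 = np.asarray(a, float) - b
    b1 = np.asarray(c, float) - b
    b2 = np.asarray(d, float) - c
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return wrap_degrees(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of a new atom bonded to ``c``.

    The new point d satisfies |d-c| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = dihedral.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    ang = np.radians(angle)
    tor = np.radians(dihedral)
    d_local = bond * np.array(
        [
            -np.cos(ang),
            np.sin(ang) * np.cos(tor),
            np.sin(ang) * np.sin(tor),
        ]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    norm_n = np.linalg.norm(n)
    if norm_n < 1e-12:
        # a, b, c collinear: any perpendicular will do; dihedral is then
        # measured from an arbitrary but deterministic reference.
        helper = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(helper, bc)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        norm_n = np.linalg.norm(n)
    n /= norm_n
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def rotation_about_axis(axis_point, axis_dir, angle: float) -> tuple[np.ndarray, np.ndarray]:
    """Rotation by ``angle`` about the line through ``axis_point`` along
    ``axis_dir``; returns (R, t) so that x -> R @ x + t."""
    k = np.asarray(axis_dir, float)
    k = k / np.linalg.norm(k)
    th = np.radians(angle)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    R = np.eye(3) + np.sin(th) * K + (1.0 - np.cos(th)) * (K @ K)
    p = np.asarray(axis_point, float)
    t = p - R @ p
    return R, t
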
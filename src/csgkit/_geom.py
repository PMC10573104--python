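"""Internal geometry primitives: signed torsions and NeRF atom placement.

These are shared by the descriptor code (torsion measurement), the
glutathione grafter and the toy-peptide builder (internal-coordinate
construction).  Angles are degrees everywhere at this surface.
"""

from __future__ import annotations

import numpy as np


def torsion(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed IUPAC torsion angle p1-p2-p3-p4 in degrees, in (-180, 180].

    cis (eclipsed) is 0; the sign follows the right-hand rule looking from
    p2 to p3.  Computed with the atan2 formulation, which is stable near
    +-180.  Collinear p1-p2-p3 or p2-p3-p4 is a hard error (the torsion is
    undefined there).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.linalg.norm(b1) == 0 or np.linalg.norm(b2) == 0 or np.linalg.norm(b3) == 0:
        raise ValueError("torsion: consecutive points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 * np.linalg.norm(b1) * b2n:
        raise ValueError("torsion: p1, p2, p3 are collinear")
    if np.linalg.norm(n2) < 1e-10 * np.linalg.norm(b3) * b2n:
        raise ValueError("torsion: p2, p3, p4 are collinear")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / b2n)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> +180 so the range is (-180, 180]
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def angle(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Bond angle p1-p2-p3 in degrees."""
    v1 = np.asarray(p1, float) - np.asarray(p2, float)
    v2 = np.asarray(p3, float) - np.asarray(p2, float)
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, theta: float, chi: float) -> np.ndarray:
    """Place atom D given references C (bonded), B, A (NeRF construction).

    D is at distance ``bond`` (Å) from ``c``, with angle B-C-D = ``theta``
    (degrees) and torsion A-B-C-D = ``chi`` (degrees).  The construction is
    exact: measuring the torsion back returns ``chi`` up to roundoff.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    th = np.radians(theta)
    ph = np.radians(chi)
    # local displacement in the frame where bc is +x
    d_local = np.array([
        -bond * np.cos(th),
        bond * np.sin(th) * np.cos(ph),
        bond * np.sin(th) * np.sin(ph),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-10:
        raise ValueError("place_atom: reference atoms A, B, C are collinear")
    n /= n_norm
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about an arbitrary axis (Rodrigues), angle in degrees."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    th = np.radians(angle_deg)
    kx, ky, kz = axis
    k_cross = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + np.sin(th) * k_cross + (1 - np.cos(th)) * (k_cross @ k_cross)
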
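"""Independent naive reimplementations used as oracles.

Everything here is deliberately written with a different formulation from
the package (quaternion superposition instead of SVD, explicit Python
loops instead of vectorized linear algebra) so agreement is evidence, not
tautology.
"""

from __future__ import annotations

import math

import numpy as np


def quaternion_rmsd(mobile: np.ndarray, ref: np.ndarray) -> float:
    """Best-fit RMSD via Horn's quaternion method (largest eigenvalue of
    the 4x4 key matrix); no rotation matrix is ever formed."""
    x = np.asarray(mobile, float)
    y = np.asarray(ref, float)
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    s = xc.T @ yc
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(key)[-1]
    e0 = (xc ** 2).sum() + (yc ** 2).sum()
    val = max(0.0, (e0 - 2.0 * lam) / n)
    return math.sqrt(val)


def quaternion_rotation(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Optimal proper rotation from the dominant quaternion."""
    x = np.asarray(mobile, float)
    y = np.asarray(ref, float)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    s = xc.T @ yc
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    _, vecs = np.linalg.eigh(key)
    q0, q1, q2, q3 = vecs[:, -1]
    return np.array([
        [q0*q0 + q1*q1 - q2*q2 - q3*q3, 2*(q1*q2 - q0*q3), 2*(q1*q3 + q0*q2)],
        [2*(q1*q2 + q0*q3), q0*q0 - q1*q1 + q2*q2 - q3*q3, 2*(q2*q3 - q0*q1)],
        [2*(q1*q3 - q0*q2), 2*(q2*q3 + q0*q1), q0*q0 - q1*q1 - q2*q2 + q3*q3],
    ])


def naive_rg(coords, masses) -> float:
    total = 0.0
    msum = 0.0
    cx = cy = cz = 0.0
    for (x, y, z), m in zip(coords, masses):
        cx += m * x
        cy += m * y
        cz += m * z
        msum += m
    cx, cy, cz = cx / msum, cy / msum, cz / msum
    for (x, y, z), m in zip(coords, masses):
        total += m * ((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
    return math.sqrt(total / msum)


def naive_dihedral(p1, p2, p3, p4) -> float:
    """Torsion through explicit plane normals and a sign from the triple
    product (different route from the package's atan2 form)."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    if ang <= -180.0:
        ang += 360.0
    return ang


def naive_rmsd_series(frames, ref_coords, fit_idx, calc_idx):
    """Per-frame fit-then-measure RMSD using the quaternion rotation."""
    out = []
    for frame in frames:
        rot = quaternion_rotation(frame[fit_idx], ref_coords[fit_idx])
        mob_center = frame[fit_idx].mean(axis=0)
        ref_center = ref_coords[fit_idx].mean(axis=0)
        moved = (frame[calc_idx] - mob_center) @ rot.T + ref_center
        sq = 0.0
        for a, b in zip(moved, ref_coords[calc_idx]):
            sq += ((a - b) ** 2).sum()
        out.append(math.sqrt(sq / len(calc_idx)))
    return np.array(out)


def brute_force_clashes(coords, elements, new_indices, threshold, excluded):
    """O(N^2) loop over all pairs; heavy atoms only."""
    pairs = []
    n = len(coords)
    newset = set(new_indices)
    for i in range(n):
        for j in range(i + 1, n):
            if elements[i] == "H" or elements[j] == "H":
                continue
            if i not in newset and j not in newset:
                continue
            if frozenset((i, j)) in excluded:
                continue
            d = math.dist(coords[i], coords[j])
            if d < threshold:
                pairs.append((i, j, round(d, 3)))
    return pairs


def brute_force_coverage(atoms, bonds, types, params):
    """Path enumeration + naive tuple lookup (both orientations tried
    explicitly) for the parameter-coverage oracle."""
    adj = {a: set() for a in atoms}
    for a, b in bonds:
        adj[a].add(b)
        adj[b].add(a)
    missing = set()
    for a, b in bonds:
        tt = (types[a], types[b])
        if tt not in params["bond"] and tt[::-1] not in params["bond"]:
            missing.add(("bond",) + min(tt, tt[::-1]))
    for b in atoms:
        nbs = sorted(adj[b])
        for i in range(len(nbs)):
            for j in range(i + 1, len(nbs)):
                tt = (types[nbs[i]], types[b], types[nbs[j]])
                if tt not in params["angle"] and tt[::-1] not in params["angle"]:
                    missing.add(("angle",) + min(tt, tt[::-1]))
    for a in atoms:
        for b in adj[a]:
            for c in adj[b]:
                if c == a:
                    continue
                for d in adj[c]:
                    if d in (b, a):
                        continue
                    tt = (types[a], types[b], types[c], types[d])
                    wild = ("X", types[b], types[c], "X")
                    hits = (tt in params["dihedral"] or tt[::-1] in params["dihedral"]
                            or wild in params["dihedral"] or wild[::-1] in params["dihedral"])
                    if not hits:
                        missing.add(("dihedral",) + min(tt, tt[::-1]))
    return missing
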
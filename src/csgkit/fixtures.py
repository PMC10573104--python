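"""Deterministic synthetic fixtures: toy peptides, perturbation
trajectories, and point-charge ESP grids.

These generators emulate the statistical structure of the inputs the
toolkit consumes — not force-field physics.  A wobble trajectory replaces
MD thermal noise with i.i.d. Gaussian coordinate noise (expected unfitted
RMSD = sigma * sqrt(3)); a two-state trajectory plants a known
conformational mixture for clustering oracles; ESP grids are generated
exactly from known point charges on Merz-Singh-Kollman style shells so a
restraint-free RESP fit must recover the generating charges.

Every generator is a pure function of its arguments: the same seed gives
bit-identical output.
"""

from __future__ import annotations

import math

import numpy as np

from ._elements import element_from_name, mass_of, vdw_radius_of
from ._geom import place_atom
from .charges import BOHR_PER_ANGSTROM, ChargeSet, ESPGrid, ResidueTemplate
from .grafting import GraftSpec, graft_glutathione, load_csg_template
from .structure import Atom, Residue, Structure, Trajectory

#: Ideal backbone internals (Å, degrees): bond, angle values from standard
#: peptide geometry; the default conformation is an open beta-like strand.
_PHI, _PSI, _OMEGA = -135.0, 135.0, 180.0


def make_toy_peptide(sequence: str, include_csg_at: int | None = None,
                     chain: str = "A",
                     tmpl: ResidueTemplate | None = None,
                     chi_ss: float = 90.0) -> Structure:
    """Build an extended-chain peptide from A/G/C residues.

    Residues are chemically complete (backbone with amide H, side-chain
    hydrogens, C-terminal OXT); geometry comes from ideal internal
    coordinates in a beta-strand conformation, so the chain is open and
    clash-free.  ``include_csg_at`` (1-based resid) grafts glutathione
    onto a cysteine at that position through the standard grafting path.
    """
    sequence = sequence.upper()
    bad = sorted(set(sequence) - set("AGC"))
    if bad:
        raise ValueError(f"unsupported residue letters {bad}; only A, G, C")
    if not sequence:
        raise ValueError("empty sequence")
    if include_csg_at is not None:
        if not (1 <= include_csg_at <= len(sequence)):
            raise ValueError("include_csg_at out of range")
        if sequence[include_csg_at - 1] != "C":
            raise ValueError("CSG position must hold a cysteine (C)")

    residues: list[Residue] = []
    # seed the first backbone triplet in the xy-plane
    n_pos = np.array([0.0, 0.0, 0.0])
    ca_pos = np.array([1.458, 0.0, 0.0])
    ang = math.radians(180.0 - 111.1)
    c_pos = ca_pos + 1.525 * np.array([math.cos(ang), math.sin(ang), 0.0])
    prev = None  # (N, CA, C) of previous residue
    for i, letter in enumerate(sequence, start=1):
        if prev is not None:
            n_pos = place_atom(prev["N"], prev["CA"], prev["C"], 1.329, 116.6, _PSI)
            ca_pos = place_atom(prev["CA"], prev["C"], n_pos, 1.458, 121.9, _OMEGA)
            c_pos = place_atom(prev["C"], n_pos, ca_pos, 1.525, 111.1, _PHI)
        resname = {"A": "ALA", "G": "GLY", "C": "CYS"}[letter]
        atoms = _residue_atoms(letter, n_pos, ca_pos, c_pos,
                               prev_c=None if prev is None else prev["C"],
                               is_last=(i == len(sequence)))
        residues.append(Residue(resname, i, chain, atoms))
        prev = {"N": n_pos, "CA": ca_pos, "C": c_pos}
    # carbonyl O for residues 1..n-1: anti to the following amide N
    for i in range(len(residues) - 1):
        res = residues[i]
        nxt = residues[i + 1]
        o = place_atom(nxt.atoms[0].position, res.atom("CA").position,
                       res.atom("C").position, 1.231, 122.9, 180.0)
        res.atoms.insert(3, Atom("O", "O", mass_of("O"), o))
    s = Structure(residues, title=f"toy peptide {sequence}")
    if include_csg_at is not None:
        s = graft_glutathione(
            s, GraftSpec(chain, include_csg_at, chi_ss=chi_ss), tmpl=tmpl)
    return s


def _residue_atoms(letter: str, n: np.ndarray, ca: np.ndarray, c: np.ndarray,
                   prev_c: np.ndarray | None, is_last: bool) -> list[Atom]:
    def mk(name: str, pos: np.ndarray) -> Atom:
        elem = element_from_name(name)
        return Atom(name, elem, mass_of(elem), pos)

    atoms = [mk("N", n), mk("CA", ca), mk("C", c)]
    if is_last:
        o = place_atom(n, ca, c, 1.231, 120.5, -45.0)
        oxt = place_atom(n, ca, c, 1.231, 120.5, 135.0)
        atoms.append(mk("O", o))
        atoms.append(mk("OXT", oxt))
    # amide hydrogen: trans to the preceding carbonyl carbon (or to C for
    # the first residue, which keeps it out of the chain)
    if prev_c is not None:
        h = place_atom(prev_c, ca, n, 1.010, 119.0, 180.0)
    else:
        h = place_atom(c, ca, n, 1.010, 119.0, 180.0)
    atoms.append(mk("H", h))
    # CB placed for L-chirality: torsion(C, N, CA, CB) = -122.5
    if letter in ("A", "C"):
        cb = place_atom(c, n, ca, 1.530, 110.5, -122.5)
        ha = place_atom(c, n, ca, 1.090, 108.5, 119.0)
        atoms.append(mk("CB", cb))
        atoms.append(mk("HA", ha))
        if letter == "A":
            for j, tor in enumerate((60.0, 180.0, -60.0), start=1):
                hb = place_atom(n, ca, cb, 1.090, 109.5, tor)
                atoms.append(mk(f"HB{j}", hb))
        else:
            sg = place_atom(n, ca, cb, 1.810, 114.0, 180.0)
            atoms.append(mk("SG", sg))
            for name, tor in (("HB2", 60.0), ("HB3", -60.0)):
                hb = place_atom(n, ca, cb, 1.090, 109.5, tor)
                atoms.append(mk(name, hb))
            hg = place_atom(ca, cb, sg, 1.340, 96.0, 180.0)
            atoms.append(mk("HG", hg))
    else:  # glycine: two HA
        ha2 = place_atom(c, n, ca, 1.090, 108.5, -122.5)
        ha3 = place_atom(c, n, ca, 1.090, 108.5, 119.0)
        atoms.append(mk("HA2", ha2))
        atoms.append(mk("HA3", ha3))
    return atoms


def make_wobble_trajectory(ref: Structure, sigma: float, n_frames: int,
                           seed: int, frame_interval: float | None = None
                           ) -> Trajectory:
    """Frames = reference coordinates + i.i.d. Gaussian(0, sigma^2) noise
    on every coordinate.  The expected unfitted all-atom RMSD per frame is
    sigma * sqrt(3); sigma = 0 reproduces the reference exactly.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    base = ref.coords
    frames = base[None, :, :] + rng.normal(0.0, sigma, size=(n_frames, *base.shape)) \
        if sigma > 0 else np.repeat(base[None, :, :], n_frames, axis=0)
    return Trajectory(ref.copy(), frames, frame_interval)


def make_two_state_trajectory(ref_a: Structure, ref_b: Structure,
                              fractions: tuple[float, float],
                              sigma: float, n_frames: int, seed: int
                              ) -> tuple[Trajectory, np.ndarray]:
    """A planted two-conformer mixture with per-frame ground-truth labels.

    Frame counts are allocated deterministically (``round(f * F)`` for the
    first state, the remainder for the second) and shuffled by the seed;
    each frame is its conformer plus Gaussian(0, sigma^2) noise.  Returns
    (trajectory, labels) with labels in {0, 1} for oracle scoring.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    ca, cb = ref_a.coords, ref_b.coords
    if ca.shape != cb.shape:
        raise ValueError("ref_a and ref_b topologies differ")
    names_a = [(r.chain, r.resid, a.name) for r in ref_a.residues for a in r.atoms]
    names_b = [(r.chain, r.resid, a.name) for r in ref_b.residues for a in r.atoms]
    if names_a != names_b:
        raise ValueError("ref_a and ref_b topologies differ")
    n_a = int(round(fractions[0] * n_frames))
    labels = np.array([0] * n_a + [1] * (n_frames - n_a))
    rng = np.random.default_rng(seed)
    labels = labels[rng.permutation(n_frames)]
    refs = np.stack([ca, cb])
    frames = refs[labels]
    if sigma > 0:
        frames = frames + rng.normal(0.0, sigma, size=frames.shape)
    return Trajectory(ref_a.copy(), frames), labels


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via QR of a Gaussian matrix."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_esp_grid(charges: ChargeSet, positions: np.ndarray,
                  shells: tuple[float, ...] = (1.4, 1.6, 1.8, 2.0),
                  density: float = 1.0, seed: int = 0) -> ESPGrid:
    """An exact point-charge ESP grid on Merz-Singh-Kollman style shells.

    For each shell scale ``s``, quasi-uniform points are laid on every
    atom's sphere of radius ``s * r_vdw`` (Bondi radii from the atom
    name's element) and points falling inside any other atom's sphere at
    the same scale are removed, leaving the union surface.  The potential
    at each point is exactly ``sum_j q_j / r_ij`` in atomic units, so a
    restraint-free RESP fit has the generating charges as its optimum.
    ``density`` is points per Å²; the point cloud is rotated by a seeded
    random rotation so grids differ between seeds but are reproducible.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    names = list(charges.charges.keys())
    if positions.shape[0] != len(names):
        raise ValueError("positions and charge set disagree")
    q = charges.as_array(names)
    radii = np.array([vdw_radius_of(element_from_name(nm)) for nm in names])
    rng = np.random.default_rng(seed)
    pts: list[np.ndarray] = []
    for s in shells:
        rot = _random_rotation(rng)
        for i in range(len(names)):
            r = s * radii[i]
            n_pts = max(8, int(round(density * 4.0 * np.pi * r * r)))
            sphere = positions[i] + r * (_fibonacci_sphere(n_pts) @ rot.T)
            d = np.linalg.norm(sphere[:, None, :] - positions[None, :, :], axis=2)
            keep = np.all(d >= s * radii[None, :] - 1e-9, axis=1)
            pts.append(sphere[keep])
    points = np.vstack(pts) * BOHR_PER_ANGSTROM
    apos = positions * BOHR_PER_ANGSTROM
    d = np.linalg.norm(points[:, None, :] - apos[None, :, :], axis=2)
    potentials = d ** -1 @ q
    return ESPGrid(apos, names, points, potentials)
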
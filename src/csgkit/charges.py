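"""Two-stage RESP charge fitting and residue-library bookkeeping.

This module turns a quantum-mechanical electrostatic potential (ESP) grid
into a force-field-ready charge set for a modified residue:

1. :func:`fit_resp` performs the restrained electrostatic potential fit —
   least-squares atomic point charges reproducing the grid potential under
   a hyperbolic restraint ``a (sqrt(q^2 + b^2) - b)`` toward zero, with a
   total-charge constraint, frozen charges, and charge equivalencing, in
   the canonical two-stage protocol (heavy atoms restrained with ``a1`` in
   stage 1; methyl/methylene carbons and their hydrogens refit with ``a2``
   and equivalencing in stage 2, everything else frozen).
2. :func:`normalize_charges` applies the model-compound bookkeeping used to
   splice the fitted fragment into a protein force field: capping-group
   charges are discarded, backbone charges are replaced by the parent
   force field's cysteine values, and the residual is spread equally over
   the side-chain atoms so the residue carries an exact integer charge.
3. :func:`check_parameter_coverage` enumerates every bonded term implied by
   the residue's bond graph and reports type tuples absent from a
   parameter set (frcmod/parm dialect).
4. :func:`write_library` / :func:`read_library` and :func:`write_mol2`
   emit the AMBER OFF (.lib) and TRIPOS mol2 artifacts.

Units: ESP geometry and potentials are atomic units (Bohr, Hartree/e);
charges are elementary charges throughout.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from ._elements import ATOMIC_NUMBERS, element_from_name

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903
ANGSTROM_PER_BOHR = 0.529177210903

#: ff14SB cysteine charges (elementary charge), used as the backbone
#: reference when normalizing the CSG fit.
FF14SB_CYS_CHARGES: dict[str, float] = {
    "N": -0.4157, "H": 0.2719, "CA": 0.0213, "HA": 0.1124,
    "CB": -0.1231, "HB2": 0.1112, "HB3": 0.1112,
    "SG": -0.3119, "HG": 0.1933, "C": 0.5973, "O": -0.5679,
}

#: The backbone subset replaced during normalization.
BACKBONE_ATOMS = ("N", "H", "CA", "HA", "C", "O")


class RespError(RuntimeError):
    """Singular or non-convergent RESP system."""


# ---------------------------------------------------------------------------
# data types

@dataclass
class ESPGrid:
    """Molecular geometry plus ESP sample points, all in atomic units."""

    atom_positions: np.ndarray  # M x 3, Bohr
    atom_names: list[str]
    points: np.ndarray          # P x 3, Bohr
    potentials: np.ndarray      # P, Hartree/e

    def __post_init__(self) -> None:
        self.atom_positions = np.asarray(self.atom_positions, dtype=float).reshape(-1, 3)
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.potentials = np.asarray(self.potentials, dtype=float).reshape(-1)
        m, p = len(self.atom_names), len(self.potentials)
        if self.atom_positions.shape[0] != m:
            raise ValueError("atom_positions and atom_names disagree")
        if self.points.shape[0] != p:
            raise ValueError("points and potentials disagree")
        if len(set(self.atom_names)) != m:
            raise ValueError("atom names must be unique")
        if p < m:
            raise ValueError("need at least as many grid points as atoms")
        d = np.linalg.norm(self.points[:, None, :] - self.atom_positions[None, :, :], axis=2)
        if d.size and d.min() <= 1.0:
            raise ValueError("grid points must lie > 1 Bohr from every nucleus")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)


@dataclass
class RespConfig:
    """RESP fit configuration.

    ``a1``/``a2`` are the stage-1/stage-2 restraint strengths (e^2 units;
    defaults 0.0005 / 0.001), ``b`` the hyperbola width (e, default 0.1).
    ``frozen`` maps atom names to fixed charges.  ``equivalence_groups``
    (0-based atom-index lists) and ``stage2_refit_set`` drive the second
    stage; with an empty refit set the fit is single-stage.
    """

    total_charge: int = 0
    a1: float = 0.0005
    a2: float = 0.001
    b: float = 0.1
    frozen: dict[str, float] = field(default_factory=dict)
    equivalence_groups: list[list[int]] = field(default_factory=list)
    stage2_refit_set: list[int] = field(default_factory=list)
    max_iter: int = 200
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("restraint strengths must be >= 0")
        if not self.b > 0:
            raise ValueError("restraint width b must be positive")
        seen: set[int] = set()
        for grp in self.equivalence_groups:
            if len(grp) < 2:
                raise ValueError("equivalence groups need >= 2 members")
            if seen & set(grp):
                raise ValueError("equivalence groups overlap")
            seen |= set(grp)


@dataclass
class ChargeSet:
    """Atom-name -> charge map (elementary charges)."""

    charges: dict[str, float]

    def total(self) -> float:
        return float(sum(self.charges.values()))

    def __getitem__(self, name: str) -> float:
        return self.charges[name]

    def __contains__(self, name: str) -> bool:
        return name in self.charges

    def as_array(self, names: list[str]) -> np.ndarray:
        return np.array([self.charges[n] for n in names], dtype=float)


@dataclass
class ResidueTemplate:
    """A force-field residue definition: atoms (name/type/charge), bonds,
    chain-link (head/tail) atoms, and internal-coordinate rows used to
    graft the non-backbone moiety onto an existing structure.

    Each z-matrix row is ``(atom, ref1, ref2, ref3, bond Å, angle °,
    torsion °)``: the atom is placed at the given internals relative to
    three previously defined atoms (NeRF construction).
    """

    name: str
    atoms: list[tuple[str, str, float]]  # (name, atype, charge)
    bonds: list[tuple[str, str]]
    head: str
    tail: str
    zmatrix: list[tuple[str, str, str, str, float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [a[0] for a in self.atoms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate atom names in template")
        nameset = set(names)
        for a, b in self.bonds:
            if a not in nameset or b not in nameset:
                raise ValueError(f"bond ({a}, {b}) references unknown atom")
        if self.head not in nameset or self.tail not in nameset:
            raise ValueError("head/tail must be template atoms")
        if self.atoms and not self._connected():
            raise ValueError("template bond graph is not connected")

    def _connected(self) -> bool:
        adj = self.adjacency()
        names = [a[0] for a in self.atoms]
        seen = {names[0]}
        stack = [names[0]]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == len(names)

    def adjacency(self) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = {a[0]: [] for a in self.atoms}
        for a, b in self.bonds:
            adj[a].append(b)
            adj[b].append(a)
        return adj

    @property
    def atom_names(self) -> list[str]:
        return [a[0] for a in self.atoms]

    def charge_of(self, name: str) -> float:
        for n, _, q in self.atoms:
            if n == name:
                return q
        raise KeyError(name)

    def atype_of(self, name: str) -> str:
        for n, t, _ in self.atoms:
            if n == name:
                return t
        raise KeyError(name)

    def total_charge(self) -> float:
        return float(sum(a[2] for a in self.atoms))


def canonical_bond(t: tuple[str, str]) -> tuple[str, str]:
    return t if t <= t[::-1] else t[::-1]


def canonical_angle(t: tuple[str, str, str]) -> tuple[str, str, str]:
    return t if (t[0], t[2]) <= (t[2], t[0]) else (t[2], t[1], t[0])


def canonical_dihedral(t: tuple[str, str, str, str]) -> tuple[str, str, str, str]:
    fwd, rev = t, t[::-1]
    return fwd if fwd <= rev else rev


@dataclass
class ParameterSet:
    """Bond/angle/dihedral/improper/nonbonded tables keyed by canonical
    atom-type tuples (AMBER frcmod/parm dialect).  Values are the raw
    parameter rows; coverage checking only consults the keys."""

    bond: dict[tuple, list] = field(default_factory=dict)
    angle: dict[tuple, list] = field(default_factory=dict)
    dihedral: dict[tuple, list] = field(default_factory=dict)
    improper: dict[tuple, list] = field(default_factory=dict)
    nonbonded: dict[str, list] = field(default_factory=dict)

    def add_bond(self, t1, t2, params=None):
        self.bond[canonical_bond((t1, t2))] = params or []

    def add_angle(self, t1, t2, t3, params=None):
        self.angle[canonical_angle((t1, t2, t3))] = params or []

    def add_dihedral(self, t1, t2, t3, t4, params=None):
        self.dihedral[canonical_dihedral((t1, t2, t3, t4))] = params or []

    def has_bond(self, t1, t2) -> bool:
        return canonical_bond((t1, t2)) in self.bond

    def has_angle(self, t1, t2, t3) -> bool:
        return canonical_angle((t1, t2, t3)) in self.angle

    def has_dihedral(self, t1, t2, t3, t4) -> bool:
        """Exact canonical match first, then the wildcard X-t2-t3-X form."""
        if canonical_dihedral((t1, t2, t3, t4)) in self.dihedral:
            return True
        return canonical_dihedral(("X", t2, t3, "X")) in self.dihedral


# ---------------------------------------------------------------------------
# RESP

def _is_hydrogen(name: str) -> bool:
    return element_from_name(name) == "H"


def _solve_stage(dist: np.ndarray, potentials: np.ndarray, names: list[str],
                 free: list[int], groups: list[list[int]],
                 fixed_q: np.ndarray, a: float, b: float,
                 restrained: set[int], total_charge: float,
                 max_iter: int, tol: float) -> np.ndarray:
    """One RESP stage: iterated linear solves with the hyperbolic restraint
    re-linearized each pass.  ``groups`` partitions ``free`` (equivalenced
    atoms share one unknown).  Returns the full charge vector."""
    m = len(names)
    inv_r = 1.0 / dist  # P x M
    fixed_idx = [j for j in range(m) if j not in free]
    v_eff = potentials - inv_r[:, fixed_idx] @ fixed_q[fixed_idx] if fixed_idx \
        else potentials.copy()
    q_target = total_charge - fixed_q[fixed_idx].sum() if fixed_idx else total_charge

    x_red = np.stack([inv_r[:, g].sum(axis=1) for g in groups], axis=1)
    a0 = x_red.T @ x_red
    b0 = x_red.T @ v_eff
    sizes = np.array([len(g) for g in groups], dtype=float)
    n_restr = np.array([sum(1 for j in g if j in restrained) for g in groups], dtype=float)

    ng = len(groups)
    q = np.zeros(ng)
    for _ in range(max_iter):
        penal = a * n_restr / np.sqrt(q ** 2 + b ** 2)
        lhs = np.zeros((ng + 1, ng + 1))
        lhs[:ng, :ng] = a0 + np.diag(penal)
        lhs[:ng, ng] = sizes
        lhs[ng, :ng] = sizes
        rhs = np.concatenate([b0, [q_target]])
        try:
            sol = np.linalg.solve(lhs, rhs)
        except np.linalg.LinAlgError as exc:
            raise RespError(f"singular constrained RESP system: {exc}") from None
        if not np.all(np.isfinite(sol)):
            raise RespError("singular constrained RESP system: non-finite solution")
        q_new = sol[:ng]
        delta = float(np.max(np.abs(q_new - q)))
        q = q_new
        if delta < tol:
            break
    else:
        raise RespError(
            f"RESP did not converge in {max_iter} iterations (last |dq|max = {delta:.3e})")

    out = fixed_q.copy()
    for g, qg in zip(groups, q):
        for j in g:
            out[j] = qg
    return out


def fit_resp(grid: ESPGrid, cfg: RespConfig) -> ChargeSet:
    """Two-stage RESP fit of atomic charges to an ESP grid.

    Minimizes ``sum_i (V_i - sum_j q_j / r_ij)^2 +
    sum_j a (sqrt(q_j^2 + b^2) - b)`` subject to the total-charge
    constraint, frozen charges and within-group equality.  Stage 1
    restrains every non-hydrogen atom with ``a1`` and fits all free atoms
    independently; stage 2 (run only when ``stage2_refit_set`` is
    non-empty) refits that set with ``a2`` and the equivalence groups,
    holding everything else at its stage-1 value.  Hydrogens are never
    restrained.
    """
    names = grid.atom_names
    m = grid.n_atoms
    for nm in cfg.frozen:
        if nm not in names:
            raise ValueError(f"frozen atom {nm!r} not in grid")
    frozen_idx = {names.index(nm): q for nm, q in cfg.frozen.items()}
    in_group = {j for grp in cfg.equivalence_groups for j in grp}
    for j in frozen_idx:
        for grp in cfg.equivalence_groups:
            if j in grp and any(k not in frozen_idx for k in grp):
                raise ValueError(
                    f"frozen atom {names[j]!r} shares an equivalence group with free atoms")
    del in_group

    dist = np.linalg.norm(grid.points[:, None, :] - grid.atom_positions[None, :, :], axis=2)

    fixed_q = np.zeros(m)
    for j, qv in frozen_idx.items():
        fixed_q[j] = qv

    # stage 1: all non-frozen atoms free, no equivalencing, heavy atoms restrained
    free1 = [j for j in range(m) if j not in frozen_idx]
    if not free1:
        raise ValueError("all atoms frozen; nothing to fit")
    groups1 = [[j] for j in free1]
    restrained1 = {j for j in free1 if not _is_hydrogen(names[j])}
    q1 = _solve_stage(dist, grid.potentials, names, free1, groups1, fixed_q,
                      cfg.a1, cfg.b, restrained1, float(cfg.total_charge),
                      cfg.max_iter, cfg.tol)

    if not cfg.stage2_refit_set:
        return ChargeSet({nm: float(q) for nm, q in zip(names, q1)})

    # stage 2: refit set free (equivalenced), everything else frozen at stage-1
    refit = sorted(set(cfg.stage2_refit_set))
    for j in refit:
        if j in frozen_idx:
            raise ValueError(f"stage-2 refit atom {names[j]!r} is frozen")
    refit_set = set(refit)
    groups2: list[list[int]] = []
    covered: set[int] = set()
    for grp in cfg.equivalence_groups:
        members = [j for j in grp if j in refit_set]
        if members:
            if len(members) != len(grp):
                raise ValueError("equivalence group straddles the stage-2 refit set")
            groups2.append(sorted(members))
            covered |= set(members)
    for j in refit:
        if j not in covered:
            groups2.append([j])
    fixed2 = q1.copy()
    restrained2 = {j for j in refit if not _is_hydrogen(names[j])}
    q2 = _solve_stage(dist, grid.potentials, names, refit, groups2, fixed2,
                      cfg.a2, cfg.b, restrained2, float(cfg.total_charge),
                      cfg.max_iter, cfg.tol)
    return ChargeSet({nm: float(q) for nm, q in zip(names, q2)})


# ---------------------------------------------------------------------------
# normalization

def normalize_charges(raw: ChargeSet, backbone_ref: ChargeSet,
                      cap_atoms: list[str], sidechain_atoms: list[str],
                      total_charge: int) -> ChargeSet:
    """Splice a model-compound RESP fit into a protein residue charge set.

    Capping-group atoms are dropped (their charge is discarded, not
    redistributed); atoms covered by ``backbone_ref`` take the reference
    (parent force field) values exactly; each side-chain atom takes its raw
    value plus a uniform correction
    ``delta = (total_charge - sum(backbone) - sum(raw side chain)) / n_side``
    so the residue total is exactly the integer target.
    """
    caps = set(cap_atoms)
    side = list(sidechain_atoms)
    if not side:
        raise ValueError("sidechain_atoms must be non-empty")
    if caps & set(side):
        both = sorted(caps & set(side))
        raise ValueError(f"atoms in two categories (cap and side chain): {both}")
    backbone = [nm for nm in raw.charges if nm not in caps and nm not in side]
    for nm in backbone:
        if nm not in backbone_ref:
            raise ValueError(f"backbone atom {nm!r} missing from the reference charge set")
    missing = [nm for nm in side if nm not in raw.charges]
    if missing:
        raise ValueError(f"side-chain atoms missing from raw charges: {missing}")
    bb_sum = sum(backbone_ref[nm] for nm in backbone)
    raw_side_sum = sum(raw[nm] for nm in side)
    delta = (total_charge - bb_sum - raw_side_sum) / len(side)
    out: dict[str, float] = {}
    for nm in raw.charges:
        if nm in caps:
            continue
        out[nm] = backbone_ref[nm] if nm in backbone else raw[nm] + delta
    result = ChargeSet(out)
    # exactness guard: spread any last-ulp residue over the side chain
    resid = total_charge - result.total()
    if abs(resid) > 1e-9:
        for nm in side:
            out[nm] += resid / len(side)
        result = ChargeSet(out)
    return result


# ---------------------------------------------------------------------------
# parameter coverage

def _enumerate_terms(tmpl: ResidueTemplate):
    adj = tmpl.adjacency()
    names = tmpl.atom_names
    order = {nm: i for i, nm in enumerate(names)}
    bonds = []
    for a, b in tmpl.bonds:
        bonds.append((a, b) if order[a] < order[b] else (b, a))
    angles = set()
    for b in names:
        nbs = adj[b]
        for i in range(len(nbs)):
            for j in range(i + 1, len(nbs)):
                a, c = nbs[i], nbs[j]
                angles.add((a, b, c) if order[a] < order[c] else (c, b, a))
    dihedrals = set()
    for b, c in bonds:
        for a in adj[b]:
            if a == c:
                continue
            for d in adj[c]:
                if d == b or d == a:
                    continue
                key = (a, b, c, d)
                if (order[d], order[c]) < (order[a], order[b]):
                    key = (d, c, b, a)
                dihedrals.add(key)
    return bonds, sorted(angles, key=lambda t: [order[x] for x in t]), \
        sorted(dihedrals, key=lambda t: [order[x] for x in t])


def check_parameter_coverage(tmpl: ResidueTemplate, params: ParameterSet) -> list[tuple]:
    """Enumerate every bond, angle and proper torsion implied by the
    template's bond graph and return the type tuples absent from
    ``params``.  Torsions match exactly first, then through the X-B-C-X
    wildcard.  An empty list means full coverage.
    """
    for nm, atype, _ in tmpl.atoms:
        if not atype:
            raise ValueError(f"atom {nm!r} has no atom type")
    ty = {nm: tmpl.atype_of(nm) for nm in tmpl.atom_names}
    missing: list[tuple] = []
    seen: set[tuple] = set()
    bonds, angles, dihedrals = _enumerate_terms(tmpl)
    for a, b in bonds:
        if not params.has_bond(ty[a], ty[b]):
            key = ("bond",) + canonical_bond((ty[a], ty[b]))
            if key not in seen:
                seen.add(key)
                missing.append(key)
    for a, b, c in angles:
        if not params.has_angle(ty[a], ty[b], ty[c]):
            key = ("angle",) + canonical_angle((ty[a], ty[b], ty[c]))
            if key not in seen:
                seen.add(key)
                missing.append(key)
    for a, b, c, d in dihedrals:
        if not params.has_dihedral(ty[a], ty[b], ty[c], ty[d]):
            key = ("dihedral",) + canonical_dihedral((ty[a], ty[b], ty[c], ty[d]))
            if key not in seen:
                seen.add(key)
                missing.append(key)
    return missing


# ---------------------------------------------------------------------------
# file formats

def read_frcmod(path) -> ParameterSet:
    """Parse the AMBER frcmod/parm dialect (MASS/BOND/ANGLE/DIHE/IMPROPER/
    NONBON sections; hyphen-separated type fields)."""
    params = ParameterSet()
    section = None
    headers = {"MASS", "BOND", "ANGL", "DIHE", "IMPR", "NONB", "HBON"}
    with open(path) as fh:
        for raw_line in fh:
            line = raw_line.rstrip("\n")
            stripped = line.strip()
            if not stripped:
                section = None
                continue
            head = stripped[:4].upper()
            if head in headers and len(stripped.split()) <= 2:
                section = head
                continue
            if section is None:
                continue
            if section in ("BOND", "ANGL", "DIHE", "IMPR"):
                mtc = re.match(r"^([A-Za-z0-9\*\+ ]{1,2}(?:-[A-Za-z0-9\*\+ ]{1,2}){1,3})",
                               line)
                if not mtc:
                    continue
                types = tuple(t.strip() for t in mtc.group(1).split("-"))
                rest = line[mtc.end():].split()
                if section == "BOND" and len(types) == 2:
                    params.add_bond(*types, params=rest)
                elif section == "ANGL" and len(types) == 3:
                    params.add_angle(*types, params=rest)
                elif section == "DIHE" and len(types) == 4:
                    params.add_dihedral(*types, params=rest)
                elif section == "IMPR" and len(types) == 4:
                    params.improper[types] = rest
            elif section == "NONB":
                parts = stripped.split()
                if parts:
                    params.nonbonded[parts[0]] = parts[1:]
    return params


def read_charge_csv(path) -> ChargeSet:
    """Read an ``atom,charge`` CSV table (header optional)."""
    charges: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, _, value = line.partition(",")
            name = name.strip()
            value = value.strip()
            if name.lower() in ("atom", "name") or not value:
                continue
            charges[name] = float(value)
    if not charges:
        raise ValueError(f"{path}: no charges found")
    return ChargeSet(charges)


def write_esp(grid: ESPGrid, path) -> None:
    """Write the whitespace ESP-grid dialect: a count line ``M P``, then M
    nucleus lines ``name x y z`` and P sample lines ``V x y z`` (Bohr,
    Hartree/e)."""
    with open(path, "w") as fh:
        fh.write(f"{grid.n_atoms:6d}{len(grid.potentials):8d}\n")
        for nm, pos in zip(grid.atom_names, grid.atom_positions):
            fh.write(f"{nm:<6s}{pos[0]:16.7E}{pos[1]:16.7E}{pos[2]:16.7E}\n")
        for v, pt in zip(grid.potentials, grid.points):
            fh.write(f"{v:16.7E}{pt[0]:16.7E}{pt[1]:16.7E}{pt[2]:16.7E}\n")


def read_esp(path) -> ESPGrid:
    with open(path) as fh:
        counts = fh.readline().split()
        m, p = int(counts[0]), int(counts[1])
        names, apos = [], []
        for _ in range(m):
            parts = fh.readline().split()
            names.append(parts[0])
            apos.append([float(x) for x in parts[1:4]])
        pts, pots = [], []
        for _ in range(p):
            parts = fh.readline().split()
            pots.append(float(parts[0]))
            pts.append([float(x) for x in parts[1:4]])
    return ESPGrid(np.array(apos), names, np.array(pts), np.array(pots))


def write_library(tmpl: ResidueTemplate, path,
                  coordinates: dict[str, np.ndarray] | None = None) -> None:
    """Write an AMBER OFF (.lib) residue entry.

    Emits the atoms table (name, type, charge, element), the connectivity
    table, the connect array and residueconnect entries naming the head
    and tail atoms, and positions (zeros when no coordinates are given).
    A residue whose charge sum is not an integer (to 1e-6) is refused —
    force-field residues carry integer total charge.
    """
    total = tmpl.total_charge()
    if abs(total - round(total)) > 1e-6:
        raise ValueError(
            f"template charge sum {total:.8f} is not an integer; refusing to write")
    idx = {nm: i + 1 for i, nm in enumerate(tmpl.atom_names)}
    res = tmpl.name
    lines: list[str] = []
    lines.append("!!index array str")
    lines.append(f' "{res}"')
    lines.append(f"!entry.{res}.unit.atoms table  str name  str type  int typex  "
                 "int resx  int flags  int seq  int elmnt  dbl chg")
    for i, (nm, atype, q) in enumerate(tmpl.atoms, start=1):
        elem = element_from_name(nm)
        z = ATOMIC_NUMBERS.get(elem.upper(), 0)
        lines.append(f' "{nm}" "{atype}" 0 1 131072 {i} {z} {q:.6f}')
    lines.append(f"!entry.{res}.unit.atomspertinfo table  str pname  str ptype  "
                 "int ptypex  int pelmnt  dbl pchg")
    for nm, atype, _ in tmpl.atoms:
        lines.append(f' "{nm}" "{atype}" 0 -1 0.0')
    lines.append(f"!entry.{res}.unit.boundbox array dbl")
    for _ in range(5):
        lines.append(" -1.000000")
    lines.append(f"!entry.{res}.unit.childsequence single int")
    lines.append(" 2")
    lines.append(f"!entry.{res}.unit.connect array int")
    lines.append(f" {idx[tmpl.head]}")
    lines.append(f" {idx[tmpl.tail]}")
    lines.append(f"!entry.{res}.unit.connectivity table  int atom1x  int atom2x  int flags")
    for a, b in tmpl.bonds:
        i, j = idx[a], idx[b]
        if i > j:
            i, j = j, i
        lines.append(f" {i} {j} 1")
    lines.append(f"!entry.{res}.unit.name single str")
    lines.append(f' "{res}"')
    lines.append(f"!entry.{res}.unit.positions table  dbl x  dbl y  dbl z")
    for nm in tmpl.atom_names:
        xyz = (coordinates or {}).get(nm, np.zeros(3))
        lines.append(f" {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}")
    lines.append(f"!entry.{res}.unit.residueconnect table  int c1x  int c2x  "
                 "int c3x  int c4x  int c5x  int c6x")
    lines.append(f" {idx[tmpl.head]} {idx[tmpl.tail]} 0 0 0 0")
    lines.append(f"!entry.{res}.unit.residues table  str name  int seq  int childseq  "
                 "int startatomx  str restype  int imagingx")
    lines.append(f' "{res}" 1 {len(tmpl.atoms) + 1} 1 "p" 0')
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_library(path) -> ResidueTemplate:
    """Read a (single-residue) AMBER OFF library written by
    :func:`write_library` or tleap: atoms, connectivity, head/tail."""
    atoms: list[tuple[str, str, float]] = []
    bonds: list[tuple[str, str]] = []
    connect: list[int] = []
    resconnect: list[int] = []
    name = None
    section = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!entry."):
                part = line.split(".", 2)[2].split()[0]
                section = part
                if name is None:
                    name = line.split(".")[1]
                continue
            if line.startswith("!!"):
                section = None
                continue
            body = line.strip()
            if not body or section is None:
                continue
            if section == "unit.atoms":
                parts = body.split()
                atoms.append((parts[0].strip('"'), parts[1].strip('"'), float(parts[7])))
            elif section == "unit.connectivity":
                parts = body.split()
                bonds.append((int(parts[0]), int(parts[1])))
            elif section == "unit.connect":
                connect.append(int(body))
            elif section == "unit.residueconnect":
                resconnect = [int(x) for x in body.split()]
    if not atoms:
        raise ValueError(f"{path}: no atoms table found")
    names = [a[0] for a in atoms]
    named_bonds = [(names[i - 1], names[j - 1]) for i, j in bonds]
    if resconnect:
        head = names[resconnect[0] - 1]
        tail = names[resconnect[1] - 1]
    elif len(connect) >= 2:
        head = names[connect[0] - 1]
        tail = names[connect[1] - 1]
    else:
        head = tail = names[0]
    return ResidueTemplate(name or "RES", atoms, named_bonds, head, tail)


_MOL2_SYBYL = {"H": "H", "C": "C.3", "N": "N.3", "O": "O.3", "S": "S.3", "P": "P.3"}


def write_mol2(tmpl: ResidueTemplate, coordinates: dict[str, np.ndarray], path) -> None:
    """Write a TRIPOS mol2 file for the residue with template charges.

    Charges are written at 1e-4 precision in the @<TRIPOS>ATOM block;
    bonds come from the template bond list (all single order — bond orders
    are not force-field information here).
    """
    missing = [nm for nm in tmpl.atom_names if nm not in coordinates]
    if missing:
        raise ValueError(f"no coordinates for atoms: {missing}")
    idx = {nm: i + 1 for i, nm in enumerate(tmpl.atom_names)}
    with open(path, "w") as fh:
        fh.write("@<TRIPOS>MOLECULE\n")
        fh.write(f"{tmpl.name}\n")
        fh.write(f"{len(tmpl.atoms):5d}{len(tmpl.bonds):6d}{1:6d}{0:6d}{0:6d}\n")
        fh.write("SMALL\nUSER_CHARGES\n")
        fh.write("@<TRIPOS>ATOM\n")
        for i, (nm, atype, q) in enumerate(tmpl.atoms, start=1):
            xyz = coordinates[nm]
            elem = element_from_name(nm)
            sybyl = _MOL2_SYBYL.get(elem.upper(), elem)
            fh.write(f"{i:7d} {nm:<8s}{xyz[0]:10.4f}{xyz[1]:10.4f}{xyz[2]:10.4f} "
                     f"{sybyl:<8s}{1:4d} {tmpl.name:<8s}{q:10.4f}\n")
        fh.write("@<TRIPOS>BOND\n")
        for k, (a, b) in enumerate(tmpl.bonds, start=1):
            fh.write(f"{k:6d}{idx[a]:6d}{idx[b]:6d} 1\n")


def read_mol2_charges(path) -> ChargeSet:
    """Charges from a TRIPOS mol2 @<TRIPOS>ATOM block."""
    charges: dict[str, float] = {}
    in_atoms = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("@<TRIPOS>"):
                in_atoms = line.strip() == "@<TRIPOS>ATOM"
                continue
            if in_atoms and line.strip():
                parts = line.split()
                charges[parts[1]] = float(parts[8])
    if not charges:
        raise ValueError(f"{path}: no ATOM block")
    return ChargeSet(charges)


def symmetry_equivalent_hydrogens(tmpl: ResidueTemplate, depth: int = 2) -> list[list[int]]:
    """Detect symmetry-equivalent hydrogens: H atoms bonded to the same
    heavy atom whose bonded-neighbor type environments agree to ``depth``
    shells.  Returns 0-based index groups, the default RESP equivalencing.
    """
    adj = tmpl.adjacency()
    names = tmpl.atom_names
    order = {nm: i for i, nm in enumerate(names)}

    def env(nm: str, d: int) -> tuple:
        if d == 0:
            return (tmpl.atype_of(nm),)
        return (tmpl.atype_of(nm),
                tuple(sorted(env(nb, d - 1) for nb in adj[nm])))

    groups: list[list[int]] = []
    by_parent: dict[str, list[str]] = {}
    for nm in names:
        if element_from_name(nm) == "H":
            parents = adj[nm]
            if parents:
                by_parent.setdefault(parents[0], []).append(nm)
    for parent, hs in by_parent.items():
        if len(hs) < 2:
            continue
        sig: dict[tuple, list[str]] = {}
        for h in hs:
            sig.setdefault(env(h, depth), []).append(h)
        for members in sig.values():
            if len(members) >= 2:
                groups.append(sorted(order[h] for h in members))
    return groups


def default_stage2_refit(tmpl: ResidueTemplate) -> tuple[list[int], list[list[int]]]:
    """Canonical stage-2 refit set: hydrogens on sp3 carbons that bear two
    or more equivalent hydrogens, plus those carbons.  Returns
    (refit indices, equivalence groups), both 0-based."""
    groups = symmetry_equivalent_hydrogens(tmpl)
    adj = tmpl.adjacency()
    names = tmpl.atom_names
    order = {nm: i for i, nm in enumerate(names)}
    refit: set[int] = set()
    kept_groups: list[list[int]] = []
    for grp in groups:
        parent = adj[names[grp[0]]][0]
        if element_from_name(parent) != "C":
            continue
        # sp3: carbon with 4 bonded neighbors
        if len(adj[parent]) != 4:
            continue
        refit |= set(grp)
        refit.add(order[parent])
        kept_groups.append(grp)
    return sorted(refit), kept_groups


def charge_delta_report(raw: ChargeSet, normalized: ChargeSet,
                        sidechain_atoms: list[str]) -> float:
    """The uniform per-atom side-chain correction applied by
    :func:`normalize_charges` (e), recovered from its output."""
    deltas = [normalized[nm] - raw[nm] for nm in sidechain_atoms]
    return float(np.mean(deltas))


def is_integer_charge(total: float, tol: float = 1e-6) -> bool:
    return math.isclose(total, round(total), abs_tol=tol)
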
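"""Core structure/trajectory data model with PDB I/O and atom selections.

The model is deliberately small: a :class:`Structure` is an ordered list of
residues, each an ordered list of atoms; a :class:`Trajectory` is a fixed
topology plus an ``F x N x 3`` coordinate stack in Å.  Multi-model PDB files
map one MODEL block to one frame.  Atom indices are 0-based internally and
1-based in every user-facing output (PDB serials, reports).

Altloc handling follows common preparation practice: the highest-occupancy
alternate location is kept; ties go to the lexicographically first altloc
identifier.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from ._elements import element_from_name, mass_of

logger = logging.getLogger(__name__)

#: Residue names removed by :func:`strip_solvent_ions`.
SOLVENT_ION_RESNAMES = {"WAT", "HOH", "NA", "CL", "NA+", "CL-"}

#: Backbone atom names: N, CA, C, O plus the amide hydrogen.  HA is a
#: side-chain-facing hydrogen and is excluded on purpose so that
#: backbone-RMSD numbers match the usual trajectory-analysis masks.
BACKBONE_NAMES = {"N", "CA", "C", "O", "H"}


class PDBParseError(ValueError):
    """Unrecoverable defect in a PDB file (bad field, inconsistent models)."""


@dataclass
class Atom:
    """A single atom: PDB-style name, element, mass (amu), position (Å)."""

    name: str
    element: str
    mass: float
    position: np.ndarray
    charge: float | None = None
    atype: str | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom {self.name!r}: position must be a 3-vector")
        if not self.mass > 0:
            raise ValueError(f"atom {self.name!r}: mass must be positive, got {self.mass}")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.mass, self.position.copy(),
                    self.charge, self.atype)


@dataclass
class Residue:
    """Named residue (3-4 character code) holding an ordered atom list."""

    resname: str
    resid: int
    chain: str
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(
                f"residue {self.resname} {self.chain}:{self.resid}: duplicate atom names {dup}")

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.resname} {self.chain}:{self.resid} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def copy(self) -> "Residue":
        return Residue(self.resname, self.resid, self.chain, [a.copy() for a in self.atoms])


class Structure:
    """Ordered residues; the (chain, resid, atom-name) triple is unique."""

    def __init__(self, residues: list[Residue], title: str = "") -> None:
        self.residues = list(residues)
        self.title = title
        self._validate()

    def _validate(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for res in self.residues:
            if not res.atoms:
                raise ValueError(
                    f"residue {res.resname} {res.chain}:{res.resid} is empty")
            for a in res.atoms:
                key = (res.chain, res.resid, a.name)
                if key in seen:
                    raise ValueError(f"duplicate atom {key} in structure")
                seen.add(key)

    @property
    def atoms(self) -> list[Atom]:
        return [a for res in self.residues for a in res.atoms]

    @property
    def n_atoms(self) -> int:
        return sum(len(res.atoms) for res in self.residues)

    @property
    def coords(self) -> np.ndarray:
        """N x 3 coordinate array (Å), a copy in file order."""
        if self.n_atoms == 0:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"expected {(self.n_atoms, 3)} coordinates, got {coords.shape}")
        for atom, xyz in zip(self.atoms, coords):
            atom.position = xyz.copy()

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def residue(self, chain: str, resid: int) -> Residue:
        for res in self.residues:
            if res.chain == chain and res.resid == resid:
                return res
        raise KeyError(f"no residue {chain}:{resid} in structure")

    def atom_residue(self, index: int) -> Residue:
        """Residue owning the atom at flat index ``index``."""
        n = 0
        for res in self.residues:
            n += len(res.atoms)
            if index < n:
                return res
        raise IndexError(index)

    def copy(self) -> "Structure":
        return Structure([r.copy() for r in self.residues], self.title)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Structure {len(self.residues)} residues, {self.n_atoms} atoms>"


class Trajectory:
    """A fixed topology plus F x N x 3 coordinate frames (Å)."""

    def __init__(self, topology: Structure, frames: np.ndarray,
                 frame_interval: float | None = None) -> None:
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3 or frames.shape[0] < 1:
            raise ValueError("frames must be an F x N x 3 array with F >= 1")
        if frames.shape[1] != topology.n_atoms or frames.shape[2] != 3:
            raise ValueError(
                f"frames shape {frames.shape} inconsistent with topology of "
                f"{topology.n_atoms} atoms")
        self.topology = topology
        self.frames = frames
        self.frame_interval = frame_interval

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def frame_structure(self, i: int) -> Structure:
        """A Structure whose coordinates are frame ``i`` (bit-equal copy)."""
        s = self.topology.copy()
        s.set_coords(self.frames[i])
        return s

    @classmethod
    def from_structure(cls, s: Structure) -> "Trajectory":
        return cls(s, s.coords[None, :, :])


@dataclass(frozen=True)
class Selection:
    """An atom-selection expression.

    Grammar (whitespace separated, case-insensitive keywords)::

        expr     := term ("or" term)*
        term     := factor ("and" factor)*
        factor   := "not" factor | "(" expr ")" | primary
        primary  := "all" | "backbone" | "heavy"
                  | "resname" NAME[,NAME...]
                  | "resid"   N | N:M  (comma lists allowed)
                  | "name"    NAME[,NAME...]

    ``backbone`` selects N, CA, C, O and the amide H; ``heavy`` selects
    every non-hydrogen atom.  Resolution order is file order.
    """

    expression: str

    def resolve(self, s: Structure) -> list[int]:
        return select(s, self)


# ---------------------------------------------------------------------------
# selection parsing

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(expr: str) -> list[str]:
    return _TOKEN_RE.findall(expr)


class _SelParser:
    def __init__(self, tokens: list[str], s: Structure, expression: str) -> None:
        self.tokens = tokens
        self.pos = 0
        self.expression = expression
        # Precompute per-atom attributes once.
        self.n = s.n_atoms
        self.names: list[str] = []
        self.resnames: list[str] = []
        self.resids: list[int] = []
        self.elements: list[str] = []
        for res in s.residues:
            for a in res.atoms:
                self.names.append(a.name)
                self.resnames.append(res.resname)
                self.resids.append(res.resid)
                self.elements.append(a.element)

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ValueError(f"selection {self.expression!r}: unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise ValueError(
                f"selection {self.expression!r}: trailing token {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            raise ValueError(f"selection {self.expression!r}: unexpected end of expression")
        if tok.lower() == "not":
            self.next()
            return ~self.factor()
        if tok == "(":
            self.next()
            mask = self.expr()
            if self.peek() != ")":
                raise ValueError(f"selection {self.expression!r}: missing ')'")
            self.next()
            return mask
        return self.primary()

    def primary(self) -> np.ndarray:
        tok = self.next().lower()
        if tok == "all":
            return np.ones(self.n, dtype=bool)
        if tok == "backbone":
            return np.array([nm in BACKBONE_NAMES for nm in self.names])
        if tok == "heavy":
            return np.array([el.upper() != "H" for el in self.elements])
        if tok == "resname":
            wanted = {w.upper() for w in self.next().split(",") if w}
            return np.array([rn.upper() in wanted for rn in self.resnames])
        if tok == "name":
            wanted = {w.upper() for w in self.next().split(",") if w}
            return np.array([nm.upper() in wanted for nm in self.names])
        if tok == "resid":
            spans = self.next().split(",")
            wanted: set[int] = set()
            for span in spans:
                if ":" in span:
                    lo, hi = span.split(":")
                    wanted.update(range(int(lo), int(hi) + 1))
                else:
                    wanted.add(int(span))
            return np.array([ri in wanted for ri in self.resids])
        raise ValueError(f"selection {self.expression!r}: unknown keyword {tok!r}")


def select(s: Structure, sel: Selection | str) -> list[int]:
    """Resolve a selection on a structure to an ordered 0-based index list.

    Ordering is file order; an empty result is a hard error naming the
    expression (silently analysing zero atoms is never what was meant).
    """
    expression = sel.expression if isinstance(sel, Selection) else sel
    tokens = _tokenize(expression)
    if not tokens:
        raise ValueError("empty selection expression")
    mask = _SelParser(tokens, s, expression).parse()
    indices = [int(i) for i in np.nonzero(mask)[0]]
    if not indices:
        raise ValueError(f"selection {expression!r} matches no atoms")
    return indices


# ---------------------------------------------------------------------------
# PDB I/O

def _parse_float(text: str, what: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise PDBParseError(
            f"line {lineno}: unparseable {what} field {text.strip()!r}") from None


@dataclass
class _RawAtom:
    name: str
    altloc: str
    resname: str
    chain: str
    resid: int
    xyz: tuple[float, float, float]
    occupancy: float
    element: str


def _parse_atom_line(line: str, lineno: int) -> _RawAtom:
    line = line.rstrip("\n").ljust(80)
    name = line[12:16].strip()
    altloc = line[16].strip()
    resname = line[17:21].strip()
    chain = line[21].strip() or "A"
    try:
        resid = int(line[22:26])
    except ValueError:
        raise PDBParseError(
            f"line {lineno}: unparseable residue number {line[22:26].strip()!r}") from None
    x = _parse_float(line[30:38], "x coordinate", lineno)
    y = _parse_float(line[38:46], "y coordinate", lineno)
    z = _parse_float(line[46:54], "z coordinate", lineno)
    occ_text = line[54:60].strip()
    occ = float(occ_text) if occ_text else 1.0
    element = line[76:78].strip()
    if not element:
        element = element_from_name(name, resname)
    return _RawAtom(name, altloc, resname, chain, resid, (x, y, z), occ, element)


def _resolve_altlocs(raw: list[_RawAtom]) -> list[_RawAtom]:
    """Keep one location per (chain, resid, name): highest occupancy, then
    lexicographically first altloc identifier."""
    best: dict[tuple[str, int, str], _RawAtom] = {}
    order: list[tuple[str, int, str]] = []
    for atom in raw:
        key = (atom.chain, atom.resid, atom.name)
        if key not in best:
            best[key] = atom
            order.append(key)
        else:
            cur = best[key]
            if (atom.occupancy > cur.occupancy
                    or (atom.occupancy == cur.occupancy and atom.altloc < cur.altloc)):
                best[key] = atom
    return [best[k] for k in order]


def read_pdb(path) -> Trajectory:
    """Read a (multi-model) PDB file into a Trajectory.

    One frame per MODEL record; a file without MODEL records yields a
    single frame.  Alternate locations are resolved to the
    highest-occupancy conformer.  Elements come from columns 77-78 when
    present, otherwise from the atom name.
    """
    models: list[list[_RawAtom]] = []
    current: list[_RawAtom] = []
    in_model = False
    saw_model = False
    title = ""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "TITLE ":
                title = (title + " " + line[10:80].strip()).strip()
            elif rec == "MODEL ":
                saw_model = True
                in_model = True
                current = []
            elif rec == "ENDMDL":
                in_model = False
                models.append(current)
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                current.append(_parse_atom_line(line, lineno))
    if current or not models:
        if saw_model and current:
            # atoms after the last ENDMDL: treat as a trailing model
            models.append(current)
        elif not saw_model:
            models.append(current)
    if not models or not models[0]:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")

    models = [_resolve_altlocs(m) for m in models]
    n0 = len(models[0])
    for i, m in enumerate(models, start=1):
        if len(m) != n0:
            raise PDBParseError(
                f"model {i} has {len(m)} atoms, expected {n0} (as in model 1)")

    # Build topology from the first model.
    residues: list[Residue] = []
    key_to_res: dict[tuple[str, int, str], Residue] = {}
    for atom in models[0]:
        key = (atom.chain, atom.resid, atom.resname)
        res = key_to_res.get(key)
        if res is None or residues[-1] is not res:
            res = Residue(atom.resname, atom.resid, atom.chain, [])
            residues.append(res)
            key_to_res[key] = res
        res.atoms.append(Atom(atom.name, atom.element, mass_of(atom.element),
                              np.array(atom.xyz)))
    topology = Structure(residues, title=title)

    frames = np.empty((len(models), n0, 3), dtype=float)
    ident0 = [(a.chain, a.resid, a.name) for a in models[0]]
    for f, m in enumerate(models):
        ident = [(a.chain, a.resid, a.name) for a in m]
        if ident != ident0:
            raise PDBParseError(
                f"model {f + 1}: atom identities differ from model 1")
        frames[f] = [a.xyz for a in m]
    return Trajectory(topology, frames)


def _format_atom_name(name: str, element: str) -> str:
    """PDB column 13-16 justification: names start in column 14 unless the
    element symbol is two letters or the name is four characters."""
    if len(name) >= 4 or len(element) >= 2:
        return name.ljust(4)[:4]
    return (" " + name).ljust(4)


def _coord_field(value: float) -> str:
    text = f"{value:8.3f}"
    if len(text) != 8:
        raise ValueError(
            f"coordinate {value:.3f} Å does not fit the fixed-width PDB field")
    return text


def write_pdb(traj: Trajectory | Structure, path) -> None:
    """Write a Structure or Trajectory as a (multi-model) PDB file.

    Multi-frame trajectories emit MODEL/ENDMDL blocks.  Coordinates must be
    finite and fit the 8.3f field (|x| below 10000 and above -1000 Å).
    """
    if isinstance(traj, Structure):
        traj = Trajectory.from_structure(traj)
    if not np.all(np.isfinite(traj.frames)):
        raise ValueError("refusing to write non-finite coordinates")
    top = traj.topology
    multi = traj.n_frames > 1
    with open(path, "w") as fh:
        if top.title:
            fh.write(f"TITLE     {top.title[:70]}\n")
        for f in range(traj.n_frames):
            if multi:
                fh.write(f"MODEL     {f + 1:4d}\n")
            serial = 0
            i = 0
            prev_chain: str | None = None
            for res in top.residues:
                if prev_chain is not None and res.chain != prev_chain:
                    fh.write("TER\n")
                prev_chain = res.chain
                for a in res.atoms:
                    serial += 1
                    xyz = traj.frames[f, i]
                    i += 1
                    fh.write(
                        "ATOM  {serial:>5d} {name}{alt}{resname:<4s}{chain}{resid:>4d}{icode}   "
                        "{x}{y}{z}{occ:6.2f}{bfac:6.2f}          {elem:>2s}\n".format(
                            serial=serial % 100000,
                            name=_format_atom_name(a.name, a.element),
                            alt=" ",
                            resname=res.resname.ljust(4)[:4],
                            chain=(res.chain or "A")[:1],
                            resid=res.resid,
                            icode=" ",
                            x=_coord_field(xyz[0]),
                            y=_coord_field(xyz[1]),
                            z=_coord_field(xyz[2]),
                            occ=1.0,
                            bfac=0.0,
                            elem=a.element.upper()[:2],
                        ))
            fh.write("TER\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def strip_solvent_ions(s: Structure) -> Structure:
    """Remove crystallographic waters and monatomic counter-ions.

    Residues whose name is in :data:`SOLVENT_ION_RESNAMES` (WAT, HOH,
    Na+/NA, Cl-/CL) are dropped; everything else is untouched and keeps its
    order.  An all-solvent input yields an empty structure and a warning.
    """
    kept = [res.copy() for res in s.residues
            if res.resname.upper() not in SOLVENT_ION_RESNAMES]
    if not kept:
        logger.warning("strip_solvent_ions: structure contained only solvent/ions; "
                       "result is empty")
        out = Structure.__new__(Structure)
        out.residues = []
        out.title = s.title
        return out
    return Structure(kept, title=s.title)
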
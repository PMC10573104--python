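"""Structural descriptors for validating CSG parameters against references.

Implements the panel used to benchmark S-glutathionylated protein
ensembles: optimal (Kabsch) superposition and RMSD series, mass-weighted
radius of gyration, signed torsions with circular statistics for the S-S
dihedral, and native-interaction (hydrogen bond / cation-pi) identification
and distance monitoring.

RMSD convention: the CSG-site RMSD superposes on the protein backbone and
measures over all CSG atoms without refitting, so that side-chain
reorientations (e.g. a reversed glutathione arm) show up in the series
instead of being absorbed by a local fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geom import torsion
from .structure import Selection, Structure, Trajectory, select

AROMATIC_RING_ATOMS = {
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}

#: CSG side-chain moieties monitored for native contacts: the two amide
#: moieties formed in GSH biosynthesis (carbonyl O2 / OE1 and amide
#: protons H2 / H4), the glycine-end carboxylate (C3), and the
#: glutamate-end carboxylate (C1) and amino group (N1).
CSG_POLAR_MOIETIES: dict[str, dict] = {
    "O2": {"kind": "acceptor", "heavy": "O2"},
    "OE1": {"kind": "acceptor", "heavy": "OE1"},
    "H2": {"kind": "donor_h", "heavy": "N2"},
    "H4": {"kind": "donor_h", "heavy": "N3"},
    "C1": {"kind": "carboxylate", "oxygens": ("O11", "O12")},
    "C3": {"kind": "carboxylate", "oxygens": ("O31", "O32")},
    "N1": {"kind": "donor", "heavy": "N1"},
}


@dataclass
class DescriptorSeries:
    """A named per-frame scalar descriptor (Å or degrees) with summary stats."""

    name: str
    frames: list[int]
    values: np.ndarray
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.frames):
            raise ValueError("frames and values must have equal length")
        self.mean = float(np.mean(self.values)) if len(self.values) else float("nan")
        self.sd = float(np.std(self.values)) if len(self.values) else float("nan")

    def histogram(self, bin_width: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
        """(bin_centers, counts) with fixed bin width, for distribution plots."""
        lo = np.floor(self.values.min() / bin_width) * bin_width
        hi = np.ceil(self.values.max() / bin_width) * bin_width + bin_width
        edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
        counts, edges = np.histogram(self.values, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        return centers, counts

    def boxplot_stats(self) -> dict[str, float]:
        """Median, quartiles and 1.5*IQR whiskers, mirroring boxplot panels."""
        q1, med, q3 = np.percentile(self.values, [25, 50, 75])
        iqr = q3 - q1
        in_lo = self.values[self.values >= q1 - 1.5 * iqr]
        in_hi = self.values[self.values <= q3 + 1.5 * iqr]
        return {
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "whisker_low": float(in_lo.min()),
            "whisker_high": float(in_hi.max()),
            "mean": self.mean,
            "sd": self.sd,
        }


@dataclass
class NativeInteraction:
    """A reference-structure contact of the CSG side chain, monitored as a
    distance: either a hydrogen bond or a cation-pi contact of the amino
    nitrogen with an aromatic ring centroid."""

    kind: str  # "hbond" | "cation_pi"
    csg_atom: str
    partner: tuple  # (chain, resid, atom name) or (chain, resid, "ring")
    ref_distance: float

    def __post_init__(self) -> None:
        if self.kind not in ("hbond", "cation_pi"):
            raise ValueError(f"unknown interaction kind {self.kind!r}")
        if not self.ref_distance > 0:
            raise ValueError("ref_distance must be positive")

    @property
    def label(self) -> str:
        chain, resid, atom = self.partner
        return f"CSG.{self.csg_atom}--{chain}:{resid}.{atom}"


# ---------------------------------------------------------------------------
# superposition / RMSD

def kabsch_superpose(mobile: np.ndarray, ref: np.ndarray,
                     weights: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted least-squares rigid superposition of ``mobile`` onto ``ref``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``ref``; the rotation is
    proper (det = +1, no reflection) and the RMSD is the post-fit weighted
    value sqrt(sum w_i |x_i' - y_i|^2 / sum w_i) in Å.
    """
    mobile = np.asarray(mobile, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if mobile.shape != ref.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and ref must be matching N x 3 arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 atoms")
    if weights is None:
        weights = np.ones(n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative with positive sum")
    wn = w / w.sum()
    mc = mobile - wn @ mobile
    rc = ref - wn @ ref
    cov = (mc * wn[:, None]).T @ rc
    u, s, vt = np.linalg.svd(cov)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise ValueError("degenerate geometry: points are (near-)collinear, "
                         "rotation is not determined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    D = np.diag([1.0, 1.0, d])
    rot = vt.T @ D @ u.T
    trans = (wn @ ref) - rot @ (wn @ mobile)
    fitted = mc @ rot.T
    rmsd = float(np.sqrt(np.sum(wn[:, None] * (fitted - rc) ** 2)))
    return rot, trans, rmsd


def _rmsd_plain(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _map_indices_to_ref(traj_top: Structure, ref: Structure,
                        indices: list[int]) -> list[int]:
    """Map flat atom indices on the trajectory topology to the reference
    structure through the (chain, resid, atom name) identity."""
    ref_lookup: dict[tuple[str, int, str], int] = {}
    i = 0
    for res in ref.residues:
        for a in res.atoms:
            ref_lookup[(res.chain, res.resid, a.name)] = i
            i += 1
    traj_keys = []
    for res in traj_top.residues:
        for a in res.atoms:
            traj_keys.append((res.chain, res.resid, a.name))
    mapped = []
    missing = []
    for idx in indices:
        key = traj_keys[idx]
        if key in ref_lookup:
            mapped.append(ref_lookup[key])
        else:
            missing.append(key)
    if missing:
        raise ValueError(
            "atoms not found in reference structure: "
            + ", ".join(f"{c}:{r}.{n}" for c, r, n in missing))
    return mapped


def rmsd_series(traj: Trajectory, ref: Structure,
                fit_sel: Selection | str | None = "all",
                calc_sel: Selection | str | None = None,
                name: str = "rmsd") -> DescriptorSeries:
    """Per-frame RMSD (Å) of a trajectory against a reference structure.

    Each frame is superposed on ``fit_sel`` and the RMSD evaluated over
    ``calc_sel`` without refitting; ``calc_sel=None`` reuses ``fit_sel``
    (classic RMSD).  ``fit_sel=None`` skips superposition entirely and
    reports the raw (unfitted) deviation.  Atoms are matched between the
    two topologies by (chain, resid, name); unmatched atoms are an error.
    """
    if fit_sel is None and calc_sel is None:
        calc_sel = "all"
    if calc_sel is None:
        calc_sel = fit_sel
    calc_idx = select(traj.topology, Selection(calc_sel) if isinstance(calc_sel, str) else calc_sel)
    calc_ref_idx = _map_indices_to_ref(traj.topology, ref, calc_idx)
    ref_coords = ref.coords
    values = np.empty(traj.n_frames)
    if fit_sel is not None:
        fit_idx = select(traj.topology, Selection(fit_sel) if isinstance(fit_sel, str) else fit_sel)
        fit_ref_idx = _map_indices_to_ref(traj.topology, ref, fit_idx)
        for f in range(traj.n_frames):
            frame = traj.frames[f]
            rot, trans, _ = kabsch_superpose(frame[fit_idx], ref_coords[fit_ref_idx])
            moved = frame[calc_idx] @ rot.T + trans
            values[f] = _rmsd_plain(moved, ref_coords[calc_ref_idx])
    else:
        for f in range(traj.n_frames):
            values[f] = _rmsd_plain(traj.frames[f][calc_idx], ref_coords[calc_ref_idx])
    return DescriptorSeries(name, list(range(traj.n_frames)), values)


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted radius of gyration, Å:
    Rg = sqrt(sum m_i |x_i - xbar|^2 / sum m_i) with xbar the mass-weighted
    centroid.  A compactness descriptor; a single atom has Rg = 0.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    masses = np.asarray(masses, dtype=float).reshape(-1)
    if coords.shape[0] != masses.shape[0] or coords.shape[0] < 1:
        raise ValueError("coords and masses must match and be non-empty")
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    center = masses @ coords / masses.sum()
    return float(np.sqrt(masses @ np.sum((coords - center) ** 2, axis=1) / masses.sum()))


def rg_series(traj: Trajectory, sel: Selection | str = "all",
              name: str = "rg") -> DescriptorSeries:
    """Per-frame mass-weighted Rg over a selection."""
    idx = select(traj.topology, Selection(sel) if isinstance(sel, str) else sel)
    masses = traj.topology.masses[idx]
    values = np.array([radius_of_gyration(traj.frames[f][idx], masses)
                       for f in range(traj.n_frames)])
    return DescriptorSeries(name, list(range(traj.n_frames)), values)


def dihedral(p1, p2, p3, p4) -> float:
    """Signed IUPAC torsion in degrees, (-180, 180]; cis = 0."""
    return torsion(p1, p2, p3, p4)


def circular_mean_sd(values_deg: np.ndarray) -> tuple[float, float]:
    """Circular mean and circular standard deviation (degrees) via the mean
    resultant vector; appropriate for torsions that wrap at +-180."""
    rad = np.radians(np.asarray(values_deg, dtype=float))
    c = np.mean(np.cos(rad))
    s = np.mean(np.sin(rad))
    mean = np.degrees(np.arctan2(s, c))
    if mean <= -180.0:
        mean += 360.0
    r = np.hypot(c, s)
    r = min(max(r, 1e-300), 1.0)
    sd = np.degrees(np.sqrt(-2.0 * np.log(r)))
    return float(mean), float(sd)


@dataclass
class AngleSeries(DescriptorSeries):
    """Torsion series with circular summary statistics."""

    circular_mean: float = field(init=False)
    circular_sd: float = field(init=False)

    def __post_init__(self) -> None:
        super().__post_init__()
        self.circular_mean, self.circular_sd = circular_mean_sd(self.values)


def ss_dihedral_series(traj: Trajectory, csg: tuple[str, int],
                       name: str = "chi_ss") -> AngleSeries:
    """Per-frame S-S torsion chi_ss = CB-SG-SG2-CB2 of a CSG residue.

    This is the torsion about the disulfide bond created by the
    glutathionylation; it sits near +-90 degrees in well-formed disulfides.
    Returns an :class:`AngleSeries` carrying circular mean/sd.
    """
    chain, resid = csg
    res = traj.topology.residue(chain, resid)
    name_to_local = {a.name: i for i, a in enumerate(res.atoms)}
    try:
        local = [name_to_local[nm] for nm in ("CB", "SG", "SG2", "CB2")]
    except KeyError as exc:
        raise ValueError(f"CSG residue {chain}:{resid} misses an S-S dihedral atom: {exc}")
    offset = 0
    for r in traj.topology.residues:
        if r is res:
            break
        offset += len(r.atoms)
    idx = [offset + i for i in local]
    values = np.array([torsion(*traj.frames[f][idx]) for f in range(traj.n_frames)])
    return AngleSeries(name, list(range(traj.n_frames)), values)


# ---------------------------------------------------------------------------
# native interactions

def _flat_index(s: Structure, res, atom_name: str) -> int:
    i = 0
    for r in s.residues:
        for a in r.atoms:
            if r is res and a.name == atom_name:
                return i
            i += 1
    raise KeyError(atom_name)


def _bonded_hydrogens(s: Structure, res, heavy_name: str,
                      cutoff: float = 1.25) -> list[str]:
    heavy = res.atom(heavy_name)
    out = []
    for a in res.atoms:
        if a.element.upper() == "H" and np.linalg.norm(a.position - heavy.position) <= cutoff:
            out.append(a.name)
    return out


def _moiety_distance(csg_res, moiety: str, partner_pos: np.ndarray) -> float:
    """Distance (Å) from a monitored CSG moiety to a partner position.

    Carboxylate moieties (C1, C3) report the nearest of their two oxygens,
    symmetric under crystallographic O-name swaps; everything else reports
    the named atom directly.
    """
    info = CSG_POLAR_MOIETIES[moiety]
    if info["kind"] == "carboxylate":
        ds = [float(np.linalg.norm(csg_res.atom(o).position - partner_pos))
              for o in info["oxygens"] if csg_res.has_atom(o)]
        if not ds:
            raise ValueError(f"CSG carboxylate {moiety} has no oxygens present")
        return min(ds)
    return float(np.linalg.norm(csg_res.atom(moiety).position - partner_pos))


def find_native_interactions(ref: Structure, csg: tuple[str, int],
                             d_max: float = 3.5,
                             cation_pi_max: float = 6.0) -> list[NativeInteraction]:
    """Identify reference-structure contacts of the CSG side chain.

    For each monitored CSG polar moiety (O2, OE1, H2, H4, C1, C3, N1) every
    protein N/O heavy atom within ``d_max`` (heavy-heavy, Å) yields an
    hbond entry; when a donor hydrogen is present on either side, a
    D-H...A angle >= 120 degrees filter is applied.  The amino nitrogen is
    additionally tested against TYR/PHE/TRP ring centroids within
    ``cation_pi_max`` for cation-pi contacts.  Distances reported follow
    the moiety convention (carboxylates: nearest oxygen).
    """
    chain, resid = csg
    csg_res = ref.residue(chain, resid)
    out: list[NativeInteraction] = []
    for moiety, info in CSG_POLAR_MOIETIES.items():
        if info["kind"] == "carboxylate":
            anchors = [o for o in info["oxygens"] if csg_res.has_atom(o)]
            if not anchors:
                continue
        else:
            if not csg_res.has_atom(info["heavy"]):
                continue
            if info["kind"] == "donor_h" and not csg_res.has_atom(moiety):
                # amide H absent (e.g. X-ray): monitor through the N anyway
                pass
            anchors = [info["heavy"]]
        for res in ref.residues:
            if res is csg_res:
                continue
            for a in res.atoms:
                if a.element.upper() not in ("N", "O"):
                    continue
                d_heavy = min(
                    float(np.linalg.norm(csg_res.atom(h).position - a.position))
                    for h in anchors)
                if d_heavy > d_max:
                    continue
                if not _hbond_geometry_ok(csg_res, moiety, info, res, a):
                    continue
                if info["kind"] == "donor_h" and csg_res.has_atom(moiety):
                    dist = _moiety_distance(csg_res, moiety, a.position)
                else:
                    dist = d_heavy
                out.append(NativeInteraction("hbond", moiety,
                                             (res.chain, res.resid, a.name), dist))
    # cation-pi: CSG amino nitrogen vs aromatic ring centroids
    if csg_res.has_atom("N1"):
        n1 = csg_res.atom("N1").position
        for res in ref.residues:
            ring = AROMATIC_RING_ATOMS.get(res.resname.upper())
            if ring is None or not all(res.has_atom(nm) for nm in ring):
                continue
            centroid = np.mean([res.atom(nm).position for nm in ring], axis=0)
            d = float(np.linalg.norm(n1 - centroid))
            if d <= cation_pi_max:
                out.append(NativeInteraction("cation_pi", "N1",
                                             (res.chain, res.resid, "ring"), d))
    return out


def _hbond_geometry_ok(csg_res, moiety: str, info: dict, partner_res, partner_atom,
                       min_angle: float = 120.0) -> bool:
    """D-H...A angle filter, applied only when the relevant H exists."""
    from ._geom import angle as _angle
    if info["kind"] == "donor_h" and csg_res.has_atom(moiety):
        donor = csg_res.atom(info["heavy"]).position
        h = csg_res.atom(moiety).position
        return _angle(donor, h, partner_atom.position) >= min_angle
    if info["kind"] in ("acceptor", "carboxylate") and partner_atom.element.upper() == "N":
        hs = _bonded_hydrogens(partner_res, partner_atom.name)
        if hs:
            if info["kind"] == "carboxylate":
                acc = min((csg_res.atom(o).position for o in info["oxygens"]
                           if csg_res.has_atom(o)),
                          key=lambda p: np.linalg.norm(p - partner_atom.position))
            else:
                acc = csg_res.atom(moiety).position
            return any(_angle(partner_atom.position,
                              partner_res.atom(h).position, acc) >= min_angle
                       for h in hs)
    return True


def interaction_distance_series(traj: Trajectory,
                                interactions: list[NativeInteraction],
                                csg: tuple[str, int]) -> list[DescriptorSeries]:
    """Monitor each native-interaction distance along a trajectory.

    One series per interaction, named by its label.  Ring partners use the
    centroid of the aromatic heavy atoms per frame.  An unresolvable
    partner is a hard error naming it.
    """
    chain, resid = csg
    top = traj.topology
    csg_res = top.residue(chain, resid)
    out: list[DescriptorSeries] = []
    for inter in interactions:
        pchain, presid, pname = inter.partner
        try:
            partner_res = top.residue(pchain, presid)
        except KeyError:
            raise ValueError(f"interaction partner residue {pchain}:{presid} "
                             "not present in trajectory topology") from None
        if pname == "ring":
            ring = AROMATIC_RING_ATOMS.get(partner_res.resname.upper())
            if ring is None:
                raise ValueError(
                    f"interaction {inter.label}: residue {partner_res.resname} has no ring")
            p_idx = [_flat_index(top, partner_res, nm) for nm in ring]
        else:
            if not partner_res.has_atom(pname):
                raise ValueError(f"interaction partner atom {pchain}:{presid}.{pname} "
                                 "not present in trajectory topology")
            p_idx = [_flat_index(top, partner_res, pname)]
        info = CSG_POLAR_MOIETIES[inter.csg_atom]
        if info["kind"] == "carboxylate":
            c_idx = [_flat_index(top, csg_res, o) for o in info["oxygens"]
                     if csg_res.has_atom(o)]
        elif info["kind"] == "donor_h" and not csg_res.has_atom(inter.csg_atom):
            c_idx = [_flat_index(top, csg_res, info["heavy"])]
        else:
            c_idx = [_flat_index(top, csg_res, inter.csg_atom)]
        values = np.empty(traj.n_frames)
        for f in range(traj.n_frames):
            frame = traj.frames[f]
            target = frame[p_idx].mean(axis=0)
            values[f] = min(float(np.linalg.norm(frame[i] - target)) for i in c_idx)
        out.append(DescriptorSeries(inter.label, list(range(traj.n_frames)), values))
    return out


def hbond_occupancy(series: DescriptorSeries, d_cut: float = 3.5) -> float:
    """Percentage of frames whose monitored distance is within ``d_cut`` Å —
    the fraction of the ensemble in which the native contact is formed."""
    if len(series.values) == 0:
        raise ValueError("empty series")
    return float(100.0 * np.mean(series.values <= d_cut))
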
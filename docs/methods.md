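# Methods

`csgkit` builds and validates AMBER-style force-field parameters for
S-glutathionylated cysteine (CSG), the residue formed when the tripeptide
glutathione (γ-Glu–Cys–Gly, GSH) attaches to a protein cysteine through a
disulfide bond. The package covers the desk-side portion of that
workflow: charge fitting and bookkeeping, residue-library generation,
in silico grafting of the modification onto unmodified structures, and the
structural descriptors used to compare simulation ensembles of modified
proteins against experimental references. Quantum-chemistry steps
(geometry optimization, ESP evaluation) and molecular dynamics itself are
upstream and downstream of this package, respectively; `csgkit` consumes
their outputs and prepares their inputs.

## RESP charge fitting

`charges.fit_resp` solves the restrained electrostatic potential problem:
minimize

    Σ_i ( V_i − Σ_j q_j / r_ij )²  +  Σ_j a ( √(q_j² + b²) − b )

over atomic point charges q_j, subject to a fixed total charge, optional
frozen charges, and within-group charge equality. V_i are the quantum
electrostatic potential samples (Hartree/e) at grid points r_i (Bohr);
the hyperbolic penalty pulls charges toward zero without the hard
cusp of an L1 term. Because the penalty depends on q, the normal
equations are re-linearized each pass (the penalty diagonal becomes
`a/√(q² + b²)`), and the constrained linear system — total charge enforced
through a Lagrange multiplier, equivalence groups collapsed to single
unknowns, frozen atoms moved to the right-hand side — is iterated until
`max |Δq| < 1e−8` (default cap 200 passes; non-convergence and singular
systems are hard errors).

The two-stage protocol is the canonical one: stage 1 fits all free atoms
with the weak restraint `a1 = 0.0005 e²` applied to non-hydrogen atoms
only (hydrogens are never restrained); stage 2 refits only the
methyl/methylene carbons and their hydrogens with `a2 = 0.001 e²` and
hydrogen equivalencing, holding everything else at stage-1 values.
`charges.default_stage2_refit` derives that refit set from a residue
template's bond graph (sp3 carbons carrying ≥ 2 symmetry-equivalent
hydrogens, detected by depth-2 bonded-type environment); callers can
override both the refit set and the equivalence groups. With `a = 0` and
an ESP generated exactly from point charges, the optimum is the
generating charge set, which is the package's main correctness oracle.

Restraint width `b = 0.1 e` throughout. ESP geometry is atomic units
(1 Bohr = 0.529177210903 Å); the grid-file dialect is a count line
followed by nucleus lines (`name x y z`) and sample lines (`V x y z`).

## Charge normalization

A model compound for a modified residue is capped (acetyl / methylamino),
so its fitted charges must be spliced into the protein force field.
`charges.normalize_charges` implements the standard bookkeeping: capping
atoms are deleted and their charge discarded; backbone atoms (N, H, CA,
HA, C, O) take the parent force field's cysteine values (ff14SB set
shipped as `FF14SB_CYS_CHARGES`); the residual needed to reach the
integer residue charge is spread uniformly over the side-chain atoms
(Δ = residual / n_side, order 0.001 e in practice). The output sums to
the integer target to 1e−9 by construction; the OFF writer refuses
residues whose total deviates from an integer by more than 1e−6.

## The CSG residue template

The grafting and library code is driven by a residue template: atom
names, AMBER-style atom types, charges, bonds, head/tail (N/C) chain
links, and a z-matrix for the glutathione moiety. The bundled
`data/csg_template_synthetic.toml` is a **synthetic stand-in** assembled
from ff14SB cysteine backbone charges, chemically plausible
amide/carboxylate/amine side-chain charges normalized to a total of −1 by
the package's own procedure, and textbook internal coordinates (S–S
2.04 Å, C–S 1.81 Å, CB–S–S 104°, amide planarity, carboxylates
symmetric). It is not a fitted parameter set; users doing production
parameterization should regenerate charges from their own ESP data with
`fit_resp` + `normalize_charges` and rebuild the library. Atom naming
follows the GSH chemical-component convention (SG2, CB2, CA2, N2/H2,
CD1/OE1, CG1, CB1, CA1, N1, C1/O11/O12, C2/O2, N3/H4, CA3, C3/O31/O32)
so grafted structures align with deposited S-glutathionylated entries.

The residue total charge is −1: the glutamyl α-amino/α-carboxylate pair
is zwitterionic (net 0) and the glycyl carboxylate contributes −1.

## Grafting

`grafting.graft_glutathione` renames the target CYS to CSG, removes the
thiol hydrogen, and places the 35 moiety atoms by NeRF internal-coordinate
construction seeded on the existing SG/CB/CA positions. Two torsions are
exposed: χss (CB–SG–SG2–CB2, the torsion about the new S–S bond, default
+90°) and χ2 (CA–CB–SG–SG2, default 180°). Disulfide torsions cluster
near ±90°, and both signs occur in experimental S-glutathionylated
structures, so `enumerate_rotamers` alternates χss signs first and then
walks a χ2 grid of k = ⌈n/2⌉ values spaced 360/k apart — starting
ensembles for a modification whose initial side-chain orientation is
unknown should sample both. Pre-existing atoms are never moved
(bit-identical before/after), and the three moiety residues are built as
L-amino acids; the construction was checked against an RDKit-embedded
L-cysteine reference via the signed volume (N−CA)·((C−CA)×(CB−CA)).

Steric screening uses heavy-atom contacts below 2.0 Å with 1-2/1-3 pairs
excluded (template bond graph inside the residue, distance-inferred bonds
otherwise). Clashes annotate rotamers rather than discarding them — the
geometry relaxes in any downstream minimization — but if every rotamer of
a direct graft clashes, the error carries the best clash report.

## Descriptors

- **Superposition / RMSD** — weighted Kabsch via SVD with the
  determinant-correction for proper rotations; collinear geometries are
  rejected. `rmsd_series` superposes each frame on a fit selection and
  measures over a calculation selection *without refitting*; `fit=None`
  yields the raw (unfitted) deviation. The CSG-site protocol superposes
  on the protein backbone and measures over all CSG atoms, so side-chain
  reorientations (e.g. an arm-swapped glutathione) register instead of
  being absorbed by a local fit.
- **Radius of gyration** — mass-weighted, IUPAC masses from the built-in
  element table (unknown elements are hard errors, never silently
  defaulted). All atoms present in the structure are used; crystal
  structures without hydrogens are therefore compared heavy-atom to
  heavy-atom, a sub-0.1 Å effect at protein size.
- **Torsions** — signed IUPAC convention, atan2 form, range (−180, 180].
  Series over the S–S torsion report circular mean and circular standard
  deviation (mean resultant vector), which behave correctly across the
  ±180 wrap and for broad distributions. Note that the signed torsion is
  invariant under full atom-order reversal (reversal is a symmetry, not
  an antisymmetry); mirror reflection negates it.
- **Native interactions** — the CSG polar moieties monitored are the two
  amide groups formed during GSH biosynthesis (O2, OE1 and amide protons
  H2, H4), the glycyl carboxylate (C3), and the glutamyl carboxylate (C1)
  and amino group (N1). Hydrogen bonds are identified in the reference
  structure by a 3.5 Å heavy–heavy cutoff against protein N/O atoms, with
  a D–H⋯A ≥ 120° filter applied only when the hydrogen exists;
  carboxylate distances take the nearest of the two oxygens, making them
  symmetric under crystallographic O-name swaps. Cation–π contacts pair
  N1 against TYR/PHE/TRP ring-centroid distances within 6.0 Å. Along a
  trajectory the monitored quantity is the distance only (with 0.1 Å
  histogram export); occupancy is the percentage of frames within the
  cutoff.

## Clustering

Frame-frame distances are best-fit RMSD over a user selection (backbone
for global conformations, all CSG atoms for site-level analysis). The
partition comes from average-linkage agglomerative clustering, terminated
either at a distance cutoff ε (default 2.0 Å; merging stops when the
average inter-cluster RMSD exceeds it) or at a fixed cluster count k (for
testability and degenerate cases). Clusters are numbered by descending
occupancy (ties to the lowest member frame), occupancies sum to exactly
100%, and each cluster's representative is the member minimizing the mean
distance to its co-members. The O(F²) matrix bounds ensemble size; the
CLI exposes a stride for long ensembles.

## Synthetic fixtures

The generators emulate the *statistical structure* the analyses consume,
not force-field physics:

- `make_toy_peptide` — extended (β-strand-like, φ = −135°, ψ = 135°)
  A/G/C chains from ideal internal coordinates, chemically complete
  (amide H on every N, C-terminal OXT, single N-terminal H — a simplified
  terminal treatment), with optional in-place S-glutathionylation through
  the real grafting path.
- `make_wobble_trajectory` — frames are the reference plus i.i.d.
  Gaussian(0, σ²) coordinate noise (NumPy PCG64, explicit seed). The
  expected unfitted RMSD is σ√3, giving a closed-form calibration target;
  unlike MD, the noise has no temporal correlation, no bonded structure
  and no anisotropy, so passing calibration says the estimator is
  correct, not that MD would behave this way.
- `make_two_state_trajectory` — deterministic 60/40-style allocation of
  frames to two conformers (counts are rounded, then seed-shuffled), with
  ground-truth labels returned for partition scoring.
- `make_esp_grid` — Merz–Singh–Kollman-style union-surface shells at
  {1.4, 1.6, 1.8, 2.0} × Bondi vdW radii, quasi-uniform golden-spiral
  points under a seeded random rotation, potentials computed exactly from
  the generating point charges. Because the generating model is the
  fitting model, a restraint-free fit must recover the charges to
  numerical precision — an oracle, not a claim about real QM ESPs.

All generators are pure functions of their arguments; byte-identical
output under a fixed seed is asserted in the tests.

## Numerical and design choices

- Coordinates are Å everywhere; ESP data atomic units; 0-based indices
  internally, 1-based in user-facing output (PDB serials, cluster ids,
  frame columns).
- PDB altloc resolution keeps the highest-occupancy location, ties to the
  lexicographically first altloc id; models with inconsistent atom counts
  are hard errors naming the model. Writing refuses non-finite
  coordinates and values that overflow the fixed-width field, and a
  write→read→write cycle is byte-stable.
- "Backbone" means N, CA, C, O plus the amide H; HA is excluded, matching
  the masks common in trajectory-analysis tools, so backbone-RMSD numbers
  are comparable with published ensemble statistics.
- Hydrogens are read if present and never added outside the grafted
  moiety; protonation-state assignment belongs to upstream tools.
- Problem sizes in the validation suite (200-frame wobble ensembles at
  ~500 atoms, 500-frame two-state mixtures, 10-frame oracle fixtures)
  were chosen as the smallest sizes at which the statistical targets
  (σ√3 within 5%, occupancies within 2 points) are comfortably inside
  their expected sampling error.

## Known limitations

- The bundled CSG template is synthetic (see above); its charges are
  format- and procedure-correct, not QM-derived.
- Terminal reconstruction of incomplete chains is not implemented; inputs
  are assumed complete.
- The hydrogen-bond criterion is distance-based on monitored pairs; no
  angular criterion is applied along trajectories (only at identification
  time, when the hydrogen exists).
- Clustering offers only average linkage with ε- or k-termination; no
  density-based variants or cluster-number model selection.
- Comparisons against the published crystal-structure compactness values
  require retrieving the PDB entries at run time; the corresponding
  acceptance check reports the retrieval failure when the archive is
  unreachable.
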
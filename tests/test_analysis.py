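"""Descriptor panel: superposition, RMSD, Rg, torsions, native contacts."""

import math

import numpy as np
import pytest

from csgkit.analysis import (AngleSeries, DescriptorSeries, circular_mean_sd,
                             dihedral, find_native_interactions, hbond_occupancy,
                             interaction_distance_series, kabsch_superpose,
                             radius_of_gyration, rg_series, rmsd_series,
                             ss_dihedral_series)
from csgkit._geom import rotation_about_axis
from csgkit.fixtures import (make_toy_peptide, make_two_state_trajectory,
                             make_wobble_trajectory)
from csgkit.structure import Atom, Residue, Selection, Structure, Trajectory, select

from oracles import naive_dihedral, naive_rg, naive_rmsd_series, quaternion_rmsd


class TestKabsch:
    def test_identity_gives_zero(self, rng):
        x = rng.normal(size=(20, 3))
        _, _, rmsd = kabsch_superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rigid_motion_gives_zero(self, rng):
        x = rng.normal(size=(20, 3))
        rot = rotation_about_axis([0.3, -1.0, 2.0], 37.0)
        y = x @ rot.T + np.array([1.0, -2.0, 3.0])
        r, t, rmsd = kabsch_superpose(y, x)
        assert rmsd == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(y @ r.T + t, x, atol=1e-8)

    def test_rotation_is_proper(self, rng):
        x = rng.normal(size=(10, 3))
        # mirrored target tempts an improper solution
        y = x.copy()
        y[:, 0] = -y[:, 0]
        r, _, _ = kabsch_superpose(x, y)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-10)

    def test_square_with_displaced_atom_matches_quaternion_oracle(self):
        ref = np.array([[0, 0, 0], [2, 0, 0], [2, 2, 0], [0, 2, 0]], dtype=float)
        mob = ref.copy()
        mob[3, 2] += 1.0
        _, _, rmsd = kabsch_superpose(mob, ref)
        assert rmsd == pytest.approx(quaternion_rmsd(mob, ref), abs=1e-8)

    def test_random_clouds_match_quaternion_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 40))
            mob = rng.normal(size=(n, 3)) * rng.uniform(0.5, 3.0)
            ref = rng.normal(size=(n, 3))
            _, _, rmsd = kabsch_superpose(mob, ref)
            assert rmsd == pytest.approx(quaternion_rmsd(mob, ref), abs=1e-8)

    def test_weighted_fit(self, rng):
        x = rng.normal(size=(12, 3))
        w = rng.uniform(0.5, 2.0, size=12)
        rot = rotation_about_axis([1, 1, 1], 25.0)
        y = x @ rot.T + 4.0
        _, _, rmsd = kabsch_superpose(y, x, weights=w)
        assert rmsd == pytest.approx(0.0, abs=1e-8)

    def test_collinear_points_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)


class TestRmsdSeries:
    def test_copies_of_reference_give_zeros(self, toy_csg):
        traj = make_wobble_trajectory(toy_csg, 0.0, 5, seed=1)
        series = rmsd_series(traj, toy_csg, fit_sel="all")
        np.testing.assert_allclose(series.values, 0.0, atol=1e-10)

    def test_wobble_mean_matches_closed_form(self):
        """Unfitted RMSD of sigma-Gaussian noise concentrates near
        sigma * sqrt(3)."""
        big = make_toy_peptide("A" * 50)
        traj = make_wobble_trajectory(big, 0.2, 200, seed=42)
        series = rmsd_series(traj, big, fit_sel=None)
        expected = 0.2 * math.sqrt(3.0)
        assert abs(series.mean - expected) / expected < 0.05

    def test_fitted_rmsd_not_above_unfitted(self, toy_csg):
        traj = make_wobble_trajectory(toy_csg, 0.3, 20, seed=3)
        fitted = rmsd_series(traj, toy_csg, fit_sel="all")
        unfitted = rmsd_series(traj, toy_csg, fit_sel=None)
        assert np.all(fitted.values <= unfitted.values + 1e-12)

    def test_rigid_motion_invariance(self, toy_csg):
        traj = make_wobble_trajectory(toy_csg, 0.2, 8, seed=5)
        rot = rotation_about_axis([2.0, 1.0, 0.5], 63.0)
        moved = Trajectory(toy_csg.copy(), traj.frames @ rot.T + 7.0)
        s1 = rmsd_series(traj, toy_csg, fit_sel="backbone")
        s2 = rmsd_series(moved, toy_csg, fit_sel="backbone")
        np.testing.assert_allclose(s1.values, s2.values, atol=1e-8)

    def test_monotonic_in_sigma(self, toy_csg):
        means = []
        for sigma in (0.1, 0.2, 0.4):
            traj = make_wobble_trajectory(toy_csg, sigma, 50, seed=11)
            means.append(rmsd_series(traj, toy_csg, fit_sel="all").mean)
        assert means[0] < means[1] < means[2]

    def test_csg_site_protocol_matches_naive_oracle(self, toy_csg):
        """Backbone fit + CSG measurement equals a quaternion-based
        per-frame recomputation on 10 frames."""
        traj = make_wobble_trajectory(toy_csg, 0.25, 10, seed=9)
        series = rmsd_series(traj, toy_csg, fit_sel="backbone",
                             calc_sel="resname CSG")
        fit_idx = np.array(select(toy_csg, "backbone"))
        calc_idx = np.array(select(toy_csg, "resname CSG"))
        want = naive_rmsd_series(traj.frames, toy_csg.coords, fit_idx, calc_idx)
        np.testing.assert_allclose(series.values, want, atol=1e-8)

    def test_atom_mismatch_lists_names(self, toy_csg, toy_plain):
        traj = make_wobble_trajectory(toy_csg, 0.1, 2, seed=1)
        with pytest.raises(ValueError, match="SG2"):
            rmsd_series(traj, toy_plain, fit_sel="all")


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        assert radius_of_gyration(np.zeros((1, 3)), np.array([12.0])) == 0.0

    def test_two_unit_masses_two_angstrom_apart(self):
        coords = np.array([[0, 0, 0], [2, 0, 0]], dtype=float)
        assert radius_of_gyration(coords, np.ones(2)) == pytest.approx(1.0)

    def test_cube_corners(self):
        corners = np.array([[x, y, z] for x in (0, 2) for y in (0, 2) for z in (0, 2)],
                           dtype=float)
        assert radius_of_gyration(corners, np.ones(8)) == pytest.approx(math.sqrt(3))

    def test_rigid_motion_invariance_and_scaling(self, toy_csg):
        coords = toy_csg.coords
        masses = toy_csg.masses
        base = radius_of_gyration(coords, masses)
        rot = rotation_about_axis([1, 0, 1], 81.0)
        assert radius_of_gyration(coords @ rot.T + 3.0, masses) == pytest.approx(
            base, abs=1e-9)
        assert radius_of_gyration(coords * 2.5, masses) == pytest.approx(
            2.5 * base, abs=1e-9)

    def test_matches_naive_oracle(self, toy_csg):
        got = radius_of_gyration(toy_csg.coords, toy_csg.masses)
        want = naive_rg(toy_csg.coords, toy_csg.masses)
        assert got == pytest.approx(want, abs=1e-8)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            radius_of_gyration(np.zeros((2, 3)), np.array([1.0, 0.0]))


class TestDihedral:
    def test_cis_zero(self):
        assert dihedral([1, 1, 0], [1, 0, 0], [2, 0, 0], [2, 1, 0]) == pytest.approx(0.0)

    def test_trans_180(self):
        assert dihedral([1, 1, 0], [1, 0, 0], [2, 0, 0], [2, -1, 0]) == pytest.approx(180.0)

    def test_stated_sign_convention(self):
        val = dihedral([1, 0, 0], [0, 0, 0], [0, 1, 0], [0, 1, 1])
        assert val == pytest.approx(-90.0)

    def test_reversal_symmetry_and_mirror_antisymmetry(self, rng):
        """Reversing the atom order preserves the signed torsion; a mirror
        reflection negates it (for non-180 values)."""
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 2.0
            try:
                fwd = dihedral(*pts)
            except ValueError:
                continue
            if abs(abs(fwd) - 180.0) < 1e-6:
                continue
            assert dihedral(*pts[::-1]) == pytest.approx(fwd, abs=1e-9)
            mirrored = pts * np.array([1.0, 1.0, -1.0])
            assert dihedral(*mirrored) == pytest.approx(-fwd, abs=1e-9)

    def test_matches_naive_oracle(self, rng):
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 3.0
            try:
                got = dihedral(*pts)
            except ValueError:
                continue
            assert got == pytest.approx(naive_dihedral(*pts), abs=1e-8)

    def test_collinear_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


class TestSsDihedralSeries:
    @pytest.mark.parametrize("chi", [90.0, -90.0])
    def test_grafted_value_recovered_along_frames(self, chi):
        s = make_toy_peptide("ACA", include_csg_at=2, chi_ss=chi)
        traj = make_wobble_trajectory(s, 0.0, 4, seed=1)
        series = ss_dihedral_series(traj, ("A", 2))
        np.testing.assert_allclose(series.values, chi, atol=0.5)
        assert series.circular_mean == pytest.approx(chi, abs=0.5)

    def test_circular_mean_wraps(self):
        mean, sd = circular_mean_sd(np.array([179.0, -179.0]))
        assert mean == pytest.approx(180.0, abs=1e-9)
        assert sd < 2.0

    def test_missing_atom_is_error(self, toy_plain):
        traj = make_wobble_trajectory(toy_plain, 0.0, 1, seed=1)
        with pytest.raises(ValueError, match="S-S dihedral"):
            ss_dihedral_series(traj, ("A", 2))


def _partner(resname, resid, atoms, chain="A"):
    return Residue(resname, resid, chain,
                   [Atom(nm, el, m, np.asarray(p, float))
                    for nm, el, m, p in atoms])


def _amide_acceptor_pos(s, dist):
    """A position ``dist`` Å from CSG N2 along the N2->H2 direction, so the
    donor-H-acceptor angle is ideal (180 degrees)."""
    res = s.residue("A", 2)
    n2 = res.atom("N2").position
    h2 = res.atom("H2").position
    u = (h2 - n2) / np.linalg.norm(h2 - n2)
    return n2 + dist * u


class TestNativeInteractions:
    def _csg_with_partner(self, partner_res):
        s = make_toy_peptide("ACA", include_csg_at=2)
        return Structure([r.copy() for r in s.residues] + [partner_res])

    def test_carbonyl_near_amide_found(self, toy_csg):
        partner = _partner("GLY", 50,
                           [("O", "O", 15.999, _amide_acceptor_pos(toy_csg, 2.9))])
        s = self._csg_with_partner(partner)
        hits = find_native_interactions(s, ("A", 2))
        labels = {(i.csg_atom, i.partner) for i in hits if i.kind == "hbond"}
        assert ("H2", ("A", 50, "O")) in labels

    def test_distant_carbonyl_not_found(self, toy_csg):
        partner = _partner("GLY", 50,
                           [("O", "O", 15.999, _amide_acceptor_pos(toy_csg, 4.0))])
        s = self._csg_with_partner(partner)
        hits = [i for i in find_native_interactions(s, ("A", 2))
                if i.partner[1] == 50 and i.csg_atom == "H2"]
        assert hits == []

    def test_cation_pi_distance_matches_centroid(self, toy_csg):
        ring_names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
        n1 = toy_csg.residue("A", 2).atom("N1").position
        center = n1 + np.array([4.5, 0.0, 0.0])
        ring_atoms = []
        for k, nm in enumerate(ring_names):
            ang = 2 * np.pi * k / 6
            p = center + 1.39 * np.array([0.0, np.cos(ang), np.sin(ang)])
            ring_atoms.append((nm, "C", 12.011, p))
        # give the tyrosine something polar-free so only the ring matters
        partner = _partner("TYR", 60, ring_atoms)
        s = self._csg_with_partner(partner)
        hits = [i for i in find_native_interactions(s, ("A", 2))
                if i.kind == "cation_pi"]
        assert len(hits) == 1
        centroid = np.mean([np.asarray(p) for _, _, _, p in ring_atoms], axis=0)
        assert hits[0].ref_distance == pytest.approx(
            float(np.linalg.norm(n1 - centroid)), abs=1e-9)

    def test_carboxylate_uses_nearest_oxygen_symmetrically(self, toy_csg):
        res = toy_csg.residue("A", 2)
        o31 = res.atom("O31").position
        partner = _partner("SER", 70, [("OG", "O", 15.999, o31 + [0.0, 0.0, 3.0])])
        s = self._csg_with_partner(partner)
        hits = [i for i in find_native_interactions(s, ("A", 2))
                if i.csg_atom == "C3" and i.partner[1] == 70]
        assert len(hits) == 1
        d_ref = hits[0].ref_distance
        # swap the two carboxylate oxygens: distance must be unchanged
        s2 = Structure([r.copy() for r in s.residues])
        r2 = s2.residue("A", 2)
        a31, a32 = r2.atom("O31"), r2.atom("O32")
        a31.position, a32.position = a32.position.copy(), a31.position.copy()
        hits2 = [i for i in find_native_interactions(s2, ("A", 2))
                 if i.csg_atom == "C3" and i.partner[1] == 70]
        assert hits2[0].ref_distance == pytest.approx(d_ref, abs=1e-12)


class TestDistanceSeries:
    def test_static_trajectory_sd_zero(self, toy_csg):
        partner = _partner("GLY", 50,
                           [("O", "O", 15.999, _amide_acceptor_pos(toy_csg, 2.9))])
        s = Structure([r.copy() for r in toy_csg.residues] + [partner])
        inters = find_native_interactions(s, ("A", 2))
        traj = make_wobble_trajectory(s, 0.0, 6, seed=2)
        for series in interaction_distance_series(traj, inters, ("A", 2)):
            assert series.sd == pytest.approx(0.0, abs=1e-12)

    def test_two_state_distances_bimodal(self, toy_csg):
        pos_near = _amide_acceptor_pos(toy_csg, 2.9)
        pos_far = _amide_acceptor_pos(toy_csg, 5.0)
        near = _partner("GLY", 50, [("O", "O", 15.999, pos_near)])
        s_near = Structure([r.copy() for r in toy_csg.residues] + [near])
        s_far = s_near.copy()
        s_far.residue("A", 50).atom("O").position = pos_far
        inters = [i for i in find_native_interactions(s_near, ("A", 2))
                  if i.partner[1] == 50 and i.csg_atom == "H2"]
        assert len(inters) == 1
        h2 = toy_csg.residue("A", 2).atom("H2").position
        d_near = float(np.linalg.norm(h2 - pos_near))
        d_far = float(np.linalg.norm(h2 - pos_far))
        traj, labels = make_two_state_trajectory(s_near, s_far, (0.5, 0.5),
                                                 sigma=0.0, n_frames=40, seed=8)
        series = interaction_distance_series(traj, inters, ("A", 2))[0]
        centers, counts = series.histogram(0.1)
        modes = np.sort(centers[counts > 0])
        assert len(modes) == 2
        # bin centers sit within half a bin width of the planted distances
        np.testing.assert_allclose(modes, sorted([d_near, d_far]), atol=0.051)

    def test_mean_matches_brute_force(self, toy_csg, rng):
        partner = _partner("GLY", 50,
                           [("O", "O", 15.999, _amide_acceptor_pos(toy_csg, 3.1))])
        s = Structure([r.copy() for r in toy_csg.residues] + [partner])
        inters = [i for i in find_native_interactions(s, ("A", 2))
                  if i.partner[1] == 50 and i.csg_atom == "H2"]
        traj = make_wobble_trajectory(s, 0.15, 10, seed=4)
        series = interaction_distance_series(traj, inters, ("A", 2))[0]
        h2_idx = next(i for i, (r, a) in enumerate(
            (r, a) for r in s.residues for a in r.atoms)
            if r.resid == 2 and a.name == "H2")
        o_idx = s.n_atoms - 1
        want = [float(np.linalg.norm(f[h2_idx] - f[o_idx])) for f in traj.frames]
        np.testing.assert_allclose(series.values, want, atol=1e-8)
        assert series.mean == pytest.approx(np.mean(want), abs=1e-9)

    def test_unresolvable_partner_named(self, toy_csg):
        from csgkit.analysis import NativeInteraction
        bad = NativeInteraction("hbond", "O2", ("A", 99, "O"), 3.0)
        traj = make_wobble_trajectory(toy_csg, 0.0, 2, seed=1)
        with pytest.raises(ValueError, match="A:99"):
            interaction_distance_series(traj, [bad], ("A", 2))


class TestOccupancy:
    def test_all_within_cut(self):
        s = DescriptorSeries("d", [0, 1], np.array([2.9, 2.9]))
        assert hbond_occupancy(s, 3.5) == 100.0

    def test_half_within_cut(self):
        s = DescriptorSeries("d", list(range(4)), np.array([2.9, 5.0, 2.9, 5.0]))
        assert hbond_occupancy(s, 3.5) == 50.0

    def test_none_within_cut(self):
        s = DescriptorSeries("d", [0], np.array([2.9]))
        assert hbond_occupancy(s, 1.0) == 0.0


class TestSeriesStatistics:
    def test_mean_sd_consistent(self, rng):
        vals = rng.normal(2.0, 0.3, size=100)
        s = DescriptorSeries("x", list(range(100)), vals)
        assert s.mean == pytest.approx(float(np.mean(vals)), abs=1e-9)
        assert s.sd == pytest.approx(float(np.std(vals)), abs=1e-9)

    def test_boxplot_stats_quartiles(self):
        vals = np.arange(1.0, 101.0)
        stats = DescriptorSeries("x", list(range(100)), vals).boxplot_stats()
        assert stats["median"] == pytest.approx(50.5)
        assert stats["q1"] < stats["median"] < stats["q3"]
        assert stats["whisker_low"] >= vals.min()
        assert stats["whisker_high"] <= vals.max()
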
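"""CG elongation geometry, energy-based substitution and topology."""

import numpy as np
import pytest

from gagcg.boltzmann import angle_deg, distance
from gagcg.elongate import (DecompositionTable, ElongationSpec, build_topology,
                            elongate, substitute_by_energy)
from gagcg.structures import GagComplex, Representation, residue_centroids
from gagcg.synth import make_decomposition, make_gag_helix

from .test_structures import bead


class TestElongate:
    def test_dp6_to_dp16(self, dp6, ff):
        out = elongate(dp6, ff, ElongationSpec(n_reducing=10))
        reps = [r.representation for r in out.gag_chain]
        assert len(out.gag_chain) == 16
        assert reps.count(Representation.AA) == 6
        assert reps.count(Representation.CG) == 10

    def test_zero_counts_identity(self, dp6, ff):
        out = elongate(dp6, ff, ElongationSpec())
        assert len(out.gag_chain) == len(dp6.gag_chain)
        np.testing.assert_array_equal(
            [a.position for a in out.gag_atoms],
            [a.position for a in dp6.gag_atoms])

    def test_third_bead_placement_geometry(self, ff):
        """Closed form: new bead 5.2 Å from the terminal one at 160°."""
        chain = GagComplex([], [bead(1, [0, 0, 0]), bead(2, [5.2, 0, 0])])
        out = elongate(chain, ff, ElongationSpec(n_reducing=1))
        cents = residue_centroids(out)
        assert distance(cents[1], cents[2]) == pytest.approx(5.2, abs=1e-6)
        assert angle_deg(cents[0], cents[1], cents[2]) == pytest.approx(
            160.0, abs=1e-6)

    def test_consecutive_bead_spacing_exact(self, dp6, ff):
        out = elongate(dp6, ff, ElongationSpec(n_reducing=8))
        cents = residue_centroids(out)
        for i in range(7, 13):
            assert abs(distance(cents[i], cents[i + 1]) - 5.2) < 1e-6

    def test_charge_conservation(self, dp6, ff):
        q0 = dp6.total_gag_charge
        out = elongate(dp6, ff, ElongationSpec(n_nonreducing=3, n_reducing=4,
                                               bead_charge=-2.0))
        assert out.total_gag_charge == pytest.approx(q0 + 7 * -2.0)

    def test_original_atoms_untouched(self, dp6, ff):
        orig = np.array([a.position for a in dp6.gag_atoms])
        out = elongate(dp6, ff, ElongationSpec(n_reducing=5))
        kept = np.array([a.position for a in out.gag_atoms[:orig.shape[0]]])
        np.testing.assert_array_equal(orig, kept)

    def test_junction_through_glycosidic_oxygen(self, dp6, ff):
        out = elongate(dp6, ff, ElongationSpec(n_reducing=1))
        o_pos = dp6.gag_chain[-1].glycosidic_oxygen.position
        bead_pos = out.gag_chain[-1].atoms[0].position
        assert distance(o_pos, bead_pos) == pytest.approx(2.8, abs=1e-6)

    def test_nonreducing_prepended_numbers(self, dp6, ff):
        out = elongate(dp6, ff, ElongationSpec(n_nonreducing=2))
        assert [r.residue_number for r in out.gag_chain[:3]] == [-1, 0, 1]
        assert out.gag_chain[0].representation is Representation.CG

    def test_single_residue_chain_rejected(self, ff):
        c = GagComplex([], [bead(1, [0, 0, 0])])
        with pytest.raises(ValueError, match="direction"):
            elongate(c, ff, ElongationSpec(n_reducing=1))

    def test_clash_rotation_keeps_geometry(self, ff):
        """A receptor atom on the straight-line path forces a rotation that
        still honors the bond length and angle."""
        from gagcg.structures import AtomRecord
        chain = [bead(1, [0, 0, 0]), bead(2, [5.2, 0, 0])]
        # straight-ahead placement would land near (10.3, 1.8, 0)
        probe_pos = np.array([5.2, 0, 0]) + 5.2 * np.array(
            [np.cos(np.radians(20)), np.sin(np.radians(20)), 0])
        blocker = AtomRecord(99, "CA", "GLY", "P", 1, probe_pos, "C")
        # the rotation circle has radius 5.2·sin(20°) ≈ 1.78 Å, so a clash
        # distance of 2 Å can be escaped by rotating to the far side
        out = elongate(GagComplex([blocker], chain), ff,
                       ElongationSpec(n_reducing=1, clash_distance=2.0))
        new = out.gag_chain[-1].atoms[0].position
        assert distance([5.2, 0, 0], new) == pytest.approx(5.2, abs=1e-6)
        assert angle_deg([0, 0, 0], [5.2, 0, 0], new) == pytest.approx(
            160.0, abs=1e-6)
        assert np.linalg.norm(new - probe_pos) >= 2.0

    def test_no_clash_free_placement_errors(self, ff):
        from gagcg.structures import AtomRecord
        chain = [bead(1, [0, 0, 0]), bead(2, [5.2, 0, 0])]
        # cage of receptor atoms surrounding every candidate position
        blockers = []
        k = 0
        for ang in np.arange(0, 360, 10):
            rel = np.array([np.cos(np.radians(20)),
                            np.sin(np.radians(20)) * np.cos(np.radians(ang)),
                            np.sin(np.radians(20)) * np.sin(np.radians(ang))])
            k += 1
            blockers.append(AtomRecord(k, "CA", "GLY", "P", k,
                                       np.array([5.2, 0, 0]) + 5.2 * rel, "C"))
        with pytest.raises(ValueError, match="clash-free"):
            elongate(GagComplex(blockers, chain), ff,
                     ElongationSpec(n_reducing=1, clash_distance=3.0))


class TestSubstituteByEnergy:
    def test_weak_tails_replaced(self, ff):
        gag = make_gag_helix(16, with_ring_atoms=True)
        table = make_decomposition(gag, core_dg=-3.0, tail_dg=-0.1, n_core=6)
        out = substitute_by_energy(gag, table)
        reps = [r.representation for r in out.gag_chain]
        assert reps.count(Representation.CG) == 10
        assert reps.count(Representation.AA) == 6
        # beads sit at the replaced residues' ring centroids
        for before, after in zip(gag.gag_chain, out.gag_chain):
            if after.representation is Representation.CG:
                np.testing.assert_allclose(after.atoms[0].position,
                                           before.ring_centroid)
                assert after.unit_charge == before.unit_charge

    def test_all_strong_unchanged(self, dp6):
        table = make_decomposition(dp6, core_dg=-3.0, tail_dg=-3.0)
        out = substitute_by_energy(dp6, table)
        assert all(r.representation is Representation.AA for r in out.gag_chain)

    def test_boundary_value_kept_aa(self, dp6):
        table = DecompositionTable({r.residue_number: -0.5
                                    for r in dp6.gag_chain})
        out = substitute_by_energy(dp6, table, threshold=-0.5)
        assert all(r.representation is Representation.AA for r in out.gag_chain)

    def test_idempotent(self, dp6):
        table = make_decomposition(dp6, core_dg=-3.0, tail_dg=-0.1, n_core=2)
        once = substitute_by_energy(dp6, table)
        twice = substitute_by_energy(once, table)
        assert [r.representation for r in once.gag_chain] == \
               [r.representation for r in twice.gag_chain]
        np.testing.assert_array_equal(
            [a.position for a in once.gag_atoms],
            [a.position for a in twice.gag_atoms])

    def test_missing_entries_listed(self, dp6):
        table = DecompositionTable({1: -3.0, 2: -3.0})
        with pytest.raises(ValueError, match=r"\[3, 4, 5, 6\]"):
            substitute_by_energy(dp6, table)


class TestBuildTopology:
    @pytest.mark.parametrize("n,expected", [(3, (2, 1, 0)), (4, (3, 2, 1))])
    def test_pure_bead_chain_counts(self, ff, n, expected):
        c = GagComplex([], [bead(i, [5.2 * i, i * 0.3, 0])
                            for i in range(1, n + 1)])
        terms = build_topology(c, ff)
        counts = tuple(sum(t.kind == k for t in terms)
                       for k in ("bond", "angle", "dihedral"))
        assert counts == expected

    def test_junction_bond_resolved(self, dp6, ff):
        out = elongate(dp6, ff, ElongationSpec(n_reducing=1))
        terms = build_topology(out, ff)
        junction = [t for t in terms if t.kind == "bond"
                    and set(t.types) == {"Os", "Z1"}]
        assert len(junction) == 1
        assert junction[0].param.REQ == 2.8

    def test_no_beads_rejected(self, dp6, ff):
        with pytest.raises(ValueError, match="no CG bead"):
            build_topology(dp6, ff)

    def test_unparameterized_bond_errors(self, ff):
        from gagcg.forcefield import PseudoatomForceField
        c = GagComplex([], [bead(1, [0, 0, 0]), bead(2, [5.2, 0, 0])])
        with pytest.raises(ValueError, match="Z1-Z1"):
            build_topology(c, PseudoatomForceField())
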
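"""W factors: site sums, per-residue fits, elongation prediction."""

import numpy as np
import pytest

from gagcg.elongate import DecompositionTable, ElongationSpec, elongate
from gagcg.energetics import ElectrostaticsModel
from gagcg.structures import AtomRecord, GagComplex
from gagcg.wfactor import (PEPTIDE_W, ChargedSite, compute_w,
                           detect_charged_sites, electrostatic_sum,
                           predict_elongated_energy)

from .conftest import apply_rigid, rigid_transform
from .test_structures import bead

COUL = ElectrostaticsModel(kind="coulomb")


def site(pos, sign=1):
    return ChargedSite(("P", 1), sign, np.asarray(pos, float))


class TestElectrostaticSum:
    def test_single_positive_site(self):
        res = bead(1, [0, 0, 0])
        assert electrostatic_sum(res, [site([2, 0, 0])], COUL, 10.0) == 0.5

    def test_opposite_signs_cancel(self):
        res = bead(1, [0, 0, 0])
        sites = [site([4, 0, 0], +1), site([0, 4, 0], -1)]
        assert electrostatic_sum(res, sites, COUL, 10.0) == pytest.approx(0.0)

    def test_cutoff_excludes_far_sites(self):
        res = bead(1, [0, 0, 0])
        assert electrostatic_sum(res, [site([10, 0, 0])], COUL, 8.0) == 0.0

    def test_debye_screened_reciprocal(self):
        res = bead(1, [0, 0, 0])
        debye = ElectrostaticsModel(kind="debye", ionic_strength=0.15)
        s = electrostatic_sum(res, [site([2, 0, 0])], debye, 10.0)
        lam = 3.04 / np.sqrt(0.15)
        assert s == pytest.approx(np.exp(-2.0 / lam) / 2.0)

    def test_coincident_site_rejected(self):
        res = bead(1, [0, 0, 0])
        with pytest.raises(ValueError, match="coincides"):
            electrostatic_sum(res, [site([0, 0, 0])], COUL, 10.0)


class TestComputeW:
    def test_w_is_dg_over_s(self):
        c = GagComplex([], [bead(1, [0, 0, 0]), bead(2, [5.2, 0, 0])])
        sites = [site([2, 0, 0])]  # S(res1) = 0.5
        d = DecompositionTable({1: -6.66, 2: 0.0})
        w = compute_w(c, d, COUL, cutoff=4.0, sites=sites)
        assert w.per_residue_w[1] == pytest.approx(-13.32)
        assert w.per_residue_w[2] == 0.0  # excluded? no: S(res2)...

    def test_zero_dg_gives_zero_w(self):
        c = GagComplex([], [bead(1, [0, 0, 0]), bead(2, [5.2, 0, 0])])
        sites = [site([2, 0, 0]), site([2, 5.2, 0])]
        w = compute_w(c, DecompositionTable({1: 0.0, 2: 0.0}), COUL,
                      cutoff=10.0, sites=sites)
        assert all(v == 0.0 for v in w.per_residue_w.values())

    def test_self_consistent_mean(self):
        """ΔG_res built as −3.33·S per residue gives mean W = −3.33."""
        c = GagComplex([], [bead(i, [5.2 * i, 0, 0]) for i in range(1, 4)])
        sites = [site([2, 0, 0]), site([7, 3, 0]), site([13, -2, 0], -1)]
        s_vals = {r.residue_number: electrostatic_sum(r, sites, COUL, 10.0)
                  for r in c.gag_chain}
        d = DecompositionTable({k: PEPTIDE_W * s for k, s in s_vals.items()})
        w = compute_w(c, d, COUL, cutoff=10.0, sites=sites)
        assert w.mean_w == pytest.approx(PEPTIDE_W)
        assert all(v == pytest.approx(PEPTIDE_W)
                   for v in w.per_residue_w.values())

    def test_residue_with_tiny_s_excluded(self, caplog):
        c = GagComplex([], [bead(1, [0, 0, 0]), bead(2, [5.2, 0, 0])])
        sites = [site([2, 0, 0])]
        d = DecompositionTable({1: -1.0, 2: -1.0})
        # cutoff 3 Å: site is 2 Å from residue 1 but 3.2 Å from residue 2,
        # leaving residue 2 with S = 0 → excluded
        w = compute_w(c, d, COUL, cutoff=3.0, sites=sites)
        assert set(w.per_residue_w) == {1}

    def test_all_excluded_errors(self):
        c = GagComplex([], [bead(1, [0, 0, 0]), bead(2, [5.2, 0, 0])])
        d = DecompositionTable({1: -1.0, 2: -1.0})
        with pytest.raises(ValueError, match="excluded"):
            compute_w(c, d, COUL, cutoff=10.0, sites=[])

    def test_sign_with_positive_sites_and_favorable_dg(self, peptide_complex):
        """Positively charged receptor + favorable ΔG_res ⇒ W < 0."""
        d = DecompositionTable({r.residue_number: -2.0
                                for r in peptide_complex.gag_chain})
        w = compute_w(peptide_complex, d, COUL, cutoff=12.0)
        assert w.mean_w < 0

    def test_rigid_invariance(self, peptide_complex):
        d = DecompositionTable({r.residue_number: -2.0
                                for r in peptide_complex.gag_chain})
        w0 = compute_w(peptide_complex, d, COUL, cutoff=12.0)
        rng = np.random.default_rng(2)
        rot, trans = rigid_transform(rng)
        moved = apply_rigid(peptide_complex, rot, trans)
        w1 = compute_w(moved, d, COUL, cutoff=12.0)
        assert w1.mean_w == pytest.approx(w0.mean_w, abs=1e-9)

    def test_coulomb_debye_converge_at_low_ionic_strength(self, peptide_complex):
        d = DecompositionTable({r.residue_number: -2.0
                                for r in peptide_complex.gag_chain})
        w_c = compute_w(peptide_complex, d, COUL, cutoff=12.0)
        w_d = compute_w(peptide_complex, d,
                        ElectrostaticsModel(kind="debye",
                                            ionic_strength=1e-14), cutoff=12.0)
        assert w_d.mean_w == pytest.approx(w_c.mean_w, rel=1e-6)


class TestPredict:
    def test_no_added_residues_identity(self, peptide_complex):
        got = predict_elongated_energy(-31.2, peptide_complex, [], PEPTIDE_W,
                                       COUL, 10.0)
        assert got == -31.2

    def test_known_s_arithmetic(self):
        """Two added beads with S = −1 each at W = −3.33 add +6.66."""
        c = GagComplex([], [bead(1, [0, 0, 0]), bead(2, [5.2, 0, 0])])
        # one negative site exactly 1 Å from each bead, cutoff keeps only it
        sites = [site([1, 0, 0], -1), site([6.2, 0, 0], -1)]
        got = predict_elongated_energy(-10.0, c, [1, 2], PEPTIDE_W, COUL,
                                       cutoff=1.01, sites=sites)
        assert got == pytest.approx(-10.0 + 6.66)

    def test_self_consistency_reproduces_summed_decomposition(self):
        """With equal per-residue W, predicting the complex's own residues
        from base 0 returns Σ ΔG_res."""
        c = GagComplex([], [bead(i, [5.2 * i, 0.5 * i, 0])
                            for i in range(1, 5)])
        sites = [site([3, 1, 0]), site([11, -1, 0]), site([18, 2, 0], -1)]
        d = DecompositionTable({
            r.residue_number: -3.33 * electrostatic_sum(r, sites, COUL, 12.0)
            for r in c.gag_chain})
        w = compute_w(c, d, COUL, cutoff=12.0, sites=sites)
        pred = predict_elongated_energy(
            0.0, c, [r.residue_number for r in c.gag_chain], w,
            COUL, 12.0, sites=sites)
        assert pred == pytest.approx(sum(d.entries.values()), rel=1e-9)

    def test_additive_over_disjoint_sets(self, peptide_complex, ff):
        elong = elongate(peptide_complex, ff, ElongationSpec(n_reducing=4))
        added = [r.residue_number for r in elong.gag_chain[-4:]]
        full = predict_elongated_energy(0.0, elong, added, PEPTIDE_W, COUL, 15.0)
        part = sum(predict_elongated_energy(0.0, elong, [a], PEPTIDE_W,
                                            COUL, 15.0) for a in added)
        assert full == pytest.approx(part, rel=1e-9)

    def test_unknown_added_residue_rejected(self, peptide_complex):
        with pytest.raises(ValueError, match="not in the elongated chain"):
            predict_elongated_energy(0.0, peptide_complex, [99], PEPTIDE_W,
                                     COUL, 10.0)


class TestDetectChargedSites:
    def test_gkgkg_two_positive_nz_sites(self, peptide_complex):
        sites = detect_charged_sites(peptide_complex.receptor_atoms)
        assert len(sites) == 2
        assert all(s.sign == 1 for s in sites)
        nz = [a for a in peptide_complex.receptor_atoms if a.name == "NZ"]
        for s, a in zip(sites, nz):
            np.testing.assert_array_equal(s.reference_point, a.position)

    def test_poly_gly_empty(self, dp6):
        from gagcg.synth import make_peptide_complex
        c = make_peptide_complex("GGGGG", dp6, 6.0)
        assert detect_charged_sites(c.receptor_atoms) == []

    def test_missing_nz_falls_back_to_side_chain_centroid(self, caplog):
        atoms = [
            AtomRecord(1, "N", "LYS", "P", 1, [0, 0, 0], "N"),
            AtomRecord(2, "CA", "LYS", "P", 1, [1.5, 0, 0], "C"),
            AtomRecord(3, "CB", "LYS", "P", 1, [2, 1, 0], "C"),
            AtomRecord(4, "CG", "LYS", "P", 1, [3, 2, 0], "C"),
        ]
        sites = detect_charged_sites(atoms)
        assert len(sites) == 1
        np.testing.assert_allclose(sites[0].reference_point, [2.5, 1.5, 0])

    def test_negative_residues_and_his_exclusion(self):
        atoms = [
            AtomRecord(1, "CA", "GLU", "P", 1, [0, 0, 0], "C"),
            AtomRecord(2, "CD", "GLU", "P", 1, [1, 0, 0], "C"),
            AtomRecord(3, "CA", "HIS", "P", 2, [5, 0, 0], "C"),
            AtomRecord(4, "CG", "ASP", "P", 3, [9, 0, 0], "C"),
        ]
        sites = detect_charged_sites(atoms)
        assert [(s.residue_id[1], s.sign) for s in sites] == [(1, -1), (3, -1)]
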
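# gagcg

Coarse-grained elongation of docked glycosaminoglycans (GAGs) and
W-factor extrapolation of protein–GAG binding free energies.

## The problem

Natural GAGs such as heparin (HP) are very long, linear, highly charged
polysaccharides, but docking and experimental structures almost always use
short oligomers (dp4–dp6, where dp counts monosaccharide units). Binding
energies computed from those short chains systematically underestimate the
binding of the physiologically relevant long chains — on the shipped
MM/GBSA benchmark, by 39% (dp4) and 24% (dp6) relative to dp16, averaged
over five receptor systems. This package implements a workflow that fixes
the length problem without re-docking or all-atom chain building:

1. **Single-pseudoatom CG model (Z1).** One bead per monosaccharide unit,
   charge −2 for fully sulfated HP (−1 per sulfate/carboxyl group), no
   glycosidic linkages between CG units. Bonded terms (3 bonds, 7 angles,
   15 torsions) were derived by Boltzmann inversion of all-atom MD at
   300 K; the set is written/read in AMBER frcmod format
   (`src/gagcg/data/z1.frcmod`) so LEaP can load it directly.
2. **Elongation.** A docked all-atom dp4/dp6 core keeps its pose; Z1 beads
   are appended at either terminus in an extended, clash-aware geometry
   (Z1–Z1 bond 5.2 Å, Z1-Z1-Z1 angle 160°, junction through the glycosidic
   oxygen at 2.8 Å). Alternatively, all-atom residues whose per-residue
   MM/GBSA contribution is weaker than −0.5 kcal/mol can be substituted by
   beads in place.
3. **Parameter derivation.** `boltzmann` turns conformational samples into
   CG parameters: U(x) = −k_B·T ln P(x), harmonic fits
   K = k_B·T/(2σ²) in the AMBER convention E = K(x−x₀)², torsion
   periodicity (1 or 3) from the number of PMF minima per 360°, amplitude
   PK = barrier/2.
4. **W factor.** For each GAG residue, W = ΔG_res / S with
   S = Σ₊ f(d) − Σ₋ f(d) over charged protein residues within a cutoff,
   f(d) = 1/d (Coulomb) or e^{−κd}/d (Debye–Hückel, 0.15 M ionic strength,
   Debye length ≈ 7.85 Å). The complex-level W (mean over residues)
   predicts the binding energy of any elongation as
   ΔG_pred = ΔG_base + W·Σ S(added residue). For small peptide receptors
   W ≈ −3.33 kcal mol⁻¹ e⁻¹ is universal (`gagcg.wfactor.PEPTIDE_W`);
   proteins need a system-specific W.

A self-contained energy evaluator (AMBER functional forms, 12-6 LJ with
Rmin/ε mixing, 332.0636 Coulomb constant, LIE score with α = β = 1 at
ε = 80) serves as the testing oracle in place of an MD engine, and a
synthetic-fixture generator (idealized GAG helices, model peptides such as
GLY-LYS-GLY-LYS-GLY, Boltzmann-distributed coordinate samples,
decomposition tables) makes the whole pipeline testable offline.

## Worked example

```sh
# synthetic GKGKG peptide docked alongside a dp6 GAG helix
gagcg synth --kind peptide_complex --sequence GKGKG --dp 6 --seed 1 --out complex.pdb
# elongate the GAG by 10 CG beads at the reducing end -> mixed dp16
gagcg elongate --pdb complex.pdb --gag-chain A --add-reducing 10 --out dp16.pdb
# per-residue decomposition fixture, then W factors
gagcg synth --kind decomposition --dp 6 --n-core 4 --seed 1 --out decomp.csv
gagcg wfactor --pdb complex.pdb --gag-chain A --decomp decomp.csv --cutoff 12
```

prints

```
residue    1  W    -0.7517 kcal/mol/e
residue    2  W    -8.0277 kcal/mol/e
residue    3  W    -4.2541 kcal/mol/e
residue    4  W    -5.4334 kcal/mol/e
residue    5  W    -7.2219 kcal/mol/e
residue    6  W    -0.7714 kcal/mol/e
mean W (coulomb): -4.4100 kcal/mol/e
```

Each line is one GAG residue's decomposed binding energy divided by its
signed reciprocal-distance sum to the two lysine NZ charges; the mean is
the complex-level W. Predicting the dp16 energy from the dp6 one with the
universal peptide W:

```sh
gagcg predict --pdb dp16.pdb --gag-chain A --base-energy -27.1 \
    --added-residues 7,8,9,10,11,12,13,14,15,16 --w-peptide --cutoff 12
predicted binding energy: -27.3829 kcal/mol
```

The added beads sit far from the two charges in this synthetic pose, so
the correction is small (−0.28 kcal/mol). The benchmark statistics:

```sh
gagcg benchstats --table length
dp4   underestimation vs dp16: 39%
dp6   underestimation vs dp16: 24%
dp10  underestimation vs dp16: 8%
```

## Scope

The package does not run MD, compute MM/PBSA / MM/GBSA solvation terms, or
generate LEaP topologies; it prepares mixed AA/CG structures and parameter
files for AMBER and post-processes decomposition output. The benchmark
tables ship as data because regenerating them requires AMBER MD on the
original complexes. See `docs/methods.md` for model details, numerical
choices and limitations.
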
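# Methods

## The Z1 coarse-grained model

The model collapses one GAG monosaccharide unit into a single pseudoatom
(atom type `Z1`, atom name `Z1`, residue name `ZCG`). It is intentionally
nonspecific: the bead carries only a point charge (default −2 e, the fully
sulfated heparin unit; the general rule is −1 e per sulfate or carboxyl
group, overridable per bead) and a soft 12-6 sphere (RvdW 4 Å, well depth
3.4 kcal/mol, mass 225 au). Glycosidic linkages are not represented
between CG units; chain connectivity is maintained purely by the bonded
terms:

| term | K / PK | equilibrium / PN |
|---|---|---|
| Z1-Z1, Z1-Cg bonds | 120 kcal mol⁻¹ Å⁻² | 5.2 Å |
| Os-Z1 junction bond | 120 kcal mol⁻¹ Å⁻² | 2.8 Å |
| backbone angles (Z1-Z1-Z1 class) | 100 kcal mol⁻¹ rad⁻² | 160° |
| junction angles (Z1-Cg-\* class) | 60–70 kcal mol⁻¹ rad⁻² | 108.5–110° |
| backbone torsion Z1-Z1-Z1-Z1 | PK 1.0, phase 0° | PN 1 |
| junction torsions | PK ±0.16…±1.3, phase 0° | PN 1 or 3 |

The five junction types `Cg`, `Os`, `H1`, `H2`, `Ng` belong to GLYCAM and
are referenced, never re-parameterized. Negative PK values are written to
frcmod verbatim (AMBER's reader accepts them; they are equivalent to a
positive PK with the phase shifted by 180°). The model is meant for GAG
segments that do **not** contact the receptor, where interactions are
essentially electrostatic; it under-represents van der Waals detail and
stiffens the chain relative to all-atom heparin.

## Elongation geometry

The published workflow added beads manually in LEaP and relied on MD to
relax them; this package replaces that with a deterministic rule so that
results are reproducible before any simulation. Beads propagate along the
unit vector from the penultimate to the terminal residue centroid. The
first bead bonds through the terminal residue's glycosidic oxygen at the
Os-Z1 equilibrium distance (2.8 Å) when that oxygen exists, otherwise from
the ring centroid at 5.2 Å. Each further bead is placed at 5.2 Å forming
the 160° equilibrium angle, in the plane of the previous bond
(trans-extended). If a bead lands within `clash_distance` (default 4 Å) of
any receptor atom, the position is rotated about the previous bond axis in
15° steps and the first clash-free pose is kept; a full-circle failure is
an error rather than a silent overlap. Pre-existing atoms are never
modified, so the docked pose is preserved bitwise.

Energy-based substitution uses the strict rule ΔG_res > threshold
(default −0.5 kcal/mol) — a residue contributing exactly the threshold
stays all-atom. The replacement bead sits at the residue's pyranose ring
centroid (C1–C5 + O5 when present, otherwise all atoms) and inherits the
residue's unit charge. The operation is idempotent.

Chain direction follows ascending residue number
(non-reducing → reducing); a flag reverses it, since PDB numbering
conventions vary. Added beads continue the numbering outward at both
termini (which may produce numbers ≤ 0 at the non-reducing end; the
mapping is the identity on the original core).

## Boltzmann inversion

PMFs are plain histogram inversions U(x) = −k_B·T ln(P(x)/P_max) with the
minimum pinned at 0 and empty bins undefined; no Jacobian correction
(r², sin θ) is applied by default because the parameters were originally
derived from plain distributions — a flag enables the correction. Harmonic
fits use the closed form of the Boltzmann-distributed oscillator:
equilibrium = sample mean (circular mean for torsions), K = k_B·T/(2·var),
with K in the AMBER convention E = K(x−x₀)² (the ½ is absorbed). Angle
variances are converted to rad².

Torsion classification smooths the periodic PMF with a 3-bin moving
average (72 bins over 360° by default), counts minima deeper than k_B·T/4
relative to their separating barrier, and accepts only 1 or 3 minima —
the two periodicities present in the parameter set; 2 or ≥4 raise an
error rather than guessing. PK is half the height of the highest barrier
separating the global minimum from the local minima (half the full
amplitude for a single well), matching the convention in which PK is the
barrier divided by two. The phase snaps to 0° or 180° so the cosine
minimum coincides with the PMF minimum. A flat profile (amplitude below
k_B·T/4) returns PK ≈ 0, PN = 1 with a warning. Temperature defaults to
300 K (the MD temperature behind the shipped parameters) and is
configurable.

Recovery performance under the defaults (10⁶ samples per term, measured by
`scripts/acceptance.py`): equilibria within ~0.01%, force constants within
~0.3%, torsion periodicity always exact and PK within ~2% for both the
PK = 1/PN = 1 and PK = 0.16/PN = 3 classes — comfortably inside the 1% /
5% / 20% acceptance bands.

## Energy evaluation

AMBER functional forms: E_bond = Σ RK(r−REQ)², E_angle = Σ TK(θ−TEQ)²
(θ in radians), E_torsion = Σ (PK/IDIVF)(1+cos(PN·φ−phase)), 12-6 LJ
E = ε[(Rmin/r)¹² − 2(Rmin/r)⁶] with Rmin_ij = RvdW_i + RvdW_j and
ε_ij = √(ε_i ε_j), Coulomb E = 332.0636·q_iq_j/(ε_r·r). Only CG-involving
bonded terms are evaluated (all-atom internals belong to GLYCAM and to
AMBER itself); atoms without an LJ entry in the CG set are LJ-inert
(ε = 0). Torsion windows that span deep all-atom context without a
matching parameter are skipped; an unparameterized CG bond or angle is an
error. The vectorized evaluator is validated against an all-pairs Python
reference to ~1e−15 relative.

Debye–Hückel screening multiplies each Coulomb term by e^{−κr} with
κ⁻¹[Å] = 3.04/√I (room-temperature aqueous solvent constants; I in
mol/L), giving κ⁻¹ ≈ 7.85 Å at the physiological default 0.15 M. The LIE
score is α·E_vdW + β·E_elec over all receptor–GAG pairs with α = β = 1,
ε_r = 80 and no cutoff (whether the original analysis used a cutoff is
not documented; no cutoff is the conservative choice and the option
exists).

## W factors

W_res = ΔG_res / S with S = Σ_positive f(d) − Σ_negative f(d), distances
measured from the GAG residue centroid to a fixed reference atom per
charged receptor residue (Lys NZ, Arg CZ, Asp CG, Glu CD; side-chain
centroid, then Cα as fallbacks). Histidine is excluded by default and
termini are optional, both switchable. Default cutoff 10 Å, standing in
for the nonbonded cutoff of the MD the decomposition came from. Residues
with |S| < 1e−6 are excluded from the mean with a warning. The sign
convention (positive minus negative sums) is the literal reading of the
defining sum and is exposed as a switch, because the published
Debye-variant W values carry the opposite sign from the Coulomb ones and
the two cannot be reconciled from the available description.

The prediction identity ΔG_pred = ΔG_base + mean_W·Σ S is exact when all
per-residue W are equal (the self-consistency case exercised in the
tests); for real systems it is an approximation whose error grows with
the spread of the per-residue W distribution — tight for small peptides,
broad for proteins, which is why protein receptors need a per-system W
from their own simulations.

## Synthetic fixtures

The generator provides what the real workflow would get from docking, MD
and MM/GBSA: (i) idealized GAG helices (4.5 Å rise, 180° turn per unit,
1.5 Å helix radius — a caricature of heparin's ~4-fold helix chosen once
as a fixture, not a structural claim), with either full pyranose rings +
glycosidic O1 or single centroid particles; (ii) extended model peptides
(e.g. GLY-LYS-GLY-LYS-GLY) laid parallel to the GAG with charged side
chains pointing at it; (iii) exact Gaussian samples for harmonic terms
and many-walker Metropolis samples (1000 walkers, 500-step burn-in,
1 rad proposals) for torsion Boltzmann distributions; (iv) core/tail
decomposition tables. Everything is seed-deterministic. What passing
tests on these fixtures shows is that the algorithms are implemented
correctly; they say nothing about docking accuracy, ring puckering,
solvation or conformational sampling of real complexes.

## Benchmark tables and reported statistics

The three MM/PBSA / MM/GBSA tables ship as CSV fixtures; regenerating
them would require AMBER MD on the original complexes. Correlations are
computed over all 10 rows of the AA-vs-CG table (the 2NWG complex has two
binding sites and contributes two independent points — the convention
that exactly reproduces the published Spearman coefficients). The
length-underestimation statistic is the mean over the five systems of
100·(|G_dp16|−|G_dp|)/|G_dp16|, with per-system percentages carried at
the table's printed precision (one decimal) and the mean rounded half
away from zero; the InLys dp6 entry uses the value excluding the
dissociated replica (the alternative is kept as a named constant).
Mixed-model agreement is 100·|G_AA−G_mixed|/|G_AA| per system, rounded to
integer percent. The recomputed InLys elongated-CG difference rounds to
0% and is therefore not asserted anywhere.

## Problem sizes and numerical defaults

Parameter-recovery runs use 10⁶ samples per term with 72 histogram bins;
the oracle comparison uses a 500-atom system; elongation demonstrations
use dp6 → dp16 with 10 beads. PDB coordinates carry the format's native
3-decimal precision, so structure round-trips are exact to 5e−4 Å.
Energies are float64 throughout; rigid-body invariance holds to ~1e−9
kcal/mol on the test systems.

## Known limitations

- The CG chain is stiffer and less detailed than all-atom GAGs; energies
  involving CG beads are meaningful for electrostatics-dominated lateral
  segments only.
- No minimization or MD is performed after bead placement; downstream
  relaxation is the caller's responsibility.
- The frcmod writer targets the whitespace-tolerant dialect AMBER's
  parsers accept, not byte-identical layout to files produced by other
  tools.
- Mapping of the GLYCAM junction hydrogens H1/H2 at the AA/CG boundary is
  inherited from the structure's atom naming and is not validated
  chemically.
- The Debye-variant W sign convention is a documented open choice, not a
  derived fact.
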
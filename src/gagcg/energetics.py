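"""Potential-energy evaluator for the CG/mixed GAG model.

AMBER functional forms throughout: harmonic bonds/angles, cosine torsions,
12-6 Lennard-Jones in the Rmin/ε convention with Rmin_ij = RvdW_i + RvdW_j
and ε_ij = √(ε_i ε_j), and Coulomb electrostatics with the 332.0636
kcal Å mol⁻¹ e⁻² prefactor, optionally Debye–Hückel screened.  Atom types
without an LJ entry in the CG parameter set are LJ-inert (ε = 0): the
evaluator exists to exercise the new CG terms and intermolecular
electrostatics, not to replace GLYCAM/ff14SB.

Also provides a LIE-style interaction score α·E_vdW + β·E_elec with
uncalibrated weights (α = β = 1) and a dielectric of 80.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import COULOMB_KCAL, DEFAULT_TEMPERATURE, debye_length
from .elongate import BondedTerm, build_topology
from .forcefield import PseudoatomForceField
from .structures import AtomRecord, GagComplex
from .boltzmann import angle_deg, dihedral_deg


@dataclass
class EnergyBreakdown:
    bond: float = 0.0
    angle: float = 0.0
    dihedral: float = 0.0
    lj: float = 0.0
    coulomb: float = 0.0

    @property
    def total(self) -> float:
        return self.bond + self.angle + self.dihedral + self.lj + self.coulomb

    def __add__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(self.bond + other.bond,
                               self.angle + other.angle,
                               self.dihedral + other.dihedral,
                               self.lj + other.lj,
                               self.coulomb + other.coulomb)


@dataclass
class ElectrostaticsModel:
    """Coulomb or Debye–Hückel screened electrostatics.

    kind: ``coulomb`` or ``debye``; *dielectric* defaults to 1 (vacuum,
    pass 80 for LIE-style solvent screening); *ionic_strength* in mol/L is
    used by the debye kind only (0.15 M physiological default, Debye
    length ≈ 7.85 Å).
    """

    kind: str = "coulomb"
    dielectric: float = 1.0
    ionic_strength: float = 0.15
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.kind not in ("coulomb", "debye"):
            raise ValueError(f"unknown electrostatics kind {self.kind!r}")
        if self.dielectric <= 0:
            raise ValueError("dielectric must be positive")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be >= 0")

    @property
    def kappa(self) -> float:
        """Inverse Debye length, Å⁻¹ (0 for the coulomb kind)."""
        if self.kind == "coulomb":
            return 0.0
        lam = debye_length(self.ionic_strength)
        return 0.0 if math.isinf(lam) else 1.0 / lam

    def screening(self, r: np.ndarray) -> np.ndarray:
        k = self.kappa
        return np.exp(-k * r) if k else np.ones_like(r)


def bonded_energy(c: GagComplex, topology: Sequence[BondedTerm] | None,
                  ff: PseudoatomForceField) -> EnergyBreakdown:
    """Sum the CG-involving bonded terms of a mixed complex.

    E_bond = Σ RK (r − REQ)²; E_angle = Σ TK (θ − TEQ)² with θ in radians;
    E_dihedral = Σ (PK/IDIVF)(1 + cos(PN φ − phase)).
    """
    if topology is None:
        topology = build_topology(c, ff)
    out = EnergyBreakdown()
    for term in topology:
        pts = [a.position for a in term.atoms]
        p = term.param
        if term.kind == "bond":
            r = float(np.linalg.norm(pts[1] - pts[0]))
            out.bond += p.RK * (r - p.REQ) ** 2
        elif term.kind == "angle":
            th = math.radians(angle_deg(*pts))
            out.angle += p.TK * (th - math.radians(p.TEQ)) ** 2
        else:
            phi = math.radians(dihedral_deg(*pts))
            out.dihedral += (p.PK / p.IDIVF) * (
                1.0 + math.cos(p.PN * phi - math.radians(p.phase)))
    return out


def _lj_params(atoms: Sequence[AtomRecord],
               ff: PseudoatomForceField) -> tuple[np.ndarray, np.ndarray]:
    rmin2 = np.zeros(len(atoms))
    eps = np.zeros(len(atoms))
    for i, a in enumerate(atoms):
        if ff.has_lj(a.name):
            p = ff.lj_param(a.name)
            rmin2[i], eps[i] = p.RvdW, p.EDEP
    return rmin2, eps


def pair_energy(atoms_a: Sequence[AtomRecord], atoms_b: Sequence[AtomRecord],
                ff: PseudoatomForceField, es: ElectrostaticsModel,
                cutoff: float | None = None) -> EnergyBreakdown:
    """Nonbonded interaction energy between two disjoint atom sets.

    LJ: Σ ε_ij[(Rmin_ij/r)¹² − 2(Rmin_ij/r)⁶]; Coulomb:
    Σ 332.0636 q_i q_j/(ε_r r), multiplied by exp(−κr) for the debye kind.
    Pairs beyond *cutoff* (if given) are excluded.
    """
    if not atoms_a or not atoms_b:
        return EnergyBreakdown()
    pa = np.array([a.position for a in atoms_a])
    pb = np.array([b.position for b in atoms_b])
    qa = np.array([a.charge or 0.0 for a in atoms_a])
    qb = np.array([b.charge or 0.0 for b in atoms_b])
    ra, ea = _lj_params(atoms_a, ff)
    rb, eb = _lj_params(atoms_b, ff)

    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    if np.any(d == 0):
        raise ValueError("coincident atoms (r = 0) between the two sets")
    mask = np.ones_like(d, bool) if cutoff is None else d <= cutoff

    rmin = ra[:, None] + rb[None, :]
    eps = np.sqrt(ea[:, None] * eb[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio6 = np.where(rmin > 0, (rmin / d) ** 6, 0.0)
    lj = float(np.sum((eps * (ratio6**2 - 2 * ratio6))[mask]))

    coul_terms = COULOMB_KCAL * qa[:, None] * qb[None, :] / (es.dielectric * d)
    coul_terms = coul_terms * es.screening(d)
    coulomb = float(np.sum(coul_terms[mask]))
    return EnergyBreakdown(lj=lj, coulomb=coulomb)


def pair_energy_brute(atoms_a, atoms_b, ff, es, cutoff=None) -> EnergyBreakdown:
    """All-pairs python-loop reference implementation of :func:`pair_energy`."""
    out = EnergyBreakdown()
    for a in atoms_a:
        for b in atoms_b:
            r = float(np.linalg.norm(a.position - b.position))
            if r == 0:
                raise ValueError("coincident atoms")
            if cutoff is not None and r > cutoff:
                continue
            if ff.has_lj(a.name) and ff.has_lj(b.name):
                pa, pb = ff.lj_param(a.name), ff.lj_param(b.name)
                rmin = pa.RvdW + pb.RvdW
                eps = math.sqrt(pa.EDEP * pb.EDEP)
                out.lj += eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
            qa, qb = a.charge or 0.0, b.charge or 0.0
            if qa and qb:
                term = COULOMB_KCAL * qa * qb / (es.dielectric * r)
                if es.kappa:
                    term *= math.exp(-es.kappa * r)
                out.coulomb += term
    return out


def lie_energy(c: GagComplex, ff: PseudoatomForceField,
               alpha: float = 1.0, beta: float = 1.0,
               dielectric: float = 80.0) -> float:
    """LIE-style receptor↔GAG interaction score, kcal/mol.

    α·E_vdW + β·E_elec with a solvent-screening dielectric of 80 and
    uncalibrated weights α = β = 1; no cutoff.
    """
    if not c.receptor_atoms:
        raise ValueError("receptor is empty")
    if alpha == 0 and beta == 0:
        return 0.0
    es = ElectrostaticsModel(kind="coulomb", dielectric=dielectric)
    e = pair_energy(c.receptor_atoms, c.gag_atoms, ff, es, cutoff=None)
    return alpha * e.lj + beta * e.coulomb
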
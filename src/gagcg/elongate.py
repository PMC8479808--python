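"""Elongate a docked all-atom GAG with Z1 pseudoatoms.

Two routes to a mixed AA/CG chain:

* :func:`elongate` appends/prepends CG beads to either terminus of the
  docked oligomer in an extended, clash-aware geometry (downstream MD is
  expected to relax it);
* :func:`substitute_by_energy` replaces all-atom residues whose per-residue
  MM/GBSA contribution is weaker than a threshold (−0.5 kcal/mol by
  default) with beads at their ring centroids.

:func:`build_topology` enumerates every CG-involving bonded term of the
resulting chain and resolves it against the Z1 parameter set; AA-internal
terms are owned by GLYCAM and out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np

from .forcefield import DEFAULT_BEAD_CHARGE, PseudoatomForceField
from .structures import (AtomClass, AtomRecord, BEAD_ATOM_NAME,
                         BEAD_RESIDUE_NAME, GagComplex, GagResidue,
                         Representation)

logger = logging.getLogger(__name__)

DEFAULT_ENERGY_THRESHOLD = -0.5  # kcal/mol, per-residue contribution
DEFAULT_CLASH_DISTANCE = 4.0  # Å
CLASH_SCAN_STEP_DEG = 15.0

BEAD_BOND_LENGTH = 5.2  # Å, REQ(Z1-Z1) and REQ(Z1-Cg)
JUNCTION_O_BOND_LENGTH = 2.8  # Å, REQ(Os-Z1)
BEAD_ANGLE_DEG = 160.0  # TEQ(Z1-Z1-Z1)


@dataclass
class ElongationSpec:
    """How many beads to add at each terminus and with what charge."""

    n_nonreducing: int = 0
    n_reducing: int = 0
    bead_charge: float = DEFAULT_BEAD_CHARGE
    clash_distance: float = DEFAULT_CLASH_DISTANCE

    def __post_init__(self) -> None:
        if self.n_nonreducing < 0 or self.n_reducing < 0:
            raise ValueError("bead counts must be >= 0")


@dataclass
class DecompositionTable:
    """Per-residue binding free-energy contributions, kcal/mol."""

    entries: dict[int, float]

    @classmethod
    def from_csv(cls, source: Union[str, Path]) -> "DecompositionTable":
        """Read a two-column ``residue,dg`` CSV (header required)."""
        import pandas as pd

        df = pd.read_csv(source)
        cols = {c.lower().strip(): c for c in df.columns}
        if "residue" not in cols or "dg" not in cols:
            raise ValueError("decomposition CSV needs columns 'residue' and 'dg'")
        return cls({int(r): float(g) for r, g in
                    zip(df[cols["residue"]], df[cols["dg"]])})


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction vector")
    return v / n


def _any_perpendicular(u: np.ndarray) -> np.ndarray:
    """Deterministic unit vector perpendicular to u."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(u, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(u, ref))


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of v about unit axis."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c)


def _place_with_angle(p_prev: np.ndarray, p_last: np.ndarray,
                      bond: float, angle_deg: float) -> np.ndarray:
    """Next point at *bond* from p_last making *angle_deg* at p_last,
    staying in the plane spanned by the previous bond (trans-like)."""
    u = _unit(p_last - p_prev)
    perp = _any_perpendicular(u)
    theta = np.radians(180.0 - angle_deg)  # deviation from straight-on
    d = u * np.cos(theta) + perp * np.sin(theta)
    return p_last + bond * d


def _clash_free(pos: np.ndarray, receptor: Iterable[AtomRecord],
                cutoff: float) -> bool:
    for a in receptor:
        if np.linalg.norm(a.position - pos) < cutoff:
            return False
    return True


def _resolve_clash(pos: np.ndarray, axis_origin: np.ndarray,
                   axis_dir: np.ndarray, receptor: list[AtomRecord],
                   cutoff: float) -> np.ndarray:
    """Rotate *pos* about the previous bond axis in 15° steps until
    clash-free; raise if the full circle fails."""
    if _clash_free(pos, receptor, cutoff):
        return pos
    rel = pos - axis_origin
    for k in range(1, int(360 / CLASH_SCAN_STEP_DEG)):
        ang = np.radians(CLASH_SCAN_STEP_DEG * k)
        cand = axis_origin + _rotate_about(rel, axis_dir, ang)
        if _clash_free(cand, receptor, cutoff):
            logger.info("bead placement rotated %.0f° to avoid receptor clash",
                        np.degrees(ang))
            return cand
    raise ValueError("no clash-free bead placement found in a full 360° scan; "
                     f"receptor is within {cutoff} Å in every orientation")


def _make_bead(residue_number: int, chain_id: str, position: np.ndarray,
               charge: float) -> GagResidue:
    atom = AtomRecord(serial=0, name=BEAD_ATOM_NAME,
                      residue_name=BEAD_RESIDUE_NAME, chain_id=chain_id,
                      residue_number=residue_number, position=position,
                      element="C", charge=charge,
                      atom_class=AtomClass.CG_BEAD)
    return GagResidue(residue_number, Representation.CG, [atom],
                      unit_charge=charge)


def elongate(c: GagComplex, ff: PseudoatomForceField,
             spec: ElongationSpec) -> GagComplex:
    """Extend the GAG chain with CG beads at the requested termini.

    The first bead bonds to the terminal residue through its glycosidic
    oxygen when present (Os-Z1 equilibrium distance) or from the ring
    centroid (Z1-Cg distance); subsequent beads continue at the Z1-Z1
    equilibrium distance with the Z1-Z1-Z1 equilibrium angle in an
    extended geometry.  Propagation follows the unit vector from the
    penultimate to the terminal residue centroid.  Placements clashing
    with the receptor are rotated about the previous bond axis in 15°
    steps.  Pre-existing atoms are never moved.
    """
    if spec.n_nonreducing == 0 and spec.n_reducing == 0:
        return c.copy()
    if len(c.gag_chain) < 2:
        raise ValueError("GAG chain needs >= 2 residues to define an "
                         "elongation direction")
    bond_zz = ff.bond(("Z1", "Z1")).REQ
    bond_os = ff.bond(("Os", "Z1")).REQ
    bond_cg = ff.bond(("Z1", "Cg")).REQ
    angle_eq = ff.angle(("Z1", "Z1", "Z1")).TEQ

    out = c.copy()

    def grow(residues: list[GagResidue], n: int, numbers: list[int]) -> list[GagResidue]:
        """Append n beads at the end of *residues* (chain-order tail)."""
        added: list[GagResidue] = []
        for k in range(n):
            term = residues[-1]
            prev_cent = residues[-2].ring_centroid
            term_cent = term.ring_centroid
            direction = _unit(term_cent - prev_cent)
            if k == 0 and term.representation is Representation.AA:
                if term.glycosidic_oxygen is not None:
                    origin = term.glycosidic_oxygen.position
                    pos = origin + bond_os * direction
                else:
                    origin = term_cent
                    pos = origin + bond_cg * direction
                axis_origin, axis_dir = origin, direction
            else:
                pos = _place_with_angle(prev_cent, term_cent, bond_zz, angle_eq)
                axis_origin, axis_dir = term_cent, _unit(term_cent - prev_cent)
            pos = _resolve_clash(pos, axis_origin, axis_dir,
                                 out.receptor_atoms, spec.clash_distance)
            bead = _make_bead(numbers[k], c.chain_id, pos, spec.bead_charge)
            residues.append(bead)
            added.append(bead)
        return added

    if spec.n_reducing:
        nums = [out.gag_chain[-1].residue_number + i + 1
                for i in range(spec.n_reducing)]
        grow(out.gag_chain, spec.n_reducing, nums)
    if spec.n_nonreducing:
        nums = [out.gag_chain[0].residue_number - i - 1
                for i in range(spec.n_nonreducing)]
        rev = out.gag_chain[::-1]
        grow(rev, spec.n_nonreducing, nums)
        out.gag_chain = rev[::-1]
    return out


def substitute_by_energy(c: GagComplex, d: DecompositionTable,
                         threshold: float = DEFAULT_ENERGY_THRESHOLD,
                         ) -> GagComplex:
    """Replace weak all-atom GAG residues with CG beads.

    Any all-atom residue whose decomposed contribution is strictly less
    favorable than *threshold* (ΔG_res > threshold) becomes one bead at its
    ring centroid, keeping the residue's unit charge.  Residues at or below
    the threshold are untouched.  Idempotent.
    """
    missing = [r.residue_number for r in c.gag_chain
               if r.representation is Representation.AA
               and r.residue_number not in d.entries]
    if missing:
        raise ValueError("decomposition table missing residues "
                         f"{missing}")
    out = c.copy()
    new_chain: list[GagResidue] = []
    for res in out.gag_chain:
        if (res.representation is Representation.AA
                and d.entries[res.residue_number] > threshold):
            new_chain.append(_make_bead(res.residue_number, c.chain_id,
                                        res.ring_centroid.copy(),
                                        res.unit_charge))
        else:
            new_chain.append(res)
    out.gag_chain = new_chain
    return out


#: generic bonded term: (kind, type tuple, atom records, parameter)
@dataclass
class BondedTerm:
    kind: str  # bond | angle | dihedral
    types: tuple[str, ...]
    atoms: tuple[AtomRecord, ...]
    param: object


def _junction_sites(res: GagResidue) -> list[tuple[str, AtomRecord]]:
    """Typed sites an AA residue contributes to the CG bonded path:
    a ring carbon (Cg) and, when present, the glycosidic oxygen (Os)."""
    by_name = {a.name: a for a in res.atoms}
    sites: list[tuple[str, AtomRecord]] = []
    carbon = by_name.get("C1") or by_name.get("C4")
    if carbon is None:
        carbon = next((a for a in res.atoms if a.name.startswith("C")), None)
    if carbon is not None:
        sites.append(("Cg", carbon))
    if res.glycosidic_oxygen is not None:
        sites.append(("Os", res.glycosidic_oxygen))
    return sites


def build_topology(c: GagComplex, ff: PseudoatomForceField) -> list[BondedTerm]:
    """Enumerate CG-involving bonded terms along the GAG chain.

    The chain is reduced to a linear path of typed sites: each CG residue
    contributes one Z1 site; an AA residue adjacent to beads contributes
    its ring carbon (Cg) and glycosidic oxygen (Os).  Bonds, angles and
    dihedrals are taken over consecutive sites, kept when they involve at
    least one Z1 and a matching parameter exists; a Z1-involving bond or
    angle with no parameter is an error (dihedrals across deep AA context
    are skipped, since their full GLYCAM typing is outside this model).
    """
    if not any(r.representation is Representation.CG for r in c.gag_chain):
        raise ValueError("complex contains no CG bead")
    sites: list[tuple[str, AtomRecord]] = []
    for i, res in enumerate(c.gag_chain):
        if res.representation is Representation.CG:
            sites.append(("Z1", res.atoms[0]))
        else:
            prev_cg = (i > 0 and
                       c.gag_chain[i - 1].representation is Representation.CG)
            next_cg = (i + 1 < len(c.gag_chain) and
                       c.gag_chain[i + 1].representation is Representation.CG)
            junction = _junction_sites(res)  # [Cg, Os?] toward the beads
            if prev_cg and next_cg:
                sites.append(("Cg", junction[0][1]) if junction
                             else ("BREAK", None))
            elif next_cg:
                sites.append(("BREAK", None))
                sites.extend(junction)
            elif prev_cg:
                sites.extend(junction[::-1])
                sites.append(("BREAK", None))
            else:
                sites.append(("BREAK", None))

    terms: list[BondedTerm] = []

    def windows(k: int):
        for j in range(len(sites) - k + 1):
            w = sites[j:j + k]
            if any(t == "BREAK" for t, _ in w):
                continue
            if not any(t == "Z1" for t, _ in w):
                continue
            yield tuple(t for t, _ in w), tuple(a for _, a in w)

    for types, atoms in windows(2):
        try:
            terms.append(BondedTerm("bond", types, atoms, ff.bond(types)))
        except KeyError as exc:
            raise ValueError(str(exc)) from exc
    for types, atoms in windows(3):
        try:
            terms.append(BondedTerm("angle", types, atoms, ff.angle(types)))
        except KeyError as exc:
            raise ValueError(str(exc)) from exc
    for types, atoms in windows(4):
        try:
            terms.append(BondedTerm("dihedral", types, atoms,
                                    ff.dihedral(types)))
        except KeyError:
            logger.debug("skipping unparameterized dihedral %s",
                         "-".join(types))
    return terms
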
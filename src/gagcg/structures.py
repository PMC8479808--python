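"""Receptor–GAG complex model and PDB I/O.

A :class:`GagComplex` holds the receptor atoms plus an ordered GAG chain
(non-reducing → reducing end, taken as ascending residue number) whose
residues are either all-atom monosaccharides or single Z1 pseudoatoms.
Parsing and serialization go through gemmi; CG beads follow the convention
atom name ``Z1``, residue name ``ZCG``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import IO, Union

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

BEAD_ATOM_NAME = "Z1"
BEAD_RESIDUE_NAME = "ZCG"

#: pyranose ring atoms used for centroid computation when present
RING_ATOM_NAMES = ("C1", "C2", "C3", "C4", "C5", "O5")

#: candidate glycosidic-oxygen names, in preference order (GLYCAM dialects
#: link through O1/O4 most commonly, O2/O3/O6 in branched/unusual linkages)
GLYCOSIDIC_O_NAMES = ("O1", "O4", "O2", "O3", "O6")

#: consecutive GAG residue centroids must lie within this distance, Å
MAX_CONSECUTIVE_CENTROID_DIST = 8.0


class AtomClass(Enum):
    AA = "AA"
    CG_BEAD = "CG_BEAD"


class Representation(Enum):
    AA = "AA"
    CG = "CG"


@dataclass
class AtomRecord:
    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_number: int
    position: np.ndarray  # (3,) Å
    element: str = ""
    charge: float | None = None  # elementary charges
    atom_class: AtomClass = AtomClass.AA

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if self.atom_class is AtomClass.CG_BEAD and self.name != BEAD_ATOM_NAME:
            raise ValueError("CG bead atoms must be named " + BEAD_ATOM_NAME)

    def copy(self) -> "AtomRecord":
        return replace(self, position=self.position.copy())


@dataclass
class GagResidue:
    """One GAG unit: either an all-atom monosaccharide or one CG bead."""

    residue_number: int
    representation: Representation
    atoms: list[AtomRecord]
    unit_charge: float = -2.0
    glycosidic_oxygen: AtomRecord | None = None

    def __post_init__(self) -> None:
        if self.representation is Representation.CG and len(self.atoms) != 1:
            raise ValueError("CG residues must contain exactly one atom")
        if self.unit_charge > 0:
            raise ValueError("GAG unit charge must be <= 0")

    @property
    def ring_centroid(self) -> np.ndarray:
        """Centroid of the pyranose ring atoms (all atoms as fallback);
        for a CG residue, the bead position itself."""
        if self.representation is Representation.CG:
            return self.atoms[0].position
        ring = [a.position for a in self.atoms if a.name in RING_ATOM_NAMES]
        pts = ring if len(ring) == len(RING_ATOM_NAMES) else [a.position for a in self.atoms]
        return np.mean(pts, axis=0)

    def copy(self) -> "GagResidue":
        atoms = [a.copy() for a in self.atoms]
        gly = None
        if self.glycosidic_oxygen is not None:
            idx = self.atoms.index(self.glycosidic_oxygen)
            gly = atoms[idx]
        return GagResidue(self.residue_number, self.representation, atoms,
                          self.unit_charge, gly)


@dataclass
class GagComplex:
    receptor_atoms: list[AtomRecord]
    gag_chain: list[GagResidue]
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if not self.gag_chain:
            raise ValueError("GAG chain must be non-empty")
        cents = [r.ring_centroid for r in self.gag_chain]
        for i in range(len(cents) - 1):
            d = float(np.linalg.norm(cents[i + 1] - cents[i]))
            if d > MAX_CONSECUTIVE_CENTROID_DIST:
                logger.warning(
                    "GAG residues %d and %d are %.1f Å apart (> %.0f Å); "
                    "chain may be discontinuous",
                    self.gag_chain[i].residue_number,
                    self.gag_chain[i + 1].residue_number, d,
                    MAX_CONSECUTIVE_CENTROID_DIST)

    @property
    def gag_atoms(self) -> list[AtomRecord]:
        return [a for r in self.gag_chain for a in r.atoms]

    @property
    def total_gag_charge(self) -> float:
        return sum(r.unit_charge for r in self.gag_chain)

    def copy(self) -> "GagComplex":
        return GagComplex([a.copy() for a in self.receptor_atoms],
                          [r.copy() for r in self.gag_chain], self.chain_id)


def residue_centroids(c: GagComplex) -> list[np.ndarray]:
    """One centroid per GAG residue in chain order (bead position for CG)."""
    return [r.ring_centroid for r in c.gag_chain]


def _atoms_from_gemmi(st: gemmi.Structure, model: gemmi.Model):
    serial = 0
    for chain in model:
        for res in chain:
            for atom in res:
                serial += 1
                yield chain.name, res, atom, serial


def _source_to_structure(source: Union[str, Path, IO[str]]) -> gemmi.Structure:
    if hasattr(source, "read"):
        text = source.read()
    else:
        s = str(source)
        if "\n" not in s and Path(s).is_file():
            text = Path(s).read_text()
        else:
            text = s
    st = gemmi.read_pdb_string(text)
    return st


def read_complex(pdb_source: Union[str, Path, IO[str]],
                 gag_chain_id: str,
                 reverse_chain: bool = False) -> GagComplex:
    """Parse a PDB file/text into a :class:`GagComplex`.

    All chains except *gag_chain_id* become the receptor.  GAG residues are
    ordered by ascending residue number (non-reducing → reducing end;
    *reverse_chain* flips the convention).  Atoms named ``Z1`` are
    classified as CG beads; everything else is all-atom.
    """
    st = _source_to_structure(pdb_source)
    if len(st) == 0:
        raise ValueError("PDB source contains no model")
    model = st[0]

    receptor: list[AtomRecord] = []
    gag_res: dict[int, list[AtomRecord]] = {}
    chain_seen = False
    for chain_name, res, atom, serial in _atoms_from_gemmi(st, model):
        is_bead = atom.name == BEAD_ATOM_NAME
        rec = AtomRecord(
            serial=serial, name=atom.name, residue_name=res.name,
            chain_id=chain_name, residue_number=res.seqid.num,
            position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
            element=atom.element.name,
            charge=float(atom.charge) if atom.charge else None,
            atom_class=AtomClass.CG_BEAD if is_bead else AtomClass.AA,
        )
        if chain_name == gag_chain_id:
            chain_seen = True
            gag_res.setdefault(res.seqid.num, []).append(rec)
        else:
            receptor.append(rec)

    if not chain_seen:
        raise ValueError(f"chain {gag_chain_id!r} not found in PDB source")
    if not gag_res:
        raise ValueError(f"chain {gag_chain_id!r} contains no residues")

    residues: list[GagResidue] = []
    for num in sorted(gag_res, reverse=reverse_chain):
        atoms = gag_res[num]
        beads = [a for a in atoms if a.atom_class is AtomClass.CG_BEAD]
        if beads:
            rep = Representation.CG
            atoms = beads[:1]
        else:
            rep = Representation.AA
        gly = None
        if rep is Representation.AA:
            by_name = {a.name: a for a in atoms}
            for cand in GLYCOSIDIC_O_NAMES:
                if cand in by_name:
                    gly = by_name[cand]
                    break
        charges = [a.charge for a in atoms if a.charge is not None]
        unit_charge = sum(charges) if charges else -2.0
        residues.append(GagResidue(num, rep, atoms, min(unit_charge, 0.0), gly))

    return GagComplex(receptor, residues, gag_chain_id)


def write_complex(c: GagComplex,
                  destination: Union[str, Path, IO[str], None] = None) -> str:
    """Serialize a complex to PDB text (ATOM/HETATM + CONECT records).

    CG beads are written as HETATM with residue name ``ZCG`` and a carbon
    element placeholder; CONECT records connect consecutive beads and the
    AA/CG junction.
    """
    st = gemmi.Structure()
    model = gemmi.Model("1")

    def add(chain: gemmi.Chain, rec: AtomRecord, resname: str | None = None):
        name = resname or rec.residue_name
        if (len(chain) == 0 or chain[-1].seqid.num != rec.residue_number
                or chain[-1].name != name):
            res = gemmi.Residue()
            res.name = name
            res.seqid = gemmi.SeqId(rec.residue_number, " ")
            res.het_flag = "H" if rec.atom_class is AtomClass.CG_BEAD else "A"
            chain.add_residue(res)
        a = gemmi.Atom()
        a.name = rec.name
        a.pos = gemmi.Position(*rec.position)
        el = rec.element or ("C" if rec.atom_class is AtomClass.CG_BEAD
                             else rec.name[0])
        a.element = gemmi.Element(el)
        chain[-1].add_atom(a)

    # receptor chains in order of first appearance
    chains: dict[str, gemmi.Chain] = {}
    for rec in c.receptor_atoms:
        if rec.chain_id not in chains:
            chains[rec.chain_id] = gemmi.Chain(rec.chain_id)
        add(chains[rec.chain_id], rec)
    gag_chain = gemmi.Chain(c.chain_id)
    chains[c.chain_id] = gag_chain
    serial_of: dict[int, int] = {}  # id(residue) -> serial of its bead
    serial = len(c.receptor_atoms)
    for res in c.gag_chain:
        for rec in res.atoms:
            serial += 1
            if res.representation is Representation.CG:
                add(gag_chain, rec, BEAD_RESIDUE_NAME)
                serial_of[id(res)] = serial
            else:
                add(gag_chain, rec)
                if res.glycosidic_oxygen is not None and rec is res.glycosidic_oxygen:
                    serial_of[id(res)] = serial
    if serial > 99999:
        raise ValueError(f"PDB format cannot hold {serial} atoms (max 99999)")

    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    text = st.make_pdb_string(gemmi.PdbWriteOptions(minimal=True, numbered_ter=False))

    conect: list[str] = []
    prev_serial = None
    prev_cg = False
    for res in c.gag_chain:
        is_cg = res.representation is Representation.CG
        s = serial_of.get(id(res))
        if s is not None and prev_serial is not None and (is_cg or prev_cg):
            conect.append(f"CONECT{prev_serial:>5}{s:>5}")
        if s is not None:
            prev_serial, prev_cg = s, is_cg
        elif not is_cg:
            prev_serial, prev_cg = None, False
    body = text.replace("END\n", "").rstrip("\n")
    text = body + ("\n" + "\n".join(conect) if conect else "") + "\nEND\n"

    if destination is not None:
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            Path(destination).write_text(text)
    return text
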
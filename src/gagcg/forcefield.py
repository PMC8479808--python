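"""Single-pseudoatom (Z1) coarse-grained force field for GAG elongation.

One Z1 bead stands for a whole monosaccharide unit of a glycosaminoglycan
(heparin by default, charge −2 per unit: −1 per sulfate/carboxyl group).
Glycosidic linkages are not modelled between CG units; the bead chain is
held together by the bonded terms below, derived by Boltzmann inversion of
all-atom simulations.  The bonded terms reference five externally owned
GLYCAM atom types at the all-atom/CG junction (Cg, Os, H1, H2, Ng) which
are deliberately not re-parameterized here.

The parameter set is read and written in the AMBER "parameter modification"
(frcmod) dialect so it can be loaded directly by LEaP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Union

logger = logging.getLogger(__name__)

#: GLYCAM-owned atom types referenced by junction terms but not
#: re-parameterized by this package.
EXTERNAL_TYPES = frozenset({"Cg", "Os", "H1", "H2", "Ng"})

#: Default charge of one CG bead, elementary charges (fully sulfated
#: heparin unit: one sulfate + one carboxyl or two sulfates → −2).
DEFAULT_BEAD_CHARGE = -2.0


@dataclass(frozen=True)
class BondParam:
    """Harmonic bond term E = RK (r − REQ)²."""

    type_pair: tuple[str, str]
    RK: float  # kcal mol^-1 Å^-2
    REQ: float  # Å

    def __post_init__(self) -> None:
        if self.RK <= 0 or self.REQ <= 0:
            raise ValueError(f"bond {self.type_pair}: RK and REQ must be positive")


@dataclass(frozen=True)
class AngleParam:
    """Harmonic angle term E = TK (θ − TEQ)², θ in radians internally."""

    type_triple: tuple[str, str, str]
    TK: float  # kcal mol^-1 rad^-2
    TEQ: float  # degrees

    def __post_init__(self) -> None:
        if self.TK <= 0:
            raise ValueError(f"angle {self.type_triple}: TK must be positive")
        if not (0 < self.TEQ <= 180):
            raise ValueError(f"angle {self.type_triple}: TEQ must be in (0, 180]")


@dataclass(frozen=True)
class DihedralParam:
    """Cosine torsion term E = (PK/IDIVF)(1 + cos(PN·φ − phase))."""

    type_quad: tuple[str, str, str, str]
    IDIVF: int
    PK: float  # kcal mol^-1 (barrier height / 2; may be negative as printed)
    phase: float  # degrees
    PN: int

    def __post_init__(self) -> None:
        if self.IDIVF < 1:
            raise ValueError(f"dihedral {self.type_quad}: IDIVF must be >= 1")


@dataclass(frozen=True)
class LJParam:
    """Per-type mass and 12-6 Lennard-Jones parameters (Rmin/2 convention)."""

    atom_type: str
    mass: float  # au
    RvdW: float = 0.0  # Å
    EDEP: float = 0.0  # kcal mol^-1

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"LJ {self.atom_type}: mass must be positive")
        if self.RvdW < 0 or self.EDEP < 0:
            raise ValueError(f"LJ {self.atom_type}: RvdW and EDEP must be >= 0")


@dataclass(frozen=True)
class PseudoatomForceField:
    """Container for the Z1 bonded + nonbonded parameter set.

    Lookup follows AMBER matching semantics: bonds and angles match either
    orientation of the type tuple, dihedrals try both orientations.
    """

    bonds: tuple[BondParam, ...] = ()
    angles: tuple[AngleParam, ...] = ()
    dihedrals: tuple[DihedralParam, ...] = ()
    lj: tuple[LJParam, ...] = ()
    default_bead_charge: float = DEFAULT_BEAD_CHARGE

    def bond(self, pair: Iterable[str]) -> BondParam:
        pair = tuple(pair)
        for b in self.bonds:
            if b.type_pair == pair or b.type_pair == pair[::-1]:
                return b
        raise KeyError(f"no bond parameter for {'-'.join(pair)}")

    def angle(self, triple: Iterable[str]) -> AngleParam:
        triple = tuple(triple)
        for a in self.angles:
            if a.type_triple == triple or a.type_triple == triple[::-1]:
                return a
        raise KeyError(f"no angle parameter for {'-'.join(triple)}")

    def dihedral(self, quad: Iterable[str]) -> DihedralParam:
        quad = tuple(quad)
        for d in self.dihedrals:
            if d.type_quad == quad or d.type_quad == quad[::-1]:
                return d
        raise KeyError(f"no dihedral parameter for {'-'.join(quad)}")

    def lj_param(self, atom_type: str) -> LJParam:
        for p in self.lj:
            if p.atom_type == atom_type:
                return p
        raise KeyError(f"no LJ parameter for atom type {atom_type!r}")

    def has_lj(self, atom_type: str) -> bool:
        return any(p.atom_type == atom_type for p in self.lj)


def z1_forcefield() -> PseudoatomForceField:
    """The published Z1 parameter set.

    3 bond, 7 angle and 15 dihedral terms plus the Z1 mass/LJ entry, exactly
    as derived by Boltzmann inversion from all-atom heparin simulations at
    300 K.  Repeated calls return equal values.
    """
    bonds = (
        BondParam(("Z1", "Z1"), 120.0, 5.2),
        BondParam(("Z1", "Cg"), 120.0, 5.2),
        BondParam(("Os", "Z1"), 120.0, 2.8),
    )
    angles = (
        AngleParam(("Z1", "Z1", "Z1"), 100.0, 160.0),
        AngleParam(("Z1", "Z1", "Cg"), 100.0, 160.0),
        AngleParam(("Z1", "Cg", "H2"), 70.0, 108.5),
        AngleParam(("Z1", "Cg", "Cg"), 70.0, 108.5),
        AngleParam(("Z1", "Cg", "Os"), 60.0, 110.0),
        AngleParam(("Cg", "Os", "Z1"), 100.0, 160.0),
        AngleParam(("Os", "Z1", "Z1"), 100.0, 160.0),
    )
    dihedrals = (
        DihedralParam(("Z1", "Z1", "Z1", "Z1"), 1, 1.0, 0.0, 1),
        DihedralParam(("Z1", "Z1", "Z1", "Cg"), 1, 1.0, 0.0, 1),
        DihedralParam(("Z1", "Z1", "Cg", "Cg"), 1, 0.16, 0.0, 3),
        DihedralParam(("Z1", "Cg", "Cg", "H1"), 1, 0.16, 0.0, 3),
        DihedralParam(("Z1", "Cg", "Cg", "H2"), 1, 0.16, 0.0, 3),
        DihedralParam(("Z1", "Z1", "Cg", "H2"), 1, 0.16, 0.0, 3),
        DihedralParam(("Z1", "Z1", "Cg", "Os"), 1, 0.16, 0.0, 3),
        DihedralParam(("Z1", "Cg", "Cg", "Ng"), 1, -1.3, 0.0, 1),
        DihedralParam(("Z1", "Cg", "Cg", "Cg"), 1, -0.27, 0.0, 1),
        DihedralParam(("Z1", "Cg", "Os", "Cg"), 1, -0.27, 0.0, 1),
        DihedralParam(("Cg", "Cg", "Os", "Z1"), 1, 0.16, 0.0, 3),
        DihedralParam(("Cg", "Os", "Z1", "Z1"), 1, 0.16, 0.0, 3),
        DihedralParam(("H1", "Cg", "Os", "Z1"), 1, 0.27, 0.0, 3),
        DihedralParam(("Z1", "Cg", "Cg", "Os"), 1, 0.16, 0.0, 3),
        DihedralParam(("Os", "Z1", "Z1", "Z1"), 1, 0.16, 0.0, 3),
    )
    lj = (LJParam("Z1", 225.0, 4.0, 3.4),)
    return PseudoatomForceField(bonds, angles, dihedrals, lj)


# backwards-compatible alias used by the CLI
default_forcefield = z1_forcefield


def _fmt(x: float) -> str:
    """Fixed-point with at least one decimal, trailing zeros trimmed."""
    s = f"{x:.6f}".rstrip("0")
    if s.endswith("."):
        s += "0"
    return s


def _check_type(name: str) -> str:
    if len(name) > 2:
        raise ValueError(f"atom type {name!r} longer than 2 characters "
                         "(AMBER frcmod limit)")
    return name.ljust(2)


def _join_types(types: Iterable[str]) -> str:
    return "-".join(_check_type(t) for t in types)


def write_frcmod(ff: PseudoatomForceField,
                 destination: Union[str, Path, IO[str], None] = None) -> str:
    """Serialize a force field to AMBER frcmod text.

    Writes MASS, BOND, ANGLE, DIHE and NONBON sections.  Negative PK values
    are written verbatim rather than folded into a 180° phase, keeping the
    file identical to the published tables (AMBER accepts either form).

    Returns the text; if *destination* is a path or file object it is also
    written there.
    """
    if any(d.PK < 0 for d in ff.dihedrals):
        logger.info("frcmod contains negative PK terms, written verbatim "
                    "(equivalent to positive PK with phase shifted by 180°)")
    lines = ["Z1 coarse-grained GAG elongation parameters"]
    lines.append("MASS")
    for p in ff.lj:
        lines.append(f"{_check_type(p.atom_type)} {_fmt(p.mass)}")
    lines.append("")
    lines.append("BOND")
    for b in ff.bonds:
        lines.append(f"{_join_types(b.type_pair)}  {_fmt(b.RK)}  {_fmt(b.REQ)}")
    lines.append("")
    lines.append("ANGLE")
    for a in ff.angles:
        lines.append(f"{_join_types(a.type_triple)}  {_fmt(a.TK)}  {_fmt(a.TEQ)}")
    lines.append("")
    lines.append("DIHE")
    for d in ff.dihedrals:
        lines.append(f"{_join_types(d.type_quad)}  {d.IDIVF}  {_fmt(d.PK)}"
                     f"  {_fmt(d.phase)}  {_fmt(float(d.PN))}")
    lines.append("")
    lines.append("NONBON")
    for p in ff.lj:
        lines.append(f"  {_check_type(p.atom_type)}  {_fmt(p.RvdW)}  {_fmt(p.EDEP)}")
    lines.append("")
    text = "\n".join(lines) + "\n"

    if destination is not None:
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            Path(destination).write_text(text)
    return text


class FrcmodParseError(ValueError):
    """Raised when an frcmod record cannot be parsed; carries the line number."""


_SECTIONS = ("MASS", "BOND", "ANGL", "DIHE", "NONB", "IMPR", "HBON")


def _split_types(token: str, n: int, lineno: int) -> tuple[str, ...]:
    parts = tuple(t.strip() for t in token.split("-"))
    if len(parts) != n or any(not p for p in parts):
        raise FrcmodParseError(f"line {lineno}: expected {n} hyphen-joined "
                               f"atom types, got {token!r}")
    return parts


def read_frcmod(source: Union[str, Path, IO[str]]) -> PseudoatomForceField:
    """Parse AMBER frcmod text into a :class:`PseudoatomForceField`.

    *source* may be frcmod text, a path, or an open file.  Unknown sections
    are skipped with a logged warning; a malformed numeric field raises
    :class:`FrcmodParseError` naming the line.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        s = str(source)
        text = Path(s).read_text() if "\n" not in s and Path(s).is_file() else s

    masses: dict[str, float] = {}
    nonbon: dict[str, tuple[float, float]] = {}
    bonds: list[BondParam] = []
    angles: list[AngleParam] = []
    dihedrals: list[DihedralParam] = []
    order: list[str] = []

    section = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if lineno == 1:  # title line
            continue
        stripped = line.strip()
        if not stripped:
            section = None
            continue
        upper = stripped.upper()
        if any(upper.startswith(k) for k in _SECTIONS) and len(stripped.split()) == 1:
            section = upper[:4]
            if section in ("IMPR", "HBON"):
                logger.warning("ignoring unsupported frcmod section %s", stripped)
            continue
        if section is None:
            logger.warning("line %d outside any known section ignored: %r",
                           lineno, stripped)
            continue
        try:
            if section == "MASS":
                t, m = stripped.split()[:2]
                masses[t] = float(m)
                if t not in order:
                    order.append(t)
            elif section == "BOND":
                tok = stripped.split()
                pair = _split_types(tok[0], 2, lineno)
                bonds.append(BondParam(pair, float(tok[1]), float(tok[2])))
            elif section == "ANGL":
                tok = stripped.split()
                triple = _split_types(tok[0], 3, lineno)
                angles.append(AngleParam(triple, float(tok[1]), float(tok[2])))
            elif section == "DIHE":
                tok = stripped.split()
                quad = _split_types(tok[0], 4, lineno)
                dihedrals.append(DihedralParam(
                    quad, int(tok[1]), float(tok[2]), float(tok[3]),
                    int(round(float(tok[4])))))
            elif section == "NONB":
                t, r, e = stripped.split()[:3]
                nonbon[t] = (float(r), float(e))
                if t not in order:
                    order.append(t)
            else:
                continue
        except FrcmodParseError:
            raise
        except (ValueError, IndexError) as exc:
            raise FrcmodParseError(
                f"line {lineno}: malformed {section} record {stripped!r}: {exc}"
            ) from exc

    lj = tuple(
        LJParam(t, masses.get(t, 1.0), *nonbon.get(t, (0.0, 0.0)))
        for t in order
    )
    return PseudoatomForceField(tuple(bonds), tuple(angles), tuple(dihedrals), lj)
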
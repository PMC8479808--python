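"""Deterministic synthetic fixtures: idealized GAG chains, model
peptide–GAG complexes, Boltzmann-distributed coordinate samples and
per-residue decomposition tables.

These emulate the three input classes of the elongation workflow — a
docked complex, conformational samples from all-atom MD, and an MM/GBSA
per-residue decomposition — without requiring any download or simulation.
Geometry is idealized (no ring pucker, no docking-pose realism): the
helical GAG approximates heparin's ~4-unit repeat with a 4.5 Å rise, and
peptides are built with an extended backbone and charged side chains
pointing at the GAG.  Identical arguments give bitwise-identical output.
"""

from __future__ import annotations

import math

import numpy as np

from .elongate import DecompositionTable
from .boltzmann import SampleSeries
from .constants import KB_KCAL, DEFAULT_TEMPERATURE
from .structures import (AtomRecord, GagComplex, GagResidue,
                         Representation)

DEFAULT_RISE = 4.5  # Å per residue along the helix axis
DEFAULT_TURN = 180.0  # degrees per residue
HELIX_RADIUS = 1.5  # Å
RING_RADIUS = 1.43  # Å, pyranose-like hexagon
RING_NAMES = ("C1", "C2", "C3", "C4", "C5", "O5")

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_SIDE_REF = {"LYS": "NZ", "ARG": "CZ", "ASP": "CG", "GLU": "CD"}


def make_gag_helix(dp: int, rise: float = DEFAULT_RISE,
                   turn_deg: float = DEFAULT_TURN,
                   with_ring_atoms: bool = False, seed: int = 0,
                   chain_id: str = "A",
                   unit_charge: float = -2.0) -> GagComplex:
    """Idealized helical GAG chain of *dp* monosaccharide units (no receptor).

    Residue centroids lie on a helix of radius 1.5 Å around the z axis
    (*turn_deg* = 0 gives a straight chain).  With *with_ring_atoms* each
    residue gets six pyranose-ring atoms plus a glycosidic oxygen ``O1``
    pointing toward the next (reducing-end) unit; otherwise a single
    centroid particle named ``C1``.  Unit charges default to −2 (fully
    sulfated heparin).
    """
    if dp < 2:
        raise ValueError("dp must be >= 2")
    centroids = np.array([
        [HELIX_RADIUS * math.cos(math.radians(turn_deg) * i),
         HELIX_RADIUS * math.sin(math.radians(turn_deg) * i),
         rise * i] for i in range(dp)])

    residues = []
    serial = 0
    for i in range(dp):
        cent = centroids[i]
        nxt = centroids[i + 1] if i + 1 < dp else 2 * centroids[i] - centroids[i - 1]
        axis = nxt - cent
        axis = axis / np.linalg.norm(axis)
        atoms: list[AtomRecord] = []
        if with_ring_atoms:
            # hexagon in the plane normal to the propagation axis
            ref = np.array([1.0, 0.0, 0.0])
            if abs(np.dot(axis, ref)) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            u = np.cross(axis, ref)
            u /= np.linalg.norm(u)
            v = np.cross(axis, u)
            n_atoms = len(RING_NAMES) + 1
            for k, name in enumerate(RING_NAMES):
                ang = 2 * math.pi * k / len(RING_NAMES)
                pos = cent + RING_RADIUS * (math.cos(ang) * u + math.sin(ang) * v)
                serial += 1
                atoms.append(AtomRecord(
                    serial, name, "SGC", chain_id, i + 1, pos,
                    "O" if name.startswith("O") else "C",
                    unit_charge / n_atoms))
            serial += 1
            gly = AtomRecord(serial, "O1", "SGC", chain_id, i + 1,
                             cent + 1.4 * axis, "O", unit_charge / n_atoms)
            atoms.append(gly)
            residues.append(GagResidue(i + 1, Representation.AA, atoms,
                                       unit_charge, gly))
        else:
            serial += 1
            atoms.append(AtomRecord(serial, "C1", "SGC", chain_id, i + 1,
                                    cent, "C", unit_charge))
            residues.append(GagResidue(i + 1, Representation.AA, atoms,
                                       unit_charge))
    return GagComplex([], residues, chain_id)


def _parse_sequence(sequence) -> list[str]:
    if isinstance(sequence, str) and all(len(s) == 1 for s in sequence):
        codes = list(sequence.upper())
        bad = [c for c in codes if c not in _AA3]
        if bad:
            raise ValueError(f"unknown residue code(s) {bad}")
        return [_AA3[c] for c in codes]
    names = [str(s).upper() for s in sequence]
    bad = [n for n in names if n not in _AA3.values()]
    if bad:
        raise ValueError(f"unknown residue code(s) {bad}")
    return names


def make_peptide_complex(sequence, gag: GagComplex, offset: float = 6.0,
                         seed: int = 0,
                         peptide_chain_id: str = "P") -> GagComplex:
    """Place an idealized extended peptide parallel to a GAG chain.

    The peptide backbone runs parallel to the GAG helix axis (z) at
    distance *offset* (Å), Cα spacing 3.8 Å, centred on the GAG midpoint;
    charged side chains point toward the GAG so that Lys/Arg termini land
    within interaction range.  *sequence* takes 1- or 3-letter codes.
    """
    names = _parse_sequence(sequence)
    cents = np.array([r.ring_centroid for r in gag.gag_chain])
    z_mid = cents[:, 2].mean()
    z0 = z_mid - 3.8 * (len(names) - 1) / 2.0

    toward_gag = np.array([-1.0, 0.0, 0.0])  # peptide sits at +x
    atoms: list[AtomRecord] = []
    serial = 0

    def add(name, resname, resnum, pos, element):
        nonlocal serial
        serial += 1
        atoms.append(AtomRecord(serial, name, resname, peptide_chain_id,
                                resnum, np.asarray(pos, float), element))

    for i, resname in enumerate(names):
        z = z0 + 3.8 * i
        ca = np.array([offset, 0.0, z])
        add("N", resname, i + 1, ca + [0.0, 1.2, -0.8], "N")
        add("CA", resname, i + 1, ca, "C")
        add("C", resname, i + 1, ca + [0.0, -1.2, 0.8], "C")
        add("O", resname, i + 1, ca + [0.0, -2.2, 0.4], "O")
        if resname == "GLY":
            continue
        cb = ca + 1.5 * toward_gag
        add("CB", resname, i + 1, cb, "C")
        ref = _SIDE_REF.get(resname)
        if ref:
            reach = 4.0 if resname in ("LYS", "ARG") else 1.5
            add(ref, resname, i + 1, cb + reach * toward_gag,
                "N" if ref == "NZ" else "C")
    return GagComplex(atoms, [r.copy() for r in gag.gag_chain], gag.chain_id)


def sample_boltzmann(kind: str, equilibrium: float = 0.0,
                     force_constant: float | None = None,
                     pk: float | None = None, pn: int = 1,
                     phase: float = 0.0, idivf: int = 1,
                     temperature: float = DEFAULT_TEMPERATURE,
                     n: int = 100_000, seed: int = 0) -> SampleSeries:
    """Draw *n* samples from the Boltzmann distribution of one bonded term.

    Bonds/angles: exact Gaussian draws from E = K(x − x₀)², standard
    deviation √(kT/2K) (angle samples are reflected at the 180° boundary).
    Dihedrals: many-walker Metropolis sampling of
    E = (PK/IDIVF)(1 + cos(PN φ − phase)) with a discarded burn-in.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    kt = KB_KCAL * temperature

    if kind in ("bond", "angle"):
        if force_constant is None or force_constant <= 0:
            raise ValueError("force_constant must be positive")
        sigma = math.sqrt(kt / (2.0 * force_constant))
        if kind == "angle":
            sigma = math.degrees(sigma)
        vals = rng.normal(equilibrium, sigma, size=n)
        if kind == "angle":
            vals = np.abs(vals)  # reflect at 0
            vals = np.where(vals > 180.0, 360.0 - vals, vals)
        return SampleSeries(kind, vals, temperature)

    if kind != "dihedral":
        raise ValueError(f"unknown sample kind {kind!r}")
    if pk is None:
        raise ValueError("dihedral sampling needs pk (and pn)")

    def energy(phi_rad: np.ndarray) -> np.ndarray:
        return (pk / idivf) * (1.0 + np.cos(pn * phi_rad - math.radians(phase)))

    walkers = min(1000, n)
    burn_in = 500
    steps = burn_in + math.ceil(n / walkers)
    phi = rng.uniform(-math.pi, math.pi, size=walkers)
    e = energy(phi)
    out = np.empty((steps - burn_in, walkers))
    step_size = 1.0  # rad
    for t in range(steps):
        prop = phi + rng.uniform(-step_size, step_size, size=walkers)
        prop = np.arctan2(np.sin(prop), np.cos(prop))  # wrap
        e_prop = energy(prop)
        accept = rng.random(walkers) < np.exp(-(e_prop - e) / kt)
        phi = np.where(accept, prop, phi)
        e = np.where(accept, e_prop, e)
        if t >= burn_in:
            out[t - burn_in] = phi
    vals = np.degrees(out.ravel()[:n])
    return SampleSeries("dihedral", vals, temperature)


def make_decomposition(gag: GagComplex, core_dg: float = -3.0,
                       tail_dg: float = -0.1,
                       n_core: int | None = None) -> DecompositionTable:
    """Synthetic per-residue decomposition: strong core, weak flanks.

    The central *n_core* residues get *core_dg*, the flanking residues
    *tail_dg* (kcal/mol), mimicking a binding core with loosely attached
    lateral units.
    """
    dp = len(gag.gag_chain)
    if n_core is None:
        n_core = dp
    if n_core > dp:
        raise ValueError("n_core exceeds chain length")
    start = (dp - n_core) // 2
    entries = {}
    for i, res in enumerate(gag.gag_chain):
        entries[res.residue_number] = (core_dg if start <= i < start + n_core
                                       else tail_dg)
    return DecompositionTable(entries)
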
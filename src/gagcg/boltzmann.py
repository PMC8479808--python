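"""Boltzmann inversion of conformational samples into CG bonded parameters.

Given distributions of a bond length, bending angle or torsion observed in
all-atom simulations, the potential of mean force is U(x) = −kT ln P(x)
(no Jacobian correction by default, optionally r²/sin θ).  Harmonic terms
are fitted from the sample mean and variance in the AMBER convention
E = K(x − x₀)² (K absorbs the ½: K = kT / 2σ²).  Torsions are classified
by the number of PMF minima per 360° (periodicity 1 or 3) and their
amplitude PK is half the barrier separating the global minimum from the
local minima, matching the convention of the shipped parameter tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Sequence, Union

import gemmi
import numpy as np

from .constants import DEFAULT_TEMPERATURE, KB_KCAL

logger = logging.getLogger(__name__)

MIN_SAMPLES_FOR_FIT = 100


@dataclass
class SampleSeries:
    """Measurements of one internal coordinate.

    kind: ``bond`` (Å), ``angle`` (degrees, (0, 180]) or ``dihedral``
    (degrees, (−180, 180], periodic).
    """

    kind: str
    values: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.kind not in ("bond", "angle", "dihedral"):
            raise ValueError(f"unknown sample kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.kind == "angle" and self.values.size:
            lo, hi = self.values.min(), self.values.max()
            if lo <= 0 or hi > 180:
                raise ValueError("angle samples must lie in (0, 180] degrees")
        if self.kind == "dihedral" and self.values.size:
            # wrap into (-180, 180]
            self.values = ((-self.values + 180.0) % 360.0)
            self.values = 180.0 - self.values


@dataclass
class PmfFit:
    """A fitted bonded parameter plus the PMF it came from."""

    kind: str
    equilibrium: float  # Å or degrees
    force_constant: float | None = None  # kcal/mol/Å² or kcal/mol/rad²
    PK: float | None = None  # kcal/mol (dihedrals)
    PN: int | None = None
    phase: float | None = None  # degrees
    pmf_bins: np.ndarray | None = None  # bin centers
    pmf_values: np.ndarray | None = None  # kcal/mol, NaN where empty


def pmf_from_samples(s: SampleSeries, n_bins: int = 72,
                     jacobian: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Binned potential of mean force U(x) = −kT ln(P(x)/P_max).

    Returns (bin_centers, pmf) with the minimum at exactly 0 and empty bins
    set to NaN.  Dihedral domains are treated as periodic over 360°.  With
    *jacobian* the distribution is divided by r² (bonds) or sin θ (angles)
    before inversion.
    """
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    v = s.values
    if v.size == 0:
        raise ValueError("no samples")
    if np.ptp(v) == 0:
        raise ValueError("degenerate distribution: all samples identical")
    if s.kind == "dihedral":
        edges = np.linspace(-180.0, 180.0, n_bins + 1)
    else:
        edges = np.linspace(v.min(), v.max(), n_bins + 1)
    counts, _ = np.histogram(v, bins=edges)
    if np.count_nonzero(counts) < 2:
        raise ValueError("samples span fewer than 2 bins")
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = counts.astype(float)
    if jacobian:
        if s.kind == "bond":
            density = density / centers**2
        elif s.kind == "angle":
            density = density / np.sin(np.radians(centers))
    kt = KB_KCAL * s.temperature
    with np.errstate(divide="ignore"):
        pmf = -kt * np.log(density / density.max())
    pmf[counts == 0] = np.nan
    pmf -= np.nanmin(pmf)  # exact 0 at the minimum
    return centers, pmf


def _is_bimodal(pmf: np.ndarray, kt: float) -> bool:
    """True when a second well is separated from the global minimum by a
    barrier of at least kT/2 (after 3-bin smoothing)."""
    w = pmf[~np.isnan(pmf)]
    if w.size < 7:
        return False
    kernel = np.ones(3) / 3
    s = np.convolve(np.r_[w[0], w, w[-1]], kernel, mode="valid")
    g = int(np.argmin(s))
    for i in range(1, s.size - 1):
        if i == g or not (s[i] <= s[i - 1] and s[i] <= s[i + 1]):
            continue
        lo, hi = sorted((g, i))
        barrier = float(s[lo:hi + 1].max())
        if barrier - s[i] > kt / 2 and barrier - s[g] > kt / 2:
            return True
    return False


def fit_harmonic(s: SampleSeries) -> PmfFit:
    """Fit E = K(x − x₀)² by Boltzmann inversion of a (near-)Gaussian sample.

    x₀ is the sample mean (circular mean for dihedrals) and
    K = kT / (2 var); for angles the variance is converted to rad² so K is
    in kcal mol⁻¹ rad⁻².
    """
    v = s.values
    if v.size < MIN_SAMPLES_FOR_FIT:
        raise ValueError(f"need >= {MIN_SAMPLES_FOR_FIT} samples, got {v.size}")
    kt = KB_KCAL * s.temperature
    if s.kind == "dihedral":
        rad = np.radians(v)
        mean = math.degrees(math.atan2(np.sin(rad).mean(), np.cos(rad).mean()))
        dev = np.radians(v) - math.radians(mean)
        dev = np.arctan2(np.sin(dev), np.cos(dev))
        var = float(np.mean(dev**2))
    else:
        mean = float(v.mean())
        var = float(v.var())
        if s.kind == "angle":
            var = math.radians(1.0) ** 2 * var
    if var == 0:
        raise ValueError("zero variance: cannot invert a delta distribution")
    centers, pmf = pmf_from_samples(s)
    if _is_bimodal(pmf, kt):
        logger.warning("distribution looks bimodal; harmonic fit may be poor")
    return PmfFit(kind=s.kind, equilibrium=mean, force_constant=kt / (2 * var),
                  pmf_bins=centers, pmf_values=pmf)


def _smooth_periodic(y: np.ndarray, window: int = 3) -> np.ndarray:
    """Moving average with periodic wrap (NaN bins treated as empty→max)."""
    filled = np.where(np.isnan(y), np.nanmax(y), y)
    kernel = np.ones(window) / window
    ext = np.r_[filled[-(window // 2):], filled, filled[: window // 2]]
    return np.convolve(ext, kernel, mode="valid")


def fit_dihedral(s: SampleSeries, n_bins: int = 72) -> PmfFit:
    """Classify a torsion PMF and fit E = (PK/IDIVF)(1 + cos(PN φ − phase)).

    Periodicity is 1 or 3 according to the number of minima of the smoothed
    PMF per 360°; PK is half the height of the highest barrier separating
    the global minimum from the local minima (half the total amplitude for
    a single-well profile).  The phase is snapped to 0° or 180° so that the
    cosine minimum coincides with the PMF global minimum.  A flat PMF
    (amplitude below kT/4) yields PK ≈ 0, PN = 1 with a warning.
    """
    if s.kind != "dihedral":
        raise ValueError("fit_dihedral requires dihedral samples")
    kt = KB_KCAL * s.temperature
    centers, pmf = pmf_from_samples(s, n_bins=n_bins)
    smooth = _smooth_periodic(pmf)

    n = smooth.size
    prev = np.roll(smooth, 1)
    nxt = np.roll(smooth, -1)
    is_min = (smooth <= prev) & (smooth <= nxt) & ((smooth < prev) | (smooth < nxt))
    # merge adjacent flat minima
    min_idx = np.flatnonzero(is_min)
    merged: list[int] = []
    for i in min_idx:
        if merged and (i - merged[-1]) % n <= 1:
            continue
        merged.append(int(i))
    if merged and (merged[0] - merged[-1]) % n <= 1 and len(merged) > 1:
        merged.pop()

    amplitude = float(np.nanmax(smooth) - np.nanmin(smooth))
    if amplitude < kt / 4:
        logger.warning("flat torsion PMF (amplitude %.3f kcal/mol); PK set ~0",
                       amplitude)
        return PmfFit(kind="dihedral", equilibrium=0.0, PK=amplitude / 2,
                      PN=1, phase=0.0, pmf_bins=centers, pmf_values=pmf)

    # drop shallow minima (depth below kT/4 relative to surrounding barrier)
    global_i = min(merged, key=lambda i: smooth[i])
    significant = []
    for i in merged:
        if i == global_i:
            significant.append(i)
            continue
        left = _barrier_between(smooth, global_i, i)
        if left - smooth[i] > kt / 4:
            significant.append(i)
    n_minima = len(significant)
    if n_minima not in (1, 3):
        raise ValueError(
            f"unsupported torsion periodicity: found {n_minima} minima per "
            "360° (only 1 and 3 are parameterized)")
    pn = n_minima

    gmin = float(smooth[global_i])
    if pn == 1:
        barrier = float(np.nanmax(smooth))
    else:
        barrier = max(_barrier_between(smooth, global_i, i)
                      for i in significant if i != global_i)
    pk = (barrier - gmin) / 2.0

    phi_min = float(centers[global_i])
    # cos(PN φ − phase) = −1 at the minimum; snap phase to {0, 180}
    phase = 0.0 if math.cos(math.radians(pn * phi_min)) < 0 else 180.0
    return PmfFit(kind="dihedral", equilibrium=phi_min, PK=pk, PN=pn,
                  phase=phase, pmf_bins=centers, pmf_values=pmf)


def _barrier_between(smooth: np.ndarray, i: int, j: int) -> float:
    """Lowest maximal barrier on either periodic path between bins i and j."""
    n = smooth.size
    if i == j:
        return float(smooth[i])
    path1 = [smooth[k % n] for k in range(i, i + (j - i) % n + 1)]
    path2 = [smooth[k % n] for k in range(j, j + (i - j) % n + 1)]
    return float(min(max(path1), max(path2)))


def measure_internal_coordinates(models: Union[str, Path, IO[str]],
                                 selection: Sequence[str],
                                 temperature: float = DEFAULT_TEMPERATURE,
                                 ) -> SampleSeries:
    """Measure a distance/angle/dihedral across the models of a multi-model PDB.

    *selection* is 2, 3 or 4 atom names (first occurrence in each model is
    used).  Distances in Å, angles/dihedrals in degrees with the dihedral
    sign following the right-hand rule.
    """
    if len(selection) not in (2, 3, 4):
        raise ValueError("selection must name 2, 3 or 4 atoms")
    if hasattr(models, "read"):
        text = models.read()
    else:
        s = str(models)
        text = Path(s).read_text() if "\n" not in s and Path(s).is_file() else s
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise ValueError("no models in input")

    values = []
    for mi, model in enumerate(st):
        pos: dict[str, np.ndarray] = {}
        for chain in model:
            for res in chain:
                for atom in res:
                    if atom.name in selection and atom.name not in pos:
                        pos[atom.name] = np.array([atom.pos.x, atom.pos.y,
                                                   atom.pos.z])
        missing = [a for a in selection if a not in pos]
        if missing:
            raise ValueError(f"model {mi}: atoms {missing} not found")
        pts = [pos[a] for a in selection]
        if len(pts) == 2:
            values.append(distance(*pts))
        elif len(pts) == 3:
            values.append(angle_deg(*pts))
        else:
            values.append(dihedral_deg(*pts))
    kind = {2: "bond", 3: "angle", 4: "dihedral"}[len(selection)]
    return SampleSeries(kind=kind, values=np.array(values),
                        temperature=temperature)


def distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(b, float) - np.asarray(a, float)))


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral_deg(p0, p1, p2, p3) -> float:
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def read_sample_column(source: Union[str, Path, IO[str]], kind: str,
                       temperature: float = DEFAULT_TEMPERATURE) -> SampleSeries:
    """Read a plain one-column text file of measurements into a series."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    vals = [float(tok) for line in text.splitlines()
            for tok in line.split() if tok and not tok.startswith("#")]
    return SampleSeries(kind=kind, values=np.array(vals), temperature=temperature)
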
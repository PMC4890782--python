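"""Statistical pi-pi potential for Phe/Tyr aromatic ring pairs.

The geometry of a ring pair is reduced to three variables: center-to-center
distance r, planar tilt angle theta between the ring normals, and center
dislocation angle phi between one ring's normal and the center-center
vector (both angles folded into [0, 90] degrees; the pair energy is
symmetrized over the two ring orderings).  Occurrences observed in a
structure set are binned on a 30 x 30 x 30 grid (r in [3, 12) Angstrom,
0.3 Angstrom bins; theta, phi in [0, 90) degrees, 3 degree bins) and turned
into an energy

    E_pipi(r, theta, phi) = -eps_pipi * {1 + ln[P / P_max] / |ln(P_min / P_max)|}

where P_max and P_min are the largest and smallest nonzero bin counts.
Bins with zero counts get E = 0, so the potential is attractive and varies
between -eps_pipi (modal geometry) and 0 (rarest nonzero and unobserved
geometries).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from foldswitch.sequences import AA1

R_MIN, R_MAX, R_STEP = 3.0, 12.0, 0.3
ANG_MAX, ANG_STEP = 90.0, 3.0
GRID_SHAPE = (30, 30, 30)
DEFAULT_EPS_PIPI = 1.5
PAIR_CLASSES = ("F-F", "Y-Y", "F-Y")

# Benzene-ring carbons of Phe and Tyr (hydroxyl oxygen excluded).
RING_ATOMS = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")


@dataclass
class RingGeometry:
    r: float      # Angstrom, center to center
    theta: float  # degrees in [0, 90], tilt between ring planes
    phi: float    # degrees in [0, 90], normal-1 vs center-center vector

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("ring separation must be positive")


@dataclass
class PiPiHistogram:
    counts: np.ndarray           # (30, 30, 30) integer grid
    pair_class: str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != GRID_SHAPE:
            raise ValueError(f"histogram grid must be {GRID_SHAPE}")

    @property
    def p_max(self) -> int:
        nz = self.counts[self.counts > 0]
        return int(nz.max()) if nz.size else 0

    @property
    def p_min(self) -> int:
        nz = self.counts[self.counts > 0]
        return int(nz.min()) if nz.size else 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class PiPiPotential:
    energy: np.ndarray           # (30, 30, 30), values in [-eps_pipi, 0]
    eps_pipi: float
    pair_class: str

    def __post_init__(self) -> None:
        self.energy = np.asarray(self.energy, float)
        if self.energy.shape != GRID_SHAPE:
            raise ValueError(f"energy grid must be {GRID_SHAPE}")
        if self.eps_pipi <= 0:
            raise ValueError("eps_pipi must be > 0")


def _fit_normal(ring: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit best-fit plane normal of the six ring carbons."""
    ring = np.asarray(ring, float)
    if ring.shape != (6, 3):
        raise ValueError("a ring is six (x, y, z) carbon positions")
    center = ring.mean(axis=0)
    centered = ring - center
    _, s, vt = np.linalg.svd(centered)
    if s[1] < 1e-8:  # degenerate: atoms collinear
        raise ValueError("degenerate (collinear) ring atoms")
    return center, vt[2]


def _acute(angle_deg: float) -> float:
    """Fold an angle into the first quadrant [0, 90]."""
    a = angle_deg % 180.0
    return 180.0 - a if a > 90.0 else a


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = np.clip(abs(float(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v))), 0.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def ring_geometry(ring1: np.ndarray, ring2: np.ndarray) -> RingGeometry:
    """(r, theta, phi) of a ring pair, invariant under rigid motions.

    phi is symmetrized over the two ring orderings (averaged), making the
    descriptor exchange-symmetric.
    """
    c1, n1 = _fit_normal(ring1)
    c2, n2 = _fit_normal(ring2)
    sep = c2 - c1
    r = float(np.linalg.norm(sep))
    if r < 1e-9:
        raise ValueError("coincident ring centers")
    theta = _acute(_angle_deg(n1, n2))
    phi1 = _acute(_angle_deg(n1, sep))
    phi2 = _acute(_angle_deg(n2, sep))
    return RingGeometry(r=r, theta=theta, phi=0.5 * (phi1 + phi2))


def bin_index(g: RingGeometry) -> tuple[int, int, int] | None:
    """Half-open bin of a geometry, or None when r is out of [3, 12)."""
    if not (R_MIN <= g.r < R_MAX):
        return None
    ir = int((g.r - R_MIN) / R_STEP)
    it = min(int(g.theta / ANG_STEP), GRID_SHAPE[1] - 1)  # theta = 90 folds to top bin
    ip = min(int(g.phi / ANG_STEP), GRID_SHAPE[2] - 1)
    return ir, it, ip


def _residue_rings(structure) -> list[tuple[str, np.ndarray]]:
    """(one-letter type, (6, 3) ring coordinates) for each Phe/Tyr residue.

    Works with any residue object exposing ``name`` and either named ring
    atoms (mapping ``atoms``) or at least six ``sidechain_heavy`` entries.
    """
    rings = []
    for res in structure.residues:
        aa = AA1.get(res.name)
        if aa not in ("F", "Y"):
            continue
        atoms = getattr(res, "atoms", None)
        if atoms and all(a in atoms for a in RING_ATOMS):
            coords = np.array([atoms[a] for a in RING_ATOMS], float)
        elif len(res.sidechain_heavy) >= 6:
            coords = np.asarray(res.sidechain_heavy[-6:], float)
        else:
            continue
        rings.append((aa, coords))
    return rings


def pair_class_of(aa1: str, aa2: str) -> str:
    return "F-F" if aa1 == aa2 == "F" else "Y-Y" if aa1 == aa2 == "Y" else "F-Y"


def accumulate_histogram(structures, pair_class: str) -> PiPiHistogram:
    """Bin all observed same-structure ring pairs of one residue-type class."""
    if pair_class not in PAIR_CLASSES:
        raise ValueError(f"pair_class must be one of {PAIR_CLASSES}")
    counts = np.zeros(GRID_SHAPE, dtype=np.int64)
    for st in structures:
        rings = _residue_rings(st)
        for (a1, r1), (a2, r2) in combinations(rings, 2):
            if pair_class_of(a1, a2) != pair_class:
                continue
            try:
                g = ring_geometry(r1, r2)
            except ValueError:
                continue
            idx = bin_index(g)
            if idx is not None:
                counts[idx] += 1
    return PiPiHistogram(counts=counts, pair_class=pair_class)


def potential_from_histogram(hist: PiPiHistogram,
                             eps_pipi: float = DEFAULT_EPS_PIPI) -> PiPiPotential:
    """Knowledge-based energy grid from bin counts; empty bins stay at 0."""
    counts = hist.counts
    energy = np.zeros(GRID_SHAPE, float)
    nz = counts > 0
    if not nz.any():
        return PiPiPotential(energy=energy, eps_pipi=eps_pipi, pair_class=hist.pair_class)
    p_max, p_min = hist.p_max, hist.p_min
    if p_max == p_min:
        # all occupied bins equally likely: |ln(P_min/P_max)| = 0 guard
        energy[nz] = -eps_pipi
        return PiPiPotential(energy=energy, eps_pipi=eps_pipi, pair_class=hist.pair_class)
    denom = abs(np.log(p_min / p_max))
    energy[nz] = -eps_pipi * (1.0 + np.log(counts[nz] / p_max) / denom)
    return PiPiPotential(energy=energy, eps_pipi=eps_pipi, pair_class=hist.pair_class)


def evaluate_pipi(potential: PiPiPotential, geometry: RingGeometry) -> float:
    """Table lookup by bin; geometries with r outside [3, 12) cost nothing."""
    idx = bin_index(geometry)
    if idx is None:
        return 0.0
    return float(potential.energy[idx])


def potential_to_tsv(potential: PiPiPotential, path: str | Path) -> Path:
    """Sparse TSV of nonzero bins (bin indices + energy)."""
    ir, it, ip = np.nonzero(potential.energy)
    df = pd.DataFrame({"r_bin": ir, "theta_bin": it, "phi_bin": ip,
                       "energy": potential.energy[ir, it, ip]})
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# pair_class={potential.pair_class} eps_pipi={potential.eps_pipi}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def potential_from_tsv(path: str | Path) -> PiPiPotential:
    path = Path(path)
    meta = dict(tok.split("=") for tok in path.open().readline().lstrip("# ").split())
    df = pd.read_csv(path, sep="\t", comment="#")
    energy = np.zeros(GRID_SHAPE, float)
    energy[df["r_bin"], df["theta_bin"], df["phi_bin"]] = df["energy"]
    return PiPiPotential(energy=energy, eps_pipi=float(meta["eps_pipi"]),
                         pair_class=meta["pair_class"])


def synthetic_ring(center, normal, radius: float = 1.39) -> np.ndarray:
    """Six coplanar carbons of an ideal benzene ring (synthetic test helper)."""
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    ang = np.deg2rad(np.arange(6) * 60.0)
    return np.asarray(center, float) + radius * (np.outer(np.cos(ang), u) +
                                                 np.outer(np.sin(ang), v))
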
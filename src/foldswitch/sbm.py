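"""Multi-Gaussian dual-basin structure-based potential and Q coordinates.

Each consensus native contact (i, j) contributes

    E_ij(r) = eps * [1 - prod_s (1 - exp(-(r - d_ij^(s))^2 / 2 w^2))]

with one Gaussian well per native conformer s.  The per-contact energy
equals eps (< 0) whenever r matches any conformer's native distance, and
decays to zero far from every well, so all contributing native conformers
sit at an energy minimum of the same depth.  The dual-basin potential is
the plain sum E_SBM = E_A + E_B (no logarithmic mixing), and the progress
coordinates Q_A = E_A / (n_A eps_A), Q_B = E_B / (n_B eps_B) are continuum
analogues of the fraction of native contacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from foldswitch.contacts import ConsensusMap

DEFAULT_EPS_B = -0.37
DEFAULT_EPS_RATIO = 0.96
DEFAULT_WELL_WIDTH = 0.5  # Angstrom


@dataclass
class SbmParams:
    """Strengths and width of the dual-basin potential.

    eps_A and eps_B are per-contact well depths (negative, dimensionless
    model units with k_B = 1); the calibrated baseline uses
    eps_B = -0.37 and eps_A = 0.96 * eps_B.
    """

    eps_B: float = DEFAULT_EPS_B
    eps_ratio: float = DEFAULT_EPS_RATIO
    w: float = DEFAULT_WELL_WIDTH

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("well width w must be > 0")
        if self.eps_B > 0 or self.eps_ratio < 0:
            raise ValueError("eps_B must be <= 0 and eps_ratio >= 0")

    @property
    def eps_A(self) -> float:
        return self.eps_ratio * self.eps_B


@dataclass
class ProgressPoint:
    E_A: float
    E_B: float
    Q_A: float
    Q_B: float


def contact_energy(r, d, w: float = DEFAULT_WELL_WIDTH, eps: float = -1.0):
    """Multi-Gaussian well energy for one contact; vectorized over r.

    ``d`` is the list of native distances from the contributing conformers.
    The value lies in [eps, 0) for finite r and equals eps exactly when r
    coincides with any native distance.
    """
    if w <= 0:
        raise ValueError("well width w must be > 0")
    d = np.atleast_1d(np.asarray(d, float))
    if d.size == 0:
        raise ValueError("need at least one native distance")
    r_arr = np.asarray(r, float)
    diff = r_arr[..., None] - d
    factors = 1.0 - np.exp(-(diff ** 2) / (2.0 * w * w))
    prod = np.prod(factors, axis=-1)
    out = eps * (1.0 - prod)
    return out if out.ndim else float(out)


def _contact_distances(ca: np.ndarray, cmap: ConsensusMap) -> np.ndarray:
    idx = cmap.pair_index
    if idx.size == 0:
        return np.zeros(0)
    vec = ca[idx[:, 0] - 1] - ca[idx[:, 1] - 1]
    return np.sqrt(np.sum(vec * vec, axis=1))


def _per_contact_energies(ca: np.ndarray, cmap: ConsensusMap,
                          eps: float, w: float) -> np.ndarray:
    r = _contact_distances(ca, cmap)
    if r.size == 0:
        return np.zeros(0)
    diff = r[:, None] - cmap.native_distances
    factors = 1.0 - np.exp(-(diff ** 2) / (2.0 * w * w))
    return eps * (1.0 - np.prod(factors, axis=1))


def _as_ca(conf) -> np.ndarray:
    """Accept a Structure, ChainCoords or raw (L, 3) CA array."""
    if hasattr(conf, "ca_coords"):
        return conf.ca_coords()
    if hasattr(conf, "ca"):
        return np.asarray(conf.ca, float)
    return np.asarray(conf, float)


def sbm_fold_energy(conf, cmap: ConsensusMap, eps: float,
                    w: float = DEFAULT_WELL_WIDTH) -> float:
    """Sum of multi-Gaussian contact energies over one fold's consensus map."""
    ca = _as_ca(conf)
    if len(ca) != cmap.length:
        raise ValueError(f"conformation length {len(ca)} != map length {cmap.length}")
    return float(np.sum(_per_contact_energies(ca, cmap, eps, w)))


def dual_sbm(conf, map_A: ConsensusMap, map_B: ConsensusMap,
             params: SbmParams) -> tuple[float, float, float]:
    """(E_A, E_B, E_SBM) with E_SBM = E_A + E_B."""
    e_a = sbm_fold_energy(conf, map_A, params.eps_A, params.w)
    e_b = sbm_fold_energy(conf, map_B, params.eps_B, params.w)
    return e_a, e_b, e_a + e_b


def progress(conf, map_A: ConsensusMap, map_B: ConsensusMap,
             params: SbmParams) -> ProgressPoint:
    """Q_A and Q_B, normalized by each map's fully-native energy."""
    if params.eps_A == 0 or params.eps_B == 0:
        raise ValueError("progress coordinates undefined for eps = 0")
    e_a, e_b, _ = dual_sbm(conf, map_A, map_B, params)
    q_a = e_a / (len(map_A) * params.eps_A)
    q_b = e_b / (len(map_B) * params.eps_B)
    return ProgressPoint(E_A=e_a, E_B=e_b, Q_A=q_a, Q_B=q_b)


def energy_table(d, w: float = DEFAULT_WELL_WIDTH, eps: float = -1.0,
                 r_min: float = 2.0, r_max: float = 15.0, n: int = 500):
    """(r grid, E_ij(r)) table for one contact, e.g. for well-shape plots."""
    r = np.linspace(r_min, r_max, n)
    return r, contact_energy(r, d, w, eps)


def lj_multiwell_oracle(r, d, eps: float = -1.0):
    """Summed Lennard-Jones construction used only as a comparison oracle.

    Sum over conformers s of one LJ well of depth |eps|/n_s with its
    minimum at the native distance d_s:
        (|eps|/n_s) * [ (d_s/r)^12 - 2 (d_s/r)^6 ].
    Unlike the Gaussian form, the r^-12 repulsion of a longer-distance well
    occludes any shorter-distance well.
    """
    d = np.atleast_1d(np.asarray(d, float))
    r_arr = np.atleast_1d(np.asarray(r, float))
    frac = d / r_arr[..., None]
    e = (abs(eps) / d.size) * (frac ** 12 - 2.0 * frac ** 6)
    out = np.sum(e, axis=-1)
    return out if np.ndim(r) else float(out)
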
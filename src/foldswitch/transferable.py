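"""Transferable (sequence-dependent) energy: contract, stand-in, pi-pi hook.

The hybrid energy is E_total = E_SBM + E_trans with
E_trans = E_local + E_EV + E_HB + E_SC + E_HP.  The structure-based
component is sequence independent, so all sequence discrimination between
fold-switch variants enters through these five transferable terms.

Any object with an ``evaluate(coords) -> dict`` method returning the five
named terms satisfies the contract and can drive the Monte Carlo engine.
Two implementations ship here:

* :class:`NullModel` — all terms zero (pure-SBM regime).
* :class:`StandinModel` — a deliberately simple physical stand-in on the
  reduced backbone + C-beta + sidechain-centroid representation: a
  torsion-angle bias toward the helical and extended basins (E_local), a
  truncated r^-12 repulsion (E_EV), a distance-and-orientation backbone
  hydrogen bond (E_HB), Debye-screened charge-charge interactions (E_SC),
  and a hydrophobic term counting contacting nonpolar sidechain pseudo-atom
  pairs (E_HP).  Every functional form and constant here is a package
  design choice documented in docs/methods.md, chosen for qualitative
  physical plausibility at desk scale.

``apply_pipi_override`` wraps any model exposing per-pair hydrophobic
terms so that the F-F, Y-Y and F-Y pair contributions to E_HP are replaced
by the orientation-dependent statistical potential E_pipi(r, theta, phi);
all other pairs (including anything involving Trp) are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from foldswitch.contacts import ConsensusMap
from foldswitch.geometry import ChainCoords, backbone_torsions
from foldswitch.pipi import PiPiPotential, RingGeometry, _acute, evaluate_pipi, pair_class_of
from foldswitch.sbm import SbmParams, dual_sbm
from foldswitch.sequences import CHARGE, HYDROPHOBIC, validate_sequence

TERM_NAMES = ("E_local", "E_EV", "E_HB", "E_SC", "E_HP")


@dataclass
class EnergyBreakdown:
    """Exactly additive decomposition of the hybrid energy."""

    E_A: float = 0.0
    E_B: float = 0.0
    E_local: float = 0.0
    E_EV: float = 0.0
    E_HB: float = 0.0
    E_SC: float = 0.0
    E_HP: float = 0.0

    @property
    def E_SBM(self) -> float:
        return self.E_A + self.E_B

    @property
    def E_trans(self) -> float:
        return self.E_local + self.E_EV + self.E_HB + self.E_SC + self.E_HP

    @property
    def E_total(self) -> float:
        return self.E_SBM + self.E_trans


class NullModel:
    """Transferable model with every term identically zero."""

    def evaluate(self, coords: ChainCoords) -> dict[str, float]:
        return {name: 0.0 for name in TERM_NAMES}


class StandinModel:
    """Simplified five-term transferable potential (see module docstring)."""

    def __init__(self, k_local: float = 0.4, k_ev: float = 1.0, k_hb: float = 0.5,
                 k_sc: float = 1.0, k_hp: float = 1.0,
                 sigma_ev: float = 2.5, hp_cutoff: float = 4.5,
                 debye_length: float = 10.0):
        self.k_local = k_local
        self.k_ev = k_ev
        self.k_hb = k_hb
        self.k_sc = k_sc
        self.k_hp = k_hp
        self.sigma_ev = sigma_ev
        self.hp_cutoff = hp_cutoff
        self.debye_length = debye_length

    # -- individual terms ---------------------------------------------------

    def e_local(self, coords: ChainCoords) -> float:
        """Per-residue (phi, psi) bias toward helical and extended regions."""
        phi, psi = backbone_torsions(coords)
        e = 0.0
        for basin_phi, basin_psi in ((-63.0, -43.0), (-120.0, 130.0)):
            dphi = _wrap(phi - basin_phi)
            dpsi = _wrap(psi - basin_psi)
            g = np.exp(-(dphi ** 2 + dpsi ** 2) / (2.0 * 25.0 ** 2))
            e -= self.k_local * np.nansum(g)
        return float(e)

    @staticmethod
    def _nonbonded_pairs(coords: ChainCoords):
        """All CA/CB/SC atom pairs from residues at least two apart."""
        L = len(coords)
        atoms = np.concatenate([coords.ca, coords.cb, coords.sc])
        owner = np.tile(np.arange(L), 3)
        ii, jj = np.triu_indices(len(atoms), k=1)
        keep = np.abs(owner[ii] - owner[jj]) >= 2
        ii, jj = ii[keep], jj[keep]
        d = np.linalg.norm(atoms[ii] - atoms[jj], axis=1)
        return d

    def e_ev(self, coords: ChainCoords) -> float:
        """Truncated r^-12 repulsion over nonbonded reduced-atom pairs."""
        d = self._nonbonded_pairs(coords)
        d = d[d < 2.0 * self.sigma_ev]
        if d.size == 0:
            return 0.0
        d = np.maximum(d, 1.2)  # clamp against singular overlap
        return float(self.k_ev * np.sum((self.sigma_ev / d) ** 12))

    def e_hb(self, coords: ChainCoords) -> float:
        """Backbone N(i)...O=C(j) hydrogen bond, distance x orientation."""
        L = len(coords)
        i_idx, j_idx = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
        mask = np.abs(i_idx - j_idx) >= 2
        no = coords.n[i_idx] - coords.o[j_idx]        # O_j -> N_i
        r = np.linalg.norm(no, axis=-1)
        radial = np.exp(-((r - 2.95) ** 2) / (2.0 * 0.3 ** 2))
        co = coords.o[j_idx] - coords.c[j_idx]        # C_j -> O_j
        cosang = np.sum(no * co, axis=-1) / np.maximum(
            r * np.linalg.norm(co, axis=-1), 1e-9)
        orient = np.clip(cosang, 0.0, None) ** 2
        return float(-self.k_hb * np.sum(radial * orient * mask))

    def e_sc(self, coords: ChainCoords) -> float:
        """Debye-screened Coulomb term between charged sidechain centroids."""
        q = np.array([CHARGE[aa] for aa in coords.sequence])
        charged = np.nonzero(q)[0]
        e = 0.0
        for a in range(len(charged)):
            for b in range(a + 1, len(charged)):
                i, j = charged[a], charged[b]
                if j - i < 2:
                    continue
                r = max(float(np.linalg.norm(coords.sc[i] - coords.sc[j])), 1.0)
                e += q[i] * q[j] / r * np.exp(-r / self.debye_length)
        return float(self.k_sc * e)

    def hp_pair_matrix(self, coords: ChainCoords) -> list[tuple[int, int, float]]:
        """Per-pair hydrophobic contributions [(i, j, energy), ...] (0-based)."""
        seq = coords.sequence
        idx = [i for i, aa in enumerate(seq) if aa in HYDROPHOBIC]
        pairs = []
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = idx[a], idx[b]
                if j - i < 2:
                    continue
                r = float(np.linalg.norm(coords.sc[i] - coords.sc[j]))
                if r <= self.hp_cutoff:
                    pairs.append((i, j, -self.k_hp))
        return pairs

    def e_hp(self, coords: ChainCoords) -> float:
        """-k_hp x (number of contacting nonpolar sidechain pseudo-atom pairs)."""
        return float(sum(e for _, _, e in self.hp_pair_matrix(coords)))

    def evaluate(self, coords: ChainCoords) -> dict[str, float]:
        # zero-strength terms are skipped, not evaluated
        return {
            "E_local": self.e_local(coords) if self.k_local else 0.0,
            "E_EV": self.e_ev(coords) if self.k_ev else 0.0,
            "E_HB": self.e_hb(coords) if self.k_hb else 0.0,
            "E_SC": self.e_sc(coords) if self.k_sc else 0.0,
            "E_HP": self.e_hp(coords) if self.k_hp else 0.0,
        }


def _wrap(delta_deg: np.ndarray) -> np.ndarray:
    """Angular difference folded into (-180, 180]."""
    return (np.asarray(delta_deg) + 180.0) % 360.0 - 180.0


class PipiOverrideModel:
    """Wrap a model so F/Y hydrophobic pair terms become E_pipi(r, theta, phi).

    On the reduced representation the ring center is the sidechain centroid
    and the ring pseudo-normal is derived from the local sidechain frame,
    so the geometry is a coarse proxy for the true ring geometry.
    """

    def __init__(self, base, potentials: dict[str, PiPiPotential]):
        self.base = base
        self.potentials = potentials

    def _pair_geometry(self, coords: ChainCoords, i: int, j: int) -> RingGeometry | None:
        sep = coords.sc[j] - coords.sc[i]
        r = float(np.linalg.norm(sep))
        if r < 1e-9:
            return None
        n1, n2 = coords.ring_normal[i], coords.ring_normal[j]
        if np.any(np.isnan(n1)) or np.any(np.isnan(n2)):
            return None
        theta = _acute(np.degrees(np.arccos(np.clip(abs(np.dot(n1, n2)), 0, 1))))
        u = sep / r
        phi1 = _acute(np.degrees(np.arccos(np.clip(abs(np.dot(n1, u)), 0, 1))))
        phi2 = _acute(np.degrees(np.arccos(np.clip(abs(np.dot(n2, u)), 0, 1))))
        return RingGeometry(r=r, theta=theta, phi=0.5 * (phi1 + phi2))

    def evaluate(self, coords: ChainCoords) -> dict[str, float]:
        terms = dict(self.base.evaluate(coords))
        seq = coords.sequence
        e_hp = terms["E_HP"]
        for i, j, pair_e in self.base.hp_pair_matrix(coords):
            a1, a2 = seq[i], seq[j]
            if a1 not in "FY" or a2 not in "FY":
                continue
            e_hp -= pair_e  # remove the hydrophobic contribution
            geom = self._pair_geometry(coords, i, j)
            if geom is not None:
                pot = self.potentials[pair_class_of(a1, a2)]
                e_hp += evaluate_pipi(pot, geom)
        terms["E_HP"] = e_hp
        return terms


def apply_pipi_override(model, pipi) -> PipiOverrideModel:
    """Return a model whose F-F / Y-Y / F-Y pair energies use ``pipi``.

    ``pipi`` is either a single :class:`PiPiPotential` (applied to all three
    residue-type classes) or a mapping from pair class to potential.
    """
    if isinstance(pipi, PiPiPotential):
        potentials = {cls: pipi for cls in ("F-F", "Y-Y", "F-Y")}
    else:
        potentials = dict(pipi)
    if all(not np.any(p.energy) for p in potentials.values()):
        raise ValueError("pi-pi table is empty (all-zero energies)")
    if not hasattr(model, "hp_pair_matrix"):
        raise TypeError("model does not expose per-pair hydrophobic terms")
    return PipiOverrideModel(model, potentials)


def resolve_model(spec):
    """Map a config value (none | standin | model object) to a model."""
    if spec is None or spec == "none":
        return NullModel()
    if spec == "standin":
        return StandinModel()
    if hasattr(spec, "evaluate"):
        return spec
    raise ValueError(f"unknown transferable model {spec!r}")


def _as_coords(conf) -> ChainCoords:
    if isinstance(conf, ChainCoords):
        return conf
    if hasattr(conf, "coords"):
        return conf.coords
    raise TypeError("expected ChainCoords or an object with .coords")


def evaluate_transferable(conf, sequence: str | None, model) -> dict[str, float]:
    """The five transferable terms for one conformation."""
    coords = _as_coords(conf)
    if sequence is not None and validate_sequence(sequence) != coords.sequence:
        raise ValueError("sequence does not match the conformation")
    model = resolve_model(model)
    return model.evaluate(coords)


def total_energy(conf, sequence: str | None, map_A: ConsensusMap,
                 map_B: ConsensusMap, sbm_params: SbmParams, model) -> EnergyBreakdown:
    """Full breakdown E_total = E_A + E_B + five transferable terms."""
    coords = _as_coords(conf)
    e_a, e_b, _ = dual_sbm(coords.ca, map_A, map_B, sbm_params)
    terms = evaluate_transferable(coords, sequence, model)
    return EnergyBreakdown(E_A=e_a, E_B=e_b, **terms)
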
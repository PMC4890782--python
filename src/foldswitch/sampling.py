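"""Metropolis Monte Carlo sampling of the hybrid dual-basin energy.

Chains live in torsion space (bond lengths and angles fixed); time is
propagated in MC cycles, each consisting of ``count_dof(sequence)``
elementary updates so that on average every rotational degree of freedom
is perturbed once per cycle.  The move set combines single backbone
torsion pivots, sidechain torsion rotations, and symmetric correlated
multi-torsion window moves (a semi-local stand-in for biased Gaussian
steps; the proposal density is symmetric, so the plain Metropolis ratio
preserves detailed balance).  Replica exchange is supported over a
temperature ladder (parallel tempering) or over a ladder of SBM strengths
at fixed temperature (Hamiltonian replica exchange), with adjacent-pair
swaps attempted every ``exchange_interval`` cycles, alternating even/odd
pairings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from foldswitch.contacts import ConsensusMap
from foldswitch.geometry import ChainCoords, build_chain
from foldswitch.sbm import SbmParams, dual_sbm
from foldswitch.sequences import (
    SIDECHAIN_CENTROID_DIST,
    SIDECHAIN_TORSIONS,
    validate_sequence,
)
from foldswitch.transferable import EnergyBreakdown, resolve_model

PRO_PHI = -65.0  # frozen proline backbone phi


def count_dof(sequence: str) -> int:
    """Number of free rotational degrees of freedom of a chain.

    Two backbone torsions (phi, psi) per residue with the proline phi
    frozen, plus the per-residue-type sidechain torsion counts of the
    calibrated rotor table (chi angles and terminal single-bond rotors).
    For the GA98 / GB98 fold-switch pair this gives 283 and 282.
    """
    seq = validate_sequence(sequence)
    backbone = sum(1 if aa == "P" else 2 for aa in seq)
    sidechain = sum(SIDECHAIN_TORSIONS[aa] for aa in seq)
    return backbone + sidechain


class Conformation:
    """Torsional state of a chain; coordinates are derived deterministically."""

    def __init__(self, sequence: str, phi, psi, chi=None):
        self.sequence = validate_sequence(sequence)
        L = len(self.sequence)
        self.phi = np.array(phi, float)
        self.psi = np.array(psi, float)
        self.chi = np.zeros(L) if chi is None else np.array(chi, float)
        if self.phi.shape != (L,) or self.psi.shape != (L,) or self.chi.shape != (L,):
            raise ValueError("torsion array length mismatch")
        for i, aa in enumerate(self.sequence):
            if aa == "P":
                self.phi[i] = PRO_PHI
        self._coords: ChainCoords | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def coords(self) -> ChainCoords:
        if self._coords is None:
            self._coords = build_chain(self.sequence, self.phi, self.psi, self.chi)
        return self._coords

    def invalidate(self) -> None:
        self._coords = None

    def copy(self) -> "Conformation":
        c = Conformation(self.sequence, self.phi.copy(), self.psi.copy(), self.chi.copy())
        c._coords = self._coords
        return c

    def movable_torsions(self) -> list[tuple[str, int]]:
        """Torsions the move set may touch: ('phi'|'psi'|'chi', residue)."""
        out: list[tuple[str, int]] = []
        for i, aa in enumerate(self.sequence):
            if aa != "P":
                out.append(("phi", i))
            out.append(("psi", i))
            if SIDECHAIN_CENTROID_DIST[aa] > 0.0:
                out.append(("chi", i))
        return out


def random_conformation(sequence: str, rng: np.random.Generator) -> Conformation:
    """Random chain with torsions drawn from sterically common ranges."""
    seq = validate_sequence(sequence)
    L = len(seq)
    phi = rng.uniform(-160.0, -50.0, L)
    psi = rng.uniform(-70.0, 170.0, L)
    chi = rng.uniform(-180.0, 180.0, L)
    return Conformation(seq, phi, psi, chi)


class HybridModel:
    """Bundle of consensus maps, SBM parameters and a transferable model."""

    def __init__(self, map_A: ConsensusMap, map_B: ConsensusMap,
                 sbm_params: SbmParams | None = None, transferable="none"):
        self.map_A = map_A
        self.map_B = map_B
        self.sbm_params = sbm_params if sbm_params is not None else SbmParams()
        self.transferable = resolve_model(transferable)

    def breakdown(self, conf: Conformation) -> EnergyBreakdown:
        coords = conf.coords
        e_a, e_b, _ = dual_sbm(coords.ca, self.map_A, self.map_B, self.sbm_params)
        terms = self.transferable.evaluate(coords)
        return EnergyBreakdown(E_A=e_a, E_B=e_b, **terms)

    def energy(self, conf: Conformation) -> float:
        return self.breakdown(conf).E_total

    def q_values(self, bd: EnergyBreakdown) -> tuple[float, float]:
        p = self.sbm_params
        n_a, n_b = len(self.map_A), len(self.map_B)
        q_a = bd.E_A / (n_a * p.eps_A) if n_a and p.eps_A else 0.0
        q_b = bd.E_B / (n_b * p.eps_B) if n_b and p.eps_B else 0.0
        return q_a, q_b


@dataclass
class Trajectory:
    """Recorded observables of one run; cycles strictly increasing."""

    T: float
    seed: int
    cycles: list[int] = field(default_factory=list)
    E_total: list[float] = field(default_factory=list)
    E_A: list[float] = field(default_factory=list)
    E_B: list[float] = field(default_factory=list)
    E_local: list[float] = field(default_factory=list)
    E_EV: list[float] = field(default_factory=list)
    E_HB: list[float] = field(default_factory=list)
    E_SC: list[float] = field(default_factory=list)
    E_HP: list[float] = field(default_factory=list)
    Q_A: list[float] = field(default_factory=list)
    Q_B: list[float] = field(default_factory=list)
    snapshots: list[Conformation] | None = None
    eps_B: float | None = None   # set for Hamiltonian-exchange rungs

    FIELDS = ("cycles", "E_total", "E_A", "E_B", "E_local", "E_EV", "E_HB",
              "E_SC", "E_HP", "Q_A", "Q_B")

    def record(self, cycle: int, bd: EnergyBreakdown, q_a: float, q_b: float,
               conf: Conformation | None = None) -> None:
        self.cycles.append(cycle)
        self.E_total.append(bd.E_total)
        self.E_A.append(bd.E_A)
        self.E_B.append(bd.E_B)
        self.E_local.append(bd.E_local)
        self.E_EV.append(bd.E_EV)
        self.E_HB.append(bd.E_HB)
        self.E_SC.append(bd.E_SC)
        self.E_HP.append(bd.E_HP)
        self.Q_A.append(q_a)
        self.Q_B.append(q_b)
        if self.snapshots is not None and conf is not None:
            self.snapshots.append(conf.copy())

    def __len__(self) -> int:
        return len(self.cycles)

    def arrays(self) -> dict[str, np.ndarray]:
        return {k: np.asarray(getattr(self, k)) for k in self.FIELDS}


@dataclass
class ReplicaSet:
    """One trajectory per ladder rung plus exchange bookkeeping."""

    ladder: list[float]                 # temperatures, or eps_B values
    kind: str                           # "temperature" | "hamiltonian"
    trajectories: list[Trajectory]
    exchange_attempted: int = 0
    exchange_accepted: int = 0
    # (cycle, attempted, accepted) per exchange interval
    exchange_log: list[tuple[int, int, int]] = field(default_factory=list)
    # replica identity currently at each rung; a permutation at all times
    replica_at_rung: list[int] = field(default_factory=list)

    @property
    def acceptance_rate(self) -> float:
        if self.exchange_attempted == 0:
            return float("nan")
        return self.exchange_accepted / self.exchange_attempted


def _propose(conf: Conformation, movable, rng: np.random.Generator) -> Conformation:
    """One symmetric elementary move; returns a trial conformation."""
    trial = conf.copy()
    trial._coords = None
    u = rng.random()
    if u < 0.70:
        # single-torsion pivot: small Gaussian step or full re-draw
        kind, i = movable[rng.integers(len(movable))]
        arr = getattr(trial, kind)
        if rng.random() < 0.8:
            arr[i] += rng.normal(0.0, 25.0)
        else:
            arr[i] = rng.uniform(-180.0, 180.0)
        arr[i] = (arr[i] + 180.0) % 360.0 - 180.0
    else:
        # correlated window move over consecutive backbone torsions
        L = len(conf)
        start = int(rng.integers(L))
        width = int(rng.integers(1, min(4, L - start) + 1))
        step = rng.normal(0.0, 6.0)
        for i in range(start, start + width):
            if conf.sequence[i] != "P":
                trial.phi[i] = (trial.phi[i] + step + 180.0) % 360.0 - 180.0
            trial.psi[i] = (trial.psi[i] - step + 180.0) % 360.0 - 180.0
    for i, aa in enumerate(trial.sequence):
        if aa == "P":
            trial.phi[i] = PRO_PHI
    return trial


def mc_cycle(conf: Conformation, T: float, model: HybridModel,
             rng: np.random.Generator, current_energy: float | None = None,
             n_updates: int | None = None) -> tuple[Conformation, float, int]:
    """One MC cycle: ``count_dof`` elementary Metropolis updates.

    Returns (conformation, energy, number of accepted updates).  A move
    producing a non-finite energy is rejected outright.
    """
    if n_updates is None:
        n_updates = count_dof(conf.sequence)
    movable = conf.movable_torsions()
    e = model.energy(conf) if current_energy is None else current_energy
    accepted = 0
    beta = np.inf if T == 0 else 1.0 / T
    for _ in range(n_updates):
        trial = _propose(conf, movable, rng)
        e_new = model.energy(trial)
        if not np.isfinite(e_new):
            continue
        de = e_new - e
        if de <= 0 or (np.isfinite(beta) and rng.random() < np.exp(-beta * de)):
            conf, e = trial, e_new
            accepted += 1
    return conf, e, accepted


def _relax(conf: Conformation, model: HybridModel, rng: np.random.Generator,
           n_cycles: int = 2) -> tuple[Conformation, float]:
    """Short zero-temperature descent to remove initial-state clashes."""
    e = model.energy(conf)
    for _ in range(n_cycles):
        conf, e, _ = mc_cycle(conf, 0.0, model, rng, current_energy=e)
    return conf, e


def run_constant_T(sequence: str, maps, params: SbmParams, T: float,
                   n_cycles: int, seed: int, transferable="none",
                   record_stride: int = 1, record_snapshots: bool = False,
                   initial: Conformation | None = None,
                   model: HybridModel | None = None) -> Trajectory:
    """Constant-temperature run from a random initial conformation.

    ``maps`` is the (map_A, map_B) pair.  Deterministic for a fixed seed.
    ``n_cycles = 0`` records the (relaxed) initial state only.
    """
    if model is None:
        map_a, map_b = maps
        model = HybridModel(map_a, map_b, params, transferable)
    rng = np.random.default_rng(seed)
    conf = random_conformation(sequence, rng) if initial is None else initial.copy()
    conf, e = _relax(conf, model, rng)
    traj = Trajectory(T=T, seed=seed,
                      snapshots=[] if record_snapshots else None)
    bd = model.breakdown(conf)
    traj.record(0, bd, *model.q_values(bd), conf)
    for cycle in range(1, n_cycles + 1):
        conf, e, _ = mc_cycle(conf, T, model, rng, current_energy=e)
        if cycle % record_stride == 0:
            bd = model.breakdown(conf)
            traj.record(cycle, bd, *model.q_values(bd), conf)
    return traj


def _replica_exchange(sequence: str, models: list[HybridModel],
                      temperatures: list[float], n_cycles: int,
                      exchange_interval: int, seed: int,
                      record_stride: int, record_snapshots: bool,
                      kind: str, ladder: list[float]) -> ReplicaSet:
    n_rep = len(models)
    rng = np.random.default_rng(seed)
    confs = []
    energies = []
    for k in range(n_rep):
        c = random_conformation(sequence, rng)
        c, e = _relax(c, models[k], rng)
        confs.append(c)
        energies.append(e)
    trajs = [Trajectory(T=temperatures[k], seed=seed,
                        eps_B=(ladder[k] if kind == "hamiltonian" else None),
                        snapshots=[] if record_snapshots else None)
             for k in range(n_rep)]
    rs = ReplicaSet(ladder=list(ladder), kind=kind, trajectories=trajs,
                    replica_at_rung=list(range(n_rep)))
    for k in range(n_rep):
        bd = models[k].breakdown(confs[k])
        trajs[k].record(0, bd, *models[k].q_values(bd), confs[k])

    parity = 0
    for cycle in range(1, n_cycles + 1):
        for k in range(n_rep):
            confs[k], energies[k], _ = mc_cycle(
                confs[k], temperatures[k], models[k], rng,
                current_energy=energies[k])
        if cycle % exchange_interval == 0:
            interval_attempted = interval_accepted = 0
            for k in range(parity, n_rep - 1, 2):
                rs.exchange_attempted += 1
                interval_attempted += 1
                beta_k = 1.0 / temperatures[k]
                beta_l = 1.0 / temperatures[k + 1]
                if kind == "temperature":
                    log_p = (beta_k - beta_l) * (energies[k] - energies[k + 1])
                else:
                    e_cross = (models[k].energy(confs[k + 1]) +
                               models[k + 1].energy(confs[k]))
                    e_same = energies[k] + energies[k + 1]
                    log_p = -beta_k * (e_cross - e_same)
                if log_p >= 0 or rng.random() < np.exp(log_p):
                    rs.exchange_accepted += 1
                    interval_accepted += 1
                    confs[k], confs[k + 1] = confs[k + 1], confs[k]
                    if kind == "temperature":
                        energies[k], energies[k + 1] = energies[k + 1], energies[k]
                    else:
                        energies[k] = models[k].energy(confs[k])
                        energies[k + 1] = models[k + 1].energy(confs[k + 1])
                    rs.replica_at_rung[k], rs.replica_at_rung[k + 1] = (
                        rs.replica_at_rung[k + 1], rs.replica_at_rung[k])
            rs.exchange_log.append((cycle, interval_attempted, interval_accepted))
            parity = 1 - parity
        if cycle % record_stride == 0:
            for k in range(n_rep):
                bd = models[k].breakdown(confs[k])
                trajs[k].record(cycle, bd, *models[k].q_values(bd), confs[k])
    return rs


def parallel_tempering(sequence: str, maps, params: SbmParams,
                       ladder: list[float], n_cycles: int,
                       exchange_interval: int = 5000, seed: int = 0,
                       transferable="none", record_stride: int = 1,
                       record_snapshots: bool = False) -> ReplicaSet:
    """Temperature replica exchange over a sorted ladder of temperatures."""
    ladder = list(ladder)
    if len(ladder) < 2:
        raise ValueError("temperature ladder needs at least two rungs")
    if sorted(ladder) != ladder:
        raise ValueError("temperature ladder must be sorted ascending")
    map_a, map_b = maps
    model = HybridModel(map_a, map_b, params, transferable)
    models = [model] * len(ladder)
    return _replica_exchange(sequence, models, ladder, n_cycles,
                             exchange_interval, seed, record_stride,
                             record_snapshots, "temperature", ladder)


def hamiltonian_replica_exchange(sequence: str, maps, eps_ladder: list[float],
                                 T: float, n_cycles: int,
                                 exchange_interval: int = 5000, seed: int = 0,
                                 transferable="none", record_stride: int = 1,
                                 record_snapshots: bool = False,
                                 eps_ratio: float = 0.96,
                                 w: float = 0.5) -> ReplicaSet:
    """Replica exchange over SBM strengths eps_B at fixed temperature."""
    eps_ladder = list(eps_ladder)
    if len(eps_ladder) < 2:
        raise ValueError("eps ladder needs at least two rungs")
    map_a, map_b = maps
    models = [HybridModel(map_a, map_b,
                          SbmParams(eps_B=eps, eps_ratio=eps_ratio, w=w),
                          transferable)
              for eps in eps_ladder]
    temperatures = [T] * len(eps_ladder)
    return _replica_exchange(sequence, models, temperatures, n_cycles,
                             exchange_interval, seed, record_stride,
                             record_snapshots, "hamiltonian", eps_ladder)


def temperature_ladder(t_min: float, t_max: float, n: int) -> list[float]:
    """Geometric temperature ladder (constant beta ratio between rungs)."""
    if not (0 < t_min < t_max) or n < 2:
        raise ValueError("need 0 < t_min < t_max and n >= 2")
    return list(np.geomspace(t_min, t_max, n))
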
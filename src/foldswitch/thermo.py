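"""Thermodynamic post-processing: C_V(T), WHAM, (Q_A, Q_B) landscapes.

Free energies are in units of k_B T and defined as the negative natural
logarithm of the (weighted) sampled population, with the lowest occupied
grid bin normalized to zero.  Basin populations follow the standard basin
boxes: G_A is Q_A >= 0.6 and Q_B < 0.6, G_B is Q_B >= 0.6 and Q_A < 0.6,
and dF(G_A - G_B) = -ln(P_A / P_B), negative values favoring G_A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from foldswitch.sampling import ReplicaSet

DEFAULT_BURN_IN = 0.30
DEFAULT_GRID = (100, 100)
Q_RANGE = (0.0, 1.05)  # slight overshoot accommodates Q marginally above 1

# Analysis-box presets over (Q_A, Q_B); values are ((lo_A, hi_A), (lo_B, hi_B)).
REGION_PRESETS = {
    "TS-GA": ((0.66, 0.74), (0.12, 0.22)),
    "TS1-GB": ((0.30, 0.55), (0.35, 0.43)),
    "TS2-GB": ((0.28, 0.40), (0.58, 0.66)),
}
# Unfolded-state boxes used by contact-frequency and energy-share analyses.
UNFOLDED_CONTACTS = ((0.0, 0.6), (0.0, 0.3))


class WhamConvergenceError(RuntimeError):
    """WHAM fixed point failed; carries overlap diagnostics."""

    def __init__(self, message: str, diagnostics: dict):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass
class HeatCapacityCurve:
    temperatures: np.ndarray
    C_V: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, float)
        self.C_V = np.asarray(self.C_V, float)
        if self.temperatures.shape != self.C_V.shape:
            raise ValueError("temperature and C_V arrays differ in length")

    @property
    def T_m(self) -> float:
        """Melting temperature: location of the heat-capacity maximum."""
        return float(self.temperatures[int(np.argmax(self.C_V))])


@dataclass
class WeightedSamples:
    """Per-sample (Q_A, Q_B, E_total) with normalized reweighting weights."""

    Q_A: np.ndarray
    Q_B: np.ndarray
    E_total: np.ndarray
    weights: np.ndarray
    T: float

    def __post_init__(self) -> None:
        n = len(self.Q_A)
        for name in ("Q_B", "E_total", "weights"):
            if len(getattr(self, name)) != n:
                raise ValueError("sample arrays differ in length")
        total = self.weights.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("weights must sum to a positive finite value")
        self.weights = self.weights / total

    def __len__(self) -> int:
        return len(self.Q_A)


@dataclass
class Landscape:
    """Free energy over a (Q_A, Q_B) grid; empty bins are +inf."""

    F: np.ndarray
    q_a_edges: np.ndarray
    q_b_edges: np.ndarray
    T: float

    def __post_init__(self) -> None:
        occ = np.isfinite(self.F)
        if occ.any() and abs(float(np.min(self.F[occ]))) > 1e-9:
            raise ValueError("landscape must be normalized to min = 0")


@dataclass
class DifferenceLandscape:
    """Per-bin F2 - F1; bins unoccupied in either input are NaN."""

    delta: np.ndarray
    q_a_edges: np.ndarray
    q_b_edges: np.ndarray


@dataclass
class BasinStats:
    P_A: float
    P_B: float
    dF: float
    degenerate: bool = False  # an empty basin made dF infinite


def heat_capacity(samples_by_T: dict[float, np.ndarray], k_B: float = 1.0) -> HeatCapacityCurve:
    """C_V(T) = (<E^2> - <E>^2) / (k_B T^2) from per-temperature energies."""
    temps = sorted(samples_by_T)
    cv = []
    for T in temps:
        e = np.asarray(samples_by_T[T], float)
        if e.size < 2:
            raise ValueError(f"need >= 2 energy samples at T = {T}")
        cv.append(np.var(e) / (k_B * T * T))
    return HeatCapacityCurve(np.array(temps), np.array(cv))


def burn_in_slice(n_records: int, burn_in_fraction: float) -> slice:
    """Records retained after discarding the leading burn-in fraction."""
    if not 0.0 <= burn_in_fraction < 1.0:
        raise ValueError("burn_in_fraction must be in [0, 1)")
    return slice(int(burn_in_fraction * n_records), None)


def wham_free_energies(energies: list[np.ndarray], temperatures: list[float],
                       tol: float = 1e-10, max_iter: int = 100000) -> np.ndarray:
    """Self-consistent dimensionless free-energy offsets f_k of each run.

    Binless WHAM: iterate
        f_k = -ln sum_x exp(-beta_k E_x) / sum_l N_l exp(f_l - beta_l E_x)
    over the pooled samples x until the offsets are stationary.
    """
    betas = 1.0 / np.asarray(temperatures, float)
    n_runs = len(energies)
    counts = np.array([len(e) for e in energies], float)
    pooled = np.concatenate([np.asarray(e, float) for e in energies])
    # (n_runs, n_samples) matrix of -beta_k * E_x
    neg_be = -betas[:, None] * pooled[None, :]
    f = np.zeros(n_runs)
    for _ in range(max_iter):
        # log denominator per sample: ln sum_l N_l exp(f_l - beta_l E_x)
        log_den = logsumexp(neg_be + f[:, None] + np.log(counts)[:, None], axis=0)
        f_new = -logsumexp(neg_be - log_den[None, :], axis=1)
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f)) < tol:
            return f_new
        f = f_new
    diag = {
        "energy_ranges": [(float(np.min(e)), float(np.max(e))) for e in energies],
        "temperatures": list(map(float, temperatures)),
        "hint": "adjacent runs may have non-overlapping energy histograms",
    }
    raise WhamConvergenceError("WHAM fixed point did not converge", diag)


def wham_sample_weights(energies: list[np.ndarray], temperatures: list[float],
                        T_target: float, **kwargs) -> np.ndarray:
    """Normalized per-sample weights at T_target over the pooled samples."""
    if len(energies) == 1:
        e = np.asarray(energies[0], float)
        if abs(temperatures[0] - T_target) > 1e-12:
            logw = -(1.0 / T_target - 1.0 / temperatures[0]) * e
            w = np.exp(logw - logw.max())
            return w / w.sum()
        return np.full(len(e), 1.0 / len(e))
    f = wham_free_energies(energies, temperatures, **kwargs)
    betas = 1.0 / np.asarray(temperatures, float)
    counts = np.array([len(e) for e in energies], float)
    pooled = np.concatenate([np.asarray(e, float) for e in energies])
    log_den = logsumexp(-betas[:, None] * pooled[None, :] + f[:, None]
                        + np.log(counts)[:, None], axis=0)
    logw = -pooled / T_target - log_den
    w = np.exp(logw - logw.max())
    return w / w.sum()


def wham_reweight(rs: ReplicaSet, T_target: float,
                  burn_in_fraction: float = DEFAULT_BURN_IN,
                  **kwargs) -> WeightedSamples:
    """WHAM-reweight a temperature replica set to ``T_target``.

    The leading ``burn_in_fraction`` of every rung's records is discarded
    before pooling.  A single-rung set at T_target reduces to uniform
    weights (identity).
    """
    if rs.kind != "temperature":
        raise ValueError("WHAM reweighting applies to temperature replica sets")
    energies, q_a, q_b = [], [], []
    for traj in rs.trajectories:
        arr = traj.arrays()
        keep = burn_in_slice(len(traj), burn_in_fraction)
        energies.append(arr["E_total"][keep])
        q_a.append(arr["Q_A"][keep])
        q_b.append(arr["Q_B"][keep])
    weights = wham_sample_weights(energies, list(rs.ladder), T_target, **kwargs)
    return WeightedSamples(Q_A=np.concatenate(q_a), Q_B=np.concatenate(q_b),
                           E_total=np.concatenate(energies), weights=weights,
                           T=T_target)


def _as_qw(samples) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(samples, WeightedSamples):
        return samples.Q_A, samples.Q_B, samples.weights
    q_a, q_b, w = samples
    q_a = np.asarray(q_a, float)
    if len(q_a) == 0:
        raise ValueError("no samples")
    w = np.full(len(q_a), 1.0 / len(q_a)) if w is None else np.asarray(w, float)
    return q_a, np.asarray(q_b, float), w / w.sum()


def free_energy_landscape(samples, grid_shape: tuple[int, int] = DEFAULT_GRID,
                          T: float = float("nan")) -> Landscape:
    """F(bin) = -ln(weighted population), minimum shifted to zero.

    ``samples`` is a :class:`WeightedSamples` or a (Q_A, Q_B, weights)
    triple (weights None for uniform).  Unoccupied bins are +inf.
    """
    q_a, q_b, w = _as_qw(samples)
    if len(q_a) == 0:
        raise ValueError("no samples")
    if isinstance(samples, WeightedSamples):
        T = samples.T
    hist, a_edges, b_edges = np.histogram2d(
        q_a, q_b, bins=grid_shape, range=(Q_RANGE, Q_RANGE), weights=w)
    with np.errstate(divide="ignore"):
        F = -np.log(hist)
    F -= np.min(F)
    return Landscape(F=F, q_a_edges=a_edges, q_b_edges=b_edges, T=T)


def basin_stats(samples) -> BasinStats:
    """Populations of the two native basins and dF(G_A - G_B) = -ln(P_A/P_B)."""
    q_a, q_b, w = _as_qw(samples)
    if len(q_a) == 0:
        raise ValueError("no samples")
    in_a = (q_a >= 0.6) & (q_b < 0.6)
    in_b = (q_b >= 0.6) & (q_a < 0.6)
    p_a = float(np.sum(w[in_a]))
    p_b = float(np.sum(w[in_b]))
    if p_a == 0.0 and p_b == 0.0:
        return BasinStats(P_A=0.0, P_B=0.0, dF=float("nan"), degenerate=True)
    if p_a == 0.0:
        return BasinStats(P_A=0.0, P_B=p_b, dF=float("inf"), degenerate=True)
    if p_b == 0.0:
        return BasinStats(P_A=p_a, P_B=0.0, dF=float("-inf"), degenerate=True)
    return BasinStats(P_A=p_a, P_B=p_b, dF=float(-np.log(p_a / p_b)))


def difference_landscape(l1: Landscape, l2: Landscape) -> DifferenceLandscape:
    """Per-bin F2 - F1; bins unoccupied in either landscape are masked NaN."""
    if l1.F.shape != l2.F.shape:
        raise ValueError("landscape grids differ in shape")
    if not (np.allclose(l1.q_a_edges, l2.q_a_edges)
            and np.allclose(l1.q_b_edges, l2.q_b_edges)):
        raise ValueError("landscape grids differ in bin edges")
    both = np.isfinite(l1.F) & np.isfinite(l2.F)
    delta = np.full_like(l1.F, np.nan)
    delta[both] = l2.F[both] - l1.F[both]
    return DifferenceLandscape(delta=delta, q_a_edges=l1.q_a_edges,
                               q_b_edges=l1.q_b_edges)


def landscape_to_tsv(landscape: Landscape, path) -> None:
    """Dense matrix TSV with a grid-spec header (rows = Q_A bins)."""
    header = (f"# T={landscape.T} grid={landscape.F.shape[0]}x{landscape.F.shape[1]} "
              f"q_range=[{Q_RANGE[0]},{Q_RANGE[1]}]")
    np.savetxt(path, landscape.F, delimiter="\t", header=header, comments="")
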
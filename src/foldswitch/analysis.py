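"""Superposition-map clustering and mutation-shift analyses.

A sampled conformation is represented by a 4L-dimensional superposition
vector: per-residue CA distances to an optimally superposed reference
structure of fold A, CA distances to a superposed reference of fold B,
then the corresponding CB distances to each reference.  RMSD_sm, the root
mean square difference of two such vectors, is the distance measure for
k-means clustering, centroid graphs and transition-state dissection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from foldswitch.contacts import ConsensusMap, build_contact_map
from foldswitch.geometry import kabsch
from foldswitch.structures import Structure, structure_from_chain

DEFAULT_K = 50
DEFAULT_EDGE_THRESHOLD = 5.75  # Angstrom, centroid-graph connectivity


def _ca_cb(obj, gly_policy: str = "calpha") -> tuple[np.ndarray, np.ndarray]:
    if isinstance(obj, Structure):
        return obj.ca_coords(), obj.cb_coords(gly_policy)
    coords = obj.coords if hasattr(obj, "coords") else obj
    return np.asarray(coords.ca, float), np.asarray(coords.cb, float)


def superposition_vector(conf, ref_A, ref_B, gly_policy: str = "calpha") -> np.ndarray:
    """4L-component superposition-map vector of one conformation.

    Each reference is rigidly superposed onto the conformation by CA
    least squares before the per-residue CA and CB distances are taken;
    Gly CB substitutes CA under the default policy.
    """
    ca, cb = _ca_cb(conf, gly_policy)
    L = len(ca)
    parts_ca, parts_cb = [], []
    for ref in (ref_A, ref_B):
        ref_ca, ref_cb = _ca_cb(ref, gly_policy)
        if len(ref_ca) != L:
            raise ValueError("reference length differs from conformation")
        rot, trans, moved_ca = kabsch(ref_ca, ca)
        moved_cb = ref_cb @ rot.T + trans
        parts_ca.append(np.linalg.norm(ca - moved_ca, axis=1))
        parts_cb.append(np.linalg.norm(cb - moved_cb, axis=1))
    return np.concatenate(parts_ca + parts_cb)


def rmsd_sm(v1: np.ndarray, v2: np.ndarray) -> float:
    """Root mean square difference of two superposition-map vectors."""
    v1 = np.asarray(v1, float)
    v2 = np.asarray(v2, float)
    if v1.shape != v2.shape:
        raise ValueError("superposition vectors differ in dimension")
    return float(np.sqrt(np.mean((v1 - v2) ** 2)))


@dataclass
class Clustering:
    k: int
    assignments: np.ndarray          # cluster id per conformation
    centroid_ids: np.ndarray         # index of the member nearest each center
    vectors: np.ndarray              # (n, 4L) input vectors
    source_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        for c in range(self.k):
            cid = self.centroid_ids[c]
            if self.assignments[cid] != c:
                raise ValueError(f"centroid {cid} not a member of cluster {c}")

    def members(self, cluster: int) -> np.ndarray:
        return np.nonzero(self.assignments == cluster)[0]


def cluster_conformations(vectors: np.ndarray, k: int = DEFAULT_K,
                          seed: int = 0,
                          source_labels=None) -> Clustering:
    """Seeded k-means in superposition-map space.

    The centroid of a cluster is the actual member conformation closest to
    the cluster mean (Euclidean distance; index order breaks exact ties).
    """
    vectors = np.asarray(vectors, float)
    if len(vectors) < k:
        raise ValueError(f"need at least k={k} vectors, got {len(vectors)}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, random_state=seed)
    assignments = km.fit_predict(vectors)
    centroid_ids = np.empty(k, int)
    for c in range(k):
        members = np.nonzero(assignments == c)[0]
        d = np.linalg.norm(vectors[members] - km.cluster_centers_[c], axis=1)
        centroid_ids[c] = members[int(np.argmin(d))]
    labels = None if source_labels is None else np.asarray(source_labels)
    return Clustering(k=k, assignments=assignments, centroid_ids=centroid_ids,
                      vectors=vectors, source_labels=labels)


def centroid_graph(clustering: Clustering,
                   threshold: float = DEFAULT_EDGE_THRESHOLD) -> list[tuple[int, int, float]]:
    """Undirected edges (cluster a, cluster b, RMSD_sm) with RMSD_sm <= threshold."""
    edges = []
    cent = clustering.vectors[clustering.centroid_ids]
    for a in range(clustering.k):
        for b in range(a + 1, clustering.k):
            d = rmsd_sm(cent[a], cent[b])
            if d <= threshold:
                edges.append((a, b, d))
    return edges


def select_region(q_a: np.ndarray, q_b: np.ndarray,
                  q_box: tuple[tuple[float, float], tuple[float, float]]) -> np.ndarray:
    """Indices of samples strictly inside the open (Q_A, Q_B) box."""
    (a_lo, a_hi), (b_lo, b_hi) = q_box
    if not (a_lo < a_hi and b_lo < b_hi):
        raise ValueError("empty region box")
    q_a = np.asarray(q_a, float)
    q_b = np.asarray(q_b, float)
    mask = (q_a > a_lo) & (q_a < a_hi) & (q_b > b_lo) & (q_b < b_hi)
    return np.nonzero(mask)[0]


def sequence_bias(clustering: Clustering, q_a: np.ndarray,
                  q_b: np.ndarray) -> pd.DataFrame:
    """Per-cluster mutational population shift and intrinsic fold bias.

    ``bias`` = ln of the ratio of the two source-sequence fractions in the
    cluster (requires a pooled clustering from exactly two sources with
    equal sample counts); ``fold_bias`` = ln(mean Q_B / mean Q_A) over the
    cluster members.  A cluster empty of one source yields an infinite
    bias, flagged in the ``degenerate`` column.
    """
    if clustering.source_labels is None:
        raise ValueError("clustering carries no source labels")
    labels = clustering.source_labels
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("sequence bias needs exactly two source sequences")
    n0, n1 = np.sum(labels == uniq[0]), np.sum(labels == uniq[1])
    if n0 != n1:
        raise ValueError("source sequences must contribute equal sample counts")
    q_a = np.asarray(q_a, float)
    q_b = np.asarray(q_b, float)
    rows = []
    with np.errstate(divide="ignore"):
        for c in range(clustering.k):
            m = clustering.members(c)
            c0 = int(np.sum(labels[m] == uniq[0]))
            c1 = int(np.sum(labels[m] == uniq[1]))
            bias = float(np.log(c1 / c0)) if c0 and c1 else \
                float("inf") if c1 else float("-inf") if c0 else float("nan")
            fold_bias = float(np.log(np.mean(q_b[m]) / np.mean(q_a[m])))
            rows.append({"cluster": c, "n_0": c0, "n_1": c1, "bias": bias,
                         "fold_bias": fold_bias,
                         "degenerate": not (c0 and c1)})
    return pd.DataFrame(rows)


THREE_STATE = "3-state"
EIGHT_STATE = "8-state"


def macrostate_3(q_a: float, q_b: float) -> str:
    if q_a >= 0.6 and q_b < 0.6:
        return "G_A"
    if q_b >= 0.6 and q_a < 0.6:
        return "G_B"
    return "U"


# Interpretive 8-state refinement of the landscape (boundaries are package
# presets): the three-state split plus the transition/intermediate boxes and
# an extended-chain corner.
def macrostate_8(q_a: float, q_b: float) -> str:
    if q_a >= 0.6 and q_b < 0.6:
        return "TS-GA" if q_a < 0.74 and 0.12 < q_b < 0.22 else "G_A"
    if q_b >= 0.6 and q_a < 0.6:
        return "TS2-GB" if q_b < 0.66 and 0.28 < q_a < 0.40 else "G_B"
    if 0.30 < q_a < 0.55 and 0.35 < q_b < 0.43:
        return "TS1-GB"
    if 0.30 < q_a < 0.55 and 0.43 <= q_b < 0.60:
        return "I-GB"
    if q_a < 0.2 and q_b < 0.1:
        return "ext"
    return "U"


@dataclass
class FluxMatrix:
    states: list[str]
    counts: np.ndarray  # counts[a, b] = transitions a -> b along the trajectory

    def two_way(self, a: str, b: str) -> float:
        """Normalized two-way transition frequency between two macrostates."""
        ia, ib = self.states.index(a), self.states.index(b)
        total = self.counts.sum() - np.trace(self.counts)
        if total == 0:
            return 0.0
        return float((self.counts[ia, ib] + self.counts[ib, ia]) / total)


def transition_flux(q_a: np.ndarray, q_b: np.ndarray,
                    partition: str = THREE_STATE) -> FluxMatrix:
    """Count macrostate transitions between consecutive trajectory records."""
    q_a = np.asarray(q_a, float)
    q_b = np.asarray(q_b, float)
    if np.any(~np.isfinite(q_a)) or np.any(~np.isfinite(q_b)):
        raise ValueError("trajectory contains undefined Q records")
    if partition == THREE_STATE:
        fn, states = macrostate_3, ["U", "G_A", "G_B"]
    elif partition == EIGHT_STATE:
        fn, states = macrostate_8, ["ext", "U", "TS-GA", "G_A",
                                    "TS1-GB", "I-GB", "TS2-GB", "G_B"]
    else:
        raise ValueError(f"unknown partition {partition!r}")
    idx = {s: i for i, s in enumerate(states)}
    labels = [idx[fn(a, b)] for a, b in zip(q_a, q_b)]
    counts = np.zeros((len(states), len(states)), int)
    for a, b in zip(labels, labels[1:]):
        counts[a, b] += 1
    return FluxMatrix(states=states, counts=counts)


def contact_shift(ens_A, ens_B, map_A: ConsensusMap, map_B: ConsensusMap,
                  cutoff: float = 6.0, min_seq_sep: int = 3,
                  gly_policy: str = "calpha") -> pd.DataFrame:
    """Contact-frequency shift between two equal-size conformational ensembles.

    For every contact observed in either ensemble: fractions P_A and P_B of
    conformations containing it, the overall frequency (P_A + P_B)/2, the
    shift P_B - P_A, the contact order |i - j| + 1 and its class relative
    to the two consensus native maps.
    """
    if not ens_A or not ens_B:
        raise ValueError("empty ensemble")
    if len(ens_A) != len(ens_B):
        raise ValueError("ensembles must be equal size")

    def _freqs(ensemble) -> dict[tuple[int, int], float]:
        counts: dict[tuple[int, int], int] = {}
        for conf in ensemble:
            st = conf if isinstance(conf, Structure) else structure_from_chain(
                conf.coords if hasattr(conf, "coords") else conf)
            cm = build_contact_map(st, cutoff, min_seq_sep, gly_policy)
            for pair in cm.contacts:
                counts[pair] = counts.get(pair, 0) + 1
        return {pair: n / len(ensemble) for pair, n in counts.items()}

    fa = _freqs(ens_A)
    fb = _freqs(ens_B)
    native_a = {(c.i, c.j) for c in map_A.contacts}
    native_b = {(c.i, c.j) for c in map_B.contacts}
    rows = []
    for pair in sorted(set(fa) | set(fb)):
        i, j = pair
        p_a = fa.get(pair, 0.0)
        p_b = fb.get(pair, 0.0)
        in_a, in_b = pair in native_a, pair in native_b
        klass = ("native-both" if in_a and in_b else "native-G_A" if in_a
                 else "native-G_B" if in_b else "nonnative")
        rows.append({"i": i, "j": j, "contact_order": abs(i - j) + 1,
                     "P_A": p_a, "P_B": p_b, "overall": 0.5 * (p_a + p_b),
                     "shift": p_b - p_a, "class": klass})
    return pd.DataFrame(rows)
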
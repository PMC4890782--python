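"""Native contact maps and multi-conformer consensus maps.

Two residues form a native contact when the closest distance between any
two non-hydrogen sidechain atoms, one from each residue, is at most the
cutoff (6 Angstrom, inclusive) and the residues are at least
``min_seq_sep`` (default 3) positions apart in sequence.  A consensus map
over several native conformers of one fold keeps only the contacts common
to all conformers and stores, for each kept contact, the CA-CA distance in
every conformer — these distances become the minima of the multi-Gaussian
wells of the structure-based potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from foldswitch.structures import Residue, Structure

GLY_POLICIES = ("calpha", "none")


def _effective_sidechain(res: Residue, gly_policy: str) -> np.ndarray | None:
    if res.sidechain_heavy:
        return np.asarray(res.sidechain_heavy, float)
    if gly_policy == "calpha":
        return res.ca[None, :]
    if gly_policy == "none":
        return None
    raise ValueError(f"unknown gly policy {gly_policy!r}")


def residue_contact(a: Residue, b: Residue, cutoff: float = 6.0,
                    gly_policy: str = "calpha") -> bool:
    """True iff the closest sidechain heavy-atom pair is within ``cutoff``."""
    pa = _effective_sidechain(a, gly_policy)
    pb = _effective_sidechain(b, gly_policy)
    if pa is None or pb is None:
        return False
    d2 = np.sum((pa[:, None, :] - pb[None, :, :]) ** 2, axis=-1)
    return bool(np.min(d2) <= cutoff * cutoff)


@dataclass
class ContactMap:
    contacts: set[tuple[int, int]]
    min_seq_sep: int
    length: int

    def __post_init__(self) -> None:
        for i, j in self.contacts:
            if not (1 <= i < j <= self.length):
                raise ValueError(f"contact ({i}, {j}) outside chain of length {self.length}")
            if j - i < self.min_seq_sep:
                raise ValueError(f"contact ({i}, {j}) violates min_seq_sep {self.min_seq_sep}")

    def __len__(self) -> int:
        return len(self.contacts)


@dataclass
class ConsensusContact:
    i: int
    j: int
    d: list[float]  # native CA-CA distances, one per contributing conformer

    def __post_init__(self) -> None:
        if any(x <= 0 for x in self.d):
            raise ValueError(f"non-positive native distance for contact ({self.i}, {self.j})")


@dataclass
class ConsensusMap:
    fold_label: str
    contacts: list[ConsensusContact]
    n_conformers: int
    length: int
    _index: np.ndarray = field(init=False, repr=False)
    _dists: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for c in self.contacts:
            if len(c.d) != self.n_conformers:
                raise ValueError("contact distance list length != n_conformers")
        self.contacts = sorted(self.contacts, key=lambda c: (c.i, c.j))
        if self.contacts:
            self._index = np.array([(c.i, c.j) for c in self.contacts], int)
            self._dists = np.array([c.d for c in self.contacts], float)
        else:
            self._index = np.zeros((0, 2), int)
            self._dists = np.zeros((0, self.n_conformers), float)

    def __len__(self) -> int:
        return len(self.contacts)

    @property
    def pair_index(self) -> np.ndarray:
        """(n_contacts, 2) int array of 1-based residue pairs."""
        return self._index

    @property
    def native_distances(self) -> np.ndarray:
        """(n_contacts, n_conformers) native CA-CA distances."""
        return self._dists


def build_contact_map(structure: Structure, cutoff: float = 6.0,
                      min_seq_sep: int = 3, gly_policy: str = "calpha") -> ContactMap:
    """All residue pairs with j - i >= min_seq_sep passing the contact test."""
    res = structure.residues
    L = len(res)
    pairs = set()
    for a in range(L):
        for b in range(a + min_seq_sep, L):
            if residue_contact(res[a], res[b], cutoff, gly_policy):
                pairs.add((res[a].index, res[b].index))
    return ContactMap(contacts=pairs, min_seq_sep=min_seq_sep, length=L)


def consensus_map(structures: list[Structure], cutoff: float = 6.0,
                  min_seq_sep: int = 3, gly_policy: str = "calpha",
                  fold_label: str = "fold") -> ConsensusMap:
    """Intersect per-conformer contact maps into a consensus map.

    Membership requires the contact in every conformer; each kept contact
    stores the CA-CA distance from every conformer.
    """
    if not structures:
        raise ValueError("need at least one structure")
    lengths = {len(s) for s in structures}
    if len(lengths) != 1:
        raise ValueError(f"structures differ in length: {sorted(lengths)}")
    maps = [build_contact_map(s, cutoff, min_seq_sep, gly_policy) for s in structures]
    common = set.intersection(*(m.contacts for m in maps))
    by_index = [{r.index: r for r in s.residues} for s in structures]
    contacts = []
    for (i, j) in sorted(common):
        d = [float(np.linalg.norm(bi[i].ca - bi[j].ca)) for bi in by_index]
        contacts.append(ConsensusContact(i=i, j=j, d=d))
    return ConsensusMap(fold_label=fold_label, contacts=contacts,
                        n_conformers=len(structures), length=lengths.pop())


def consensus_to_tsv(cmap: ConsensusMap, path: str | Path) -> Path:
    cols = {"i": [c.i for c in cmap.contacts], "j": [c.j for c in cmap.contacts]}
    for s in range(cmap.n_conformers):
        cols[f"d_{s + 1}"] = [c.d[s] for c in cmap.contacts]
    df = pd.DataFrame(cols)
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fold_label={cmap.fold_label} n_conformers={cmap.n_conformers} "
                 f"length={cmap.length}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def consensus_from_tsv(path: str | Path) -> ConsensusMap:
    path = Path(path)
    header = path.open().readline()
    meta = dict(tok.split("=") for tok in header.lstrip("# ").split())
    df = pd.read_csv(path, sep="\t", comment="#")
    n_s = int(meta["n_conformers"])
    contacts = [
        ConsensusContact(i=int(row["i"]), j=int(row["j"]),
                         d=[float(row[f"d_{s + 1}"]) for s in range(n_s)])
        for _, row in df.iterrows()
    ]
    return ConsensusMap(fold_label=meta["fold_label"], contacts=contacts,
                        n_conformers=n_s, length=int(meta["length"]))
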
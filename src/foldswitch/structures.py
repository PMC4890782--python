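"""PDB structure input/output and synthetic conformer fixtures.

Reading follows the conventions of the consensus-map construction: one
MODEL of a (possibly multi-model NMR) PDB file at a time, heteroatoms,
waters and hydrogens excluded, alternate locations restricted to blank or
'A', and internal residue numbering remapped to consecutive 1-based indices
with the author numbering retained for reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from foldswitch.geometry import build_chain
from foldswitch.sequences import AA1, AA3, STANDARD_RESIDUES, validate_sequence

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass
class Residue:
    """One standard amino-acid residue in the reduced representation."""

    index: int                      # 1-based consecutive internal index
    name: str                       # 3-letter code
    ca: np.ndarray                  # (3,) Angstrom
    cb: np.ndarray | None           # absent for Gly
    sidechain_heavy: list[np.ndarray] = field(default_factory=list)
    author_seqid: int | None = None  # original PDB numbering

    def __post_init__(self) -> None:
        if self.name not in STANDARD_RESIDUES:
            raise ValueError(f"nonstandard residue {self.name!r} at {self.index}")
        self.ca = np.asarray(self.ca, float)
        if not np.all(np.isfinite(self.ca)):
            raise ValueError(f"non-finite CA coordinates at residue {self.index}")
        if self.cb is not None:
            self.cb = np.asarray(self.cb, float)


@dataclass
class Structure:
    """A single-model, single-chain structure."""

    id: str
    model_index: int
    residues: list[Residue]

    def __post_init__(self) -> None:
        if self.model_index < 1:
            raise ValueError("model_index must be >= 1")
        if not self.residues:
            raise ValueError("structure has no residues")
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(AA1[r.name] for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues])

    def cb_coords(self, gly_policy: str = "calpha") -> np.ndarray:
        """C-beta coordinates; Gly substitutes CA under the default policy."""
        out = []
        for r in self.residues:
            if r.cb is not None:
                out.append(r.cb)
            elif gly_policy == "calpha":
                out.append(r.ca)
            else:
                raise ValueError(f"residue {r.index} has no CB under policy {gly_policy!r}")
        return np.array(out)


@dataclass
class FixtureSpec:
    """Specification of a synthetic conformer set."""

    length: int
    topology: str = "helix-bundle"   # helix-bundle | hairpin-sheet | random-coil
    n_conformers: int = 1
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.n_conformers < 1:
            raise ValueError("n_conformers must be >= 1")
        if self.topology not in ("helix-bundle", "hairpin-sheet", "random-coil"):
            raise ValueError(f"unknown topology {self.topology!r}")


def read_structure(path: str | Path, model_index: int = 1,
                   chain_id: str | None = None) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    Only the requested MODEL is used (never a mixture of models), only the
    first chain unless ``chain_id`` is given, heteroatoms/waters/hydrogens
    are excluded, and altloc conformers other than blank/'A' are dropped.
    Nonstandard residues raise rather than being silently skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    if model_index < 1 or model_index > len(st):
        raise IndexError(
            f"model_index {model_index} out of range (file has {len(st)} model(s))")
    model = st[model_index - 1]
    if chain_id is None:
        chain = model[0]
    else:
        chain = model.find_chain(chain_id)
        if chain is None:
            raise KeyError(f"chain {chain_id!r} not found")

    residues: list[Residue] = []
    internal = 0
    for res in chain:
        if res.is_water() or res.het_flag == "H":
            continue
        if res.name not in STANDARD_RESIDUES:
            raise ValueError(f"nonstandard residue {res.name!r} ({res.seqid.num})")
        ca = cb = None
        sidechain: list[np.ndarray] = []
        for atom in res:
            if atom.is_hydrogen():
                continue
            if atom.altloc not in ("", "\0", "A"):
                continue
            pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            if atom.name == "CA":
                ca = pos
            elif atom.name == "CB":
                cb = pos
                sidechain.append(pos)
            elif atom.name not in BACKBONE_ATOMS:
                sidechain.append(pos)
        if ca is None:
            continue  # residue unresolved; contributes nothing downstream
        internal += 1
        residues.append(Residue(index=internal, name=res.name, ca=ca, cb=cb,
                                sidechain_heavy=sidechain,
                                author_seqid=res.seqid.num))
    if not residues:
        raise ValueError(f"no standard residues with CA in {path.name}")
    return Structure(id=path.stem, model_index=model_index, residues=residues)


def write_structure(structure: Structure, path: str | Path) -> Path:
    """Write a Structure as a minimal single-model PDB file."""
    path = Path(path)
    lines = []
    serial = 1
    for r in structure.residues:
        atoms: list[tuple[str, np.ndarray]] = [("CA", r.ca)]
        if r.cb is not None:
            atoms.append(("CB", r.cb))
        extra = 0
        for pos in r.sidechain_heavy:
            if r.cb is not None and np.allclose(pos, r.cb):
                continue
            extra += 1
            atoms.append((f"S{extra}", pos))
        for name, pos in atoms:
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} {r.name:>3s} A{r.index:4d}    "
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}  1.00  0.00           C"
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


_FIXTURE_ALPHABET = "LAKEVSTIFDNQ"  # varied, Gly/Pro-free, with aromatics


def fixture_sequence(length: int) -> str:
    """Deterministic residue naming for synthetic fixtures."""
    return "".join(_FIXTURE_ALPHABET[i % len(_FIXTURE_ALPHABET)] for i in range(length))


def _fixture_torsions(spec: FixtureSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    L = spec.length
    if spec.topology == "helix-bundle":
        phi = np.full(L, -63.0)
        psi = np.full(L, -43.0)
    elif spec.topology == "hairpin-sheet":
        phi = np.full(L, -135.0)
        psi = np.full(L, 135.0)
        mid = L // 2
        # tight two-residue turn bringing the strands into register
        phi[mid - 1: mid + 1] = (90.0, 90.0)
        psi[mid - 1: mid + 1] = (40.0, 30.0)
    else:  # random-coil
        phi = rng.uniform(-170.0, -50.0, size=L)
        psi = rng.uniform(-60.0, 170.0, size=L)
    return phi, psi


def generate_fixture_set(spec: FixtureSpec) -> list[Structure]:
    """Generate ``n_conformers`` structurally similar synthetic conformers.

    All conformers share length, residue naming and topology; independent
    Gaussian coordinate jitter of width ``jitter_sd`` emulates the
    conformer-to-conformer variation of an NMR ensemble.  Deterministic for
    a fixed (spec, seed); every residue carries at least one synthetic
    sidechain heavy atom (the representation is Gly/Pro-free).
    """
    if spec.length < 4:
        raise ValueError("fixture length must be >= 4 for |i-j| >= 3 contacts")
    seq = fixture_sequence(spec.length)
    rng = np.random.default_rng(spec.seed)
    phi, psi = _fixture_torsions(spec, rng)
    base = build_chain(seq, phi, psi)
    out = []
    for s in range(spec.n_conformers):
        jitter = (rng.normal(0.0, spec.jitter_sd, size=(3, spec.length, 3))
                  if spec.jitter_sd > 0 else np.zeros((3, spec.length, 3)))
        residues = []
        for i, aa in enumerate(seq):
            ca = base.ca[i] + jitter[0, i]
            cb = base.cb[i] + jitter[1, i]
            sc = base.sc[i] + jitter[2, i]
            residues.append(Residue(index=i + 1, name=AA3[aa], ca=ca, cb=cb,
                                    sidechain_heavy=[cb, sc]))
        out.append(Structure(id=f"fixture-{spec.topology}-{s}", model_index=1,
                             residues=residues))
    return out


def structure_from_chain(coords, structure_id: str = "chain") -> Structure:
    """Wrap :class:`~foldswitch.geometry.ChainCoords` as a Structure."""
    seq = validate_sequence(coords.sequence)
    residues = []
    for i, aa in enumerate(seq):
        cb = None if aa == "G" else coords.cb[i]
        sidechain = [] if aa == "G" else [coords.cb[i], coords.sc[i]]
        residues.append(Residue(index=i + 1, name=AA3[aa], ca=coords.ca[i],
                                cb=cb, sidechain_heavy=sidechain))
    return Structure(id=structure_id, model_index=1, residues=residues)
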
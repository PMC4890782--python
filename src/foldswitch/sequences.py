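"""Amino-acid tables and the fold-switch study sequences.

The GA98/GB98 pair is the canonical single-mutation fold switch of the
protein-G system: the two 56-residue sequences differ only at position 45
(Leu in GA98, Tyr in GB98), yet GA98 folds to the three-helix G_A fold and
GB98 to the 4beta+alpha G_B fold.  The sequences below are the published
56-residue constructs (PDB 2LHC / 2LHD).
"""

from __future__ import annotations

# 56-residue GA98 construct (PDB 2LHC).  Single Trp at 43; residue 45 = Leu.
GA98 = "MTYKLILNLKQAKEEAIKELVDAGTAEKYFKLIANAKTVEGVWTLKDEILTFTVTE"

# GB98 (PDB 2LHD) is GA98 with the L45Y substitution.
GB98 = GA98[:44] + "Y" + GA98[45:]

# 56-residue redesign of protein L used as a folding control: terminal tails
# and internal loop residues removed and one Gly inserted so that the chain
# aligns residue-for-residue with the G_B fold.
PROTEIN_L_56 = "VTIKANLIFANSTQTAEFKGTFAEKATSEAYAYADTLKKEYTVDVADKGYTLNIKF"

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
AA1 = {three: one for one, three in AA3.items()}

STANDARD_RESIDUES = frozenset(AA3.values())

# Number of freely rotatable sidechain torsions per residue type under the
# fixed-bond-length / fixed-bond-angle chain representation: heavy-atom chi
# angles plus terminal single-bond rotors (CH3, OH, SH, NH3+), with planar
# groups (amide, carboxylate, guanidinium, aromatic rings) held rigid.  The
# proline ring is rigid and its phi is frozen, so Pro contributes psi only.
SIDECHAIN_TORSIONS = {
    "A": 1,  # CB methyl rotor
    "R": 4,  # chi1-4 (guanidinium planar)
    "N": 2,  # chi1-2 (amide planar)
    "D": 2,  # chi1-2 (carboxylate planar)
    "C": 2,  # chi1 + SH
    "Q": 3,  # chi1-3
    "E": 3,  # chi1-3
    "G": 0,
    "H": 2,  # chi1-2 (ring rigid)
    "I": 4,  # chi1-2 + two methyls
    "L": 4,  # chi1-2 + two methyls
    "K": 5,  # chi1-4 + NH3+
    "M": 4,  # chi1-3 + methyl
    "F": 2,  # chi1-2 (ring rigid)
    "P": 0,  # ring rigid
    "S": 2,  # chi1 + OH
    "T": 3,  # chi1 + OH + methyl
    "V": 3,  # chi1 + two methyls
    "W": 2,  # chi1-2 (indole rigid)
    "Y": 3,  # chi1-2 + OH (ring rigid)
}

# Nonpolar residue types whose sidechain pseudo-atoms enter the hydrophobic
# contact term of the stand-in transferable model.
HYDROPHOBIC = frozenset("AVLIMFWYP")

# Aromatic types carrying a ring plane (Trp excluded from the pi-pi
# treatment by construction; His not treated).
AROMATIC_PIPI = frozenset("FY")

# Net sidechain charge at neutral pH for the screened-Coulomb term.
CHARGE = {"D": -1.0, "E": -1.0, "K": +1.0, "R": +1.0}
CHARGE = {**{aa: 0.0 for aa in AA3}, **CHARGE}

# Distance (Angstrom) from C-beta to the sidechain heavy-atom centroid used
# by the reduced chain representation; coarse per-type values.
SIDECHAIN_CENTROID_DIST = {
    "A": 0.0, "R": 3.0, "N": 1.4, "D": 1.4, "C": 1.0,
    "Q": 1.9, "E": 1.9, "G": 0.0, "H": 2.2, "I": 1.5,
    "L": 1.5, "K": 2.5, "M": 2.0, "F": 2.4, "P": 1.2,
    "S": 1.0, "T": 1.0, "V": 1.0, "W": 3.0, "Y": 2.9,
}


def validate_sequence(sequence: str) -> str:
    """Upper-case and validate a one-letter sequence; raise on unknown codes."""
    seq = sequence.strip().upper()
    bad = sorted(set(seq) - set(AA3))
    if bad:
        raise ValueError(f"unknown residue code(s): {', '.join(bad)}")
    return seq
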
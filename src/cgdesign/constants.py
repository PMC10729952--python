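"""Shared constants: amino-acid alphabet, substitution matrix, accessibility
reference values, and ideal backbone geometry.

The 20-letter alphabet is fixed in the order ``ACDEFGHIKLMNPQRSTVWY``; every
categorical output of the package (logits, distributions, confusion matrices)
uses this index order.
"""

from __future__ import annotations

import numpy as np

#: Canonical amino-acid ordering used for all 20-way categorical outputs.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}

#: Residues whose side chains are predominantly apolar; the complement of this
#: set within the alphabet is treated as hydrophilic.
HYDROPHOBIC: frozenset[str] = frozenset("ILMFCWPVAG")
HYDROPHILIC: frozenset[str] = frozenset("STNQDEHRKY")

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
    # selenomethionine is read as methionine
    "MSE": "M",
}
ONE_TO_THREE: dict[str, str] = {
    v: k for k, v in THREE_TO_ONE.items() if k != "MSE"
}
ONE_TO_THREE["X"] = "UNK"

# BLOSUM62 integer substitution matrix, rows/columns in ALPHABET order.
BLOSUM62: np.ndarray = np.array([
    # A
    (4, 0, -2, -1, -2, 0, -2, -1, -1, -1, -1, -2, -1, -1, -1, 1, 0, 0, -3, -2),
    # C
    (0, 9, -3, -4, -2, -3, -3, -1, -3, -1, -1, -3, -3, -3, -3, -1, -1, -1, -2, -2),
    # D
    (-2, -3, 6, 2, -3, -1, -1, -3, -1, -4, -3, 1, -1, 0, -2, 0, -1, -3, -4, -3),
    # E
    (-1, -4, 2, 5, -3, -2, 0, -3, 1, -3, -2, 0, -1, 2, 0, 0, -1, -2, -3, -2),
    # F
    (-2, -2, -3, -3, 6, -3, -1, 0, -3, 0, 0, -3, -4, -3, -3, -2, -2, -1, 1, 3),
    # G
    (0, -3, -1, -2, -3, 6, -2, -4, -2, -4, -3, 0, -2, -2, -2, 0, -2, -3, -2, -3),
    # H
    (-2, -3, -1, 0, -1, -2, 8, -3, -1, -3, -2, 1, -2, 0, 0, -1, -2, -3, -2, 2),
    # I
    (-1, -1, -3, -3, 0, -4, -3, 4, -3, 2, 1, -3, -3, -3, -3, -2, -1, 3, -3, -1),
    # K
    (-1, -3, -1, 1, -3, -2, -1, -3, 5, -2, -1, 0, -1, 1, 2, 0, -1, -2, -3, -2),
    # L
    (-1, -1, -4, -3, 0, -4, -3, 2, -2, 4, 2, -3, -3, -2, -2, -2, -1, 1, -2, -1),
    # M
    (-1, -1, -3, -2, 0, -3, -2, 1, -1, 2, 5, -2, -2, 0, -1, -1, -1, 1, -1, -1),
    # N
    (-2, -3, 1, 0, -3, 0, 1, -3, 0, -3, -2, 6, -2, 0, 0, 1, 0, -3, -4, -2),
    # P
    (-1, -3, -1, -1, -4, -2, -2, -3, -1, -3, -2, -2, 7, -1, -2, -1, -1, -2, -4, -3),
    # Q
    (-1, -3, 0, 2, -3, -2, 0, -3, 1, -2, 0, 0, -1, 5, 1, 0, -1, -2, -2, -1),
    # R
    (-1, -3, -2, 0, -3, -2, 0, -3, 2, -2, -1, 0, -2, 1, 5, -1, -1, -3, -3, -2),
    # S
    (1, -1, 0, 0, -2, 0, -1, -2, 0, -2, -1, 1, -1, 0, -1, 4, 1, -2, -3, -2),
    # T
    (0, -1, -1, -1, -2, -2, -2, -1, -1, -1, -1, 0, -1, -1, -1, 1, 5, 0, -2, -2),
    # V
    (0, -1, -3, -2, -1, -3, -3, 3, -2, 1, 1, -3, -2, -2, -3, -2, 0, 4, -3, -1),
    # W
    (-3, -2, -4, -3, 1, -2, -2, -3, -3, -2, -1, -4, -4, -2, -3, -3, -2, -3, 11, 2),
    # Y
    (-2, -2, -3, -2, 3, -3, 2, -1, -2, -1, -1, -2, -3, -1, -2, -2, -2, -1, 2, 7),
], dtype=float)

#: Theoretical maximum accessible surface area per residue type (Tien et al.
#: 2013, "theoretical" column), in square Angstroms. Used to normalize SASA
#: into relative solvent accessibility (RSA).
MAX_ASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# Ideal backbone internal geometry used by the synthetic generator.
# Engineering constants (standard peptide values), not fitted quantities.
#   bond lengths (Angstrom)           bond angles (degrees)
#   N-CA   1.458                      C(-1)-N-CA   121.7
#   CA-C   1.525                      N-CA-C       111.2
#   C-N    1.329                      CA-C-N(+1)   116.2
#   C-O    1.231                      CA-C-O       120.8
IDEAL_GEOMETRY: dict[str, float] = {
    "len_N_CA": 1.458,
    "len_CA_C": 1.525,
    "len_C_N": 1.329,
    "len_C_O": 1.231,
    "ang_C_N_CA": 121.7,
    "ang_N_CA_C": 111.2,
    "ang_CA_C_N": 116.2,
    "ang_CA_C_O": 120.8,
}

#: Canonical phi/psi dihedrals (degrees) for ideal secondary structures.
SECONDARY_DIHEDRALS: dict[str, tuple[float, float]] = {
    "helix": (-57.0, -47.0),
    "strand": (-119.0, 113.0),
}

# Virtual C-beta reconstruction coefficients (applied to u, v, u x v around
# the C-alpha position); shared with ProteinMPNN-style featurizations.
VIRTUAL_CB_COEFF: tuple[float, float, float] = (
    -0.58273431, 0.56802827, -0.54067466,
)
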
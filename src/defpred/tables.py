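"""Residue-level lookup tables backing the composition descriptors.

All tables cover exactly the 20 standard amino acids in the canonical
one-letter ordering ``ACDEFGHIKLMNPQRSTVWY``.  The CTD three-group
partitions live in ``data/ctd_groups.json`` so they can be inspected and
overridden; everything residue-scalar lives here.
"""

from __future__ import annotations

import json
from importlib import resources

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: Residues excluded from the standard alphabet (ambiguity / non-natural codes).
NONSTANDARD = set("BJOUXZ")

# Atoms per in-chain residue (free amino acid minus one water), used for the
# atom-composition (ATC) descriptor.  Keys: C, H, N, O, S counts.
RESIDUE_ATOMS = {
    "A": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 0},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3, "S": 0},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3, "S": 0},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1, "S": 0},
    "G": {"C": 2, "H": 3, "N": 1, "O": 1, "S": 0},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1, "S": 0},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1, "S": 0},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1, "S": 0},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1, "S": 0},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2, "S": 0},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1, "S": 0},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2, "S": 0},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1, "S": 0},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2, "S": 0},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2, "S": 0},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 0},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1, "S": 0},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2, "S": 0},
}

# Bond counts per in-chain residue, derived from the molecular graph of each
# residue unit (internal bonds only; counts = atoms - 1 + rings).  Columns:
# T = total bonds, H = bonds to hydrogen, S = single bonds, D = double bonds
# (backbone carbonyl plus side-chain carbonyl/imine/aromatic doubles).
RESIDUE_BONDS = {
    "A": {"T": 9, "H": 5, "S": 8, "D": 1},
    "C": {"T": 10, "H": 5, "S": 9, "D": 1},
    "D": {"T": 12, "H": 5, "S": 10, "D": 2},
    "E": {"T": 15, "H": 7, "S": 13, "D": 2},
    "F": {"T": 20, "H": 9, "S": 16, "D": 4},
    "G": {"T": 6, "H": 3, "S": 5, "D": 1},
    "H": {"T": 17, "H": 7, "S": 14, "D": 3},
    "I": {"T": 18, "H": 11, "S": 17, "D": 1},
    "K": {"T": 20, "H": 12, "S": 19, "D": 1},
    "L": {"T": 18, "H": 11, "S": 17, "D": 1},
    "M": {"T": 16, "H": 9, "S": 15, "D": 1},
    "N": {"T": 13, "H": 6, "S": 11, "D": 2},
    "P": {"T": 14, "H": 7, "S": 13, "D": 1},
    "Q": {"T": 16, "H": 8, "S": 14, "D": 2},
    "R": {"T": 22, "H": 12, "S": 20, "D": 2},
    "S": {"T": 10, "H": 5, "S": 9, "D": 1},
    "T": {"T": 13, "H": 7, "S": 12, "D": 1},
    "V": {"T": 15, "H": 9, "S": 14, "D": 1},
    "W": {"T": 25, "H": 10, "S": 20, "D": 5},
    "Y": {"T": 21, "H": 9, "S": 17, "D": 4},
}

# Physicochemical residue classes for the PCP composition block.
# Ordered mapping: class code -> member residues.
PCP_CLASSES = {
    "PC": "HKR",                  # positively charged
    "NC": "DE",                   # negatively charged
    "NE": "ACFGILMNPQSTVWY",      # charge-neutral
    "PO": "DEHKNQRSTY",           # polar
    "NP": "ACFGILMPVW",           # non-polar
    "AL": "AGILV",                # aliphatic
    "AR": "FWY",                  # aromatic
    "CY": "P",                    # cyclic
    "HB": "ACFILMVW",             # hydrophobic
    "HL": "DEKNQRS",              # hydrophilic
    "TN": "ACGST",                # tiny
    "SM": "ACDGNPSTV",            # small
    "LR": "FHKRWY",               # large
}

# Amino-acid properties for the pseudo-amino-acid composition correlation
# terms: Tanford/Chou hydrophobicity, Hopp-Woods hydrophilicity, and
# side-chain mass (Da).  Standardized over the alphabet before use.
PAAC_HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
    "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
    "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
    "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
}
PAAC_HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
    "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
    "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
    "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
}
PAAC_SIDE_CHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0,
    "G": 1.0, "H": 81.0, "I": 57.0, "K": 73.0, "L": 57.0,
    "M": 75.0, "N": 58.0, "P": 42.0, "Q": 72.0, "R": 101.0,
    "S": 31.0, "T": 45.0, "V": 43.0, "W": 130.0, "Y": 107.0,
}


def load_ctd_groups() -> dict:
    """Load the shipped CTD three-group partition tables.

    Returns a mapping ``attribute -> {"code": str, "groups": [str, str, str]}``
    where each attribute's three groups are disjoint and jointly cover the
    20-letter alphabet.
    """
    text = resources.files("defpred").joinpath("data/ctd_groups.json").read_text()
    raw = json.loads(text)
    out = {}
    for attr, entry in raw.items():
        if attr.startswith("_"):
            continue
        groups = entry["groups"]
        covered = "".join(groups)
        if sorted(covered) != sorted(ALPHABET):
            raise ValueError(
                f"CTD attribute {attr!r}: groups do not partition the alphabet"
            )
        out[attr] = {"code": entry["code"], "groups": list(groups)}
    return out
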
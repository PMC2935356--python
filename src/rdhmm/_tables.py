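"""Amino-acid property tables used by the design energy.

All tables are indexed by :data:`ALPHABET` order (alphabetical one-letter
codes). The backbone-conditioned propensity table is a coarse,
secondary-structure-level stand-in for rotamer-library statistics: it only
needs to rank residues sensibly within each Ramachandran class, and every
test that touches it is table-relative.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}
N_AA = len(ALPHABET)

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Kyte-Doolittle hydropathy, raw scale [-4.5, 4.5].
_KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

# Mean side-chain volumes (A^3), Zamyatnin-style.
_VOLUME = {
    "A": 88.6, "C": 108.5, "D": 111.1, "E": 138.4, "F": 189.9,
    "G": 60.1, "H": 153.2, "I": 166.7, "K": 168.6, "L": 166.7,
    "M": 162.9, "N": 114.1, "P": 112.7, "Q": 143.8, "R": 173.4,
    "S": 89.0, "T": 116.1, "V": 140.0, "W": 227.8, "Y": 193.6,
}

_CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0}

RAMA_CLASSES = ("alphaR", "beta", "alphaL", "other")

# P(aa | Ramachandran class), relative weights; columns are normalized below.
# alphaR: classical helix formers up, Gly/Pro and beta-branched down.
# beta: beta-branched and aromatic up.
# alphaL: strongly Gly, then Asn/Asp - residues tolerating positive phi.
# other: turn-like composition (Gly/Pro/Ser/Asn/Asp elevated), rest flat.
_PROPENSITY = {
    #        alphaR beta  alphaL other
    "A": (1.45, 0.80, 0.30, 0.80),
    "C": (0.75, 1.15, 0.30, 0.90),
    "D": (0.90, 0.55, 1.60, 1.45),
    "E": (1.45, 0.70, 0.35, 0.75),
    "F": (1.05, 1.35, 0.30, 0.65),
    "G": (0.45, 0.60, 4.20, 1.80),
    "H": (1.00, 0.95, 0.60, 0.95),
    "I": (1.00, 1.65, 0.20, 0.50),
    "K": (1.20, 0.80, 0.45, 0.95),
    "L": (1.40, 1.10, 0.25, 0.60),
    "M": (1.30, 1.05, 0.30, 0.65),
    "N": (0.75, 0.55, 2.10, 1.55),
    "P": (0.60, 0.40, 0.15, 1.50),
    "Q": (1.30, 0.85, 0.40, 0.85),
    "R": (1.20, 0.90, 0.45, 0.90),
    "S": (0.80, 0.90, 0.60, 1.40),
    "T": (0.80, 1.20, 0.45, 1.05),
    "V": (1.00, 1.75, 0.20, 0.50),
    "W": (1.05, 1.30, 0.35, 0.70),
    "Y": (0.95, 1.35, 0.40, 0.75),
}


def default_propensity_table() -> np.ndarray:
    """20x4 table of P(aa | RamaClass); columns sum to 1."""
    t = np.array([_PROPENSITY[a] for a in ALPHABET], dtype=float)
    return t / t.sum(axis=0, keepdims=True)


def hydropathy_vector() -> np.ndarray:
    """Kyte-Doolittle hydropathy rescaled to [0, 1]."""
    v = np.array([_KYTE_DOOLITTLE[a] for a in ALPHABET], dtype=float)
    return (v - v.min()) / (v.max() - v.min())


def charge_vector() -> np.ndarray:
    return np.array([_CHARGE.get(a, 0.0) for a in ALPHABET], dtype=float)


def volume_vector() -> np.ndarray:
    """Side-chain volumes rescaled to [0, 1]."""
    v = np.array([_VOLUME[a] for a in ALPHABET], dtype=float)
    return (v - v.min()) / (v.max() - v.min())


def uniform_background() -> np.ndarray:
    return np.full(N_AA, 1.0 / N_AA)
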
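"""Residue-level reference tables used across the pipeline.

All tables are keyed by one-letter amino-acid code unless noted.
"""

from __future__ import annotations

#: The 20 standard amino acids, three-letter -> one-letter.
THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

STANDARD_AA3 = frozenset(THREE_TO_ONE)

#: Theoretical maximum solvent-accessible surface area per residue type, in A^2
#: (Tien et al. 2013, theoretical column).  Used to normalise absolute SASA
#: into relative SASA.
MAX_SASA_TIEN: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Chou-Fasman beta-turn propensities P(t).
CHOU_FASMAN_TURN: dict[str, float] = {
    "A": 0.66, "R": 0.95, "N": 1.56, "D": 1.46, "C": 1.19,
    "Q": 0.98, "E": 0.74, "G": 1.56, "H": 0.95, "I": 0.47,
    "L": 0.59, "K": 1.01, "M": 0.60, "F": 0.60, "P": 1.52,
    "S": 1.43, "T": 0.96, "W": 0.96, "Y": 1.14, "V": 0.50,
}

#: Residues counted by the WRYP content score (Trp, Arg, Tyr, Pro).
WRYP = frozenset("WRYP")

#: Van der Waals radii by element symbol, in Angstrom (Bondi set, as used by
#: common Shrake-Rupley implementations).  Unknown elements fall back to
#: :data:`DEFAULT_VDW_RADIUS`.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "HE": 1.40, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "NA": 2.27, "MG": 1.73, "P": 1.80, "S": 1.80, "CL": 1.75, "K": 2.75,
    "CA": 2.31, "NI": 1.63, "CU": 1.40, "ZN": 1.39, "SE": 1.90,
    "BR": 1.85, "CD": 1.58, "I": 1.98, "HG": 1.55,
}

DEFAULT_VDW_RADIUS = 1.70

#: Residue names treated as water when filtering heteroatoms.
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})
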
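"""Built-in reference tables: amino-acid codes, background frequencies,
van der Waals radii, and unfolded-state maximal accessibilities.

All tables are overridable at call sites; these defaults are the values a
practitioner would reach for (Swiss-Prot composition statistics, the
theoretical Gly-X-Gly maximal accessibilities of Tien et al. 2013, and
standard van der Waals radii).
"""

from __future__ import annotations

AMINO3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # selenomethionine is treated as protein
    "MSE": "M",
}

AMINO1_TO_3 = {v: k for k, v in AMINO3_TO_1.items() if k != "MSE"}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

GAP_CHARS = frozenset("-.")

# Database-wide amino-acid composition (Swiss-Prot release statistics),
# renormalized to sum exactly to 1.
_BG_RAW = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38,
    "Q": 3.93, "E": 6.72, "G": 7.07, "H": 2.27, "I": 5.91,
    "L": 9.65, "K": 5.80, "M": 2.41, "F": 3.86, "P": 4.74,
    "S": 6.65, "T": 5.36, "W": 1.10, "Y": 2.92, "V": 6.86,
}
_total = sum(_BG_RAW.values())
BACKGROUND_FREQUENCIES = {aa: v / _total for aa, v in _BG_RAW.items()}

# Theoretical maximal solvent accessibility in a Gly-X-Gly tripeptide, A^2
# (Tien et al. 2013).
MAX_ACCESSIBILITY = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLU": 223.0, "GLN": 225.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

# van der Waals radii by element, A (Bondi). Unknown elements raise at the
# call site rather than silently defaulting.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85,
    "I": 1.98, "FE": 2.00, "ZN": 1.39, "MG": 1.73, "CA": 2.00,
    "MN": 2.00, "NA": 2.27, "K": 2.75,
}
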
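"""Reference tables: amino-acid codes, physico-chemical classes, hydropathy
scale, atomic radii and maximal accessible areas.

These are the fixed lookup data the rest of the package builds on. The
polarity partition (polar / apolar / charged) is the one used by the
contacts-based affinity predictor; hydropathy follows the Kyte–Doolittle
index with the conventional sign rule (index > 0 = hydrophobic). Atomic
radii are NACCESS-compatible values (Chothia-style: N 1.65, O 1.40,
S 1.85, sp3 C 1.87, sp2/aromatic/carbonyl C 1.76 Å).
"""

from __future__ import annotations

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

#: Modified residues mapped to their standard parent; anything else
#: non-standard is skipped with a warning at parse time.
MODIFIED_PARENT: dict[str, str] = {
    "MSE": "MET", "SEC": "CYS", "CSO": "CYS", "SEP": "SER",
    "TPO": "THR", "PTR": "TYR", "MLY": "LYS", "HYP": "PRO",
}

# Leucine is assigned apolar: it is the one aliphatic residue absent from
# the published class lists, and both its chemistry and its Kyte-Doolittle
# index (+3.8) place it squarely with the other aliphatics.
POLAR = frozenset("CHNQSTYW")
APOLAR = frozenset("AFGIVMPL")
CHARGED = frozenset("EDKR")

POLARITY_CLASS: dict[str, str] = {}
for _aa in POLAR:
    POLARITY_CLASS[_aa] = "polar"
for _aa in APOLAR:
    POLARITY_CLASS[_aa] = "apolar"
for _aa in CHARGED:
    POLARITY_CLASS[_aa] = "charged"

#: Kyte & Doolittle hydropathy index (kcal/mol-free scale, dimensionless).
KD_INDEX: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: Maximal accessible surface area per residue type (Ala-X-Ala references,
#: theoretical values of Tien et al.), Å². Used for relative accessibility.
MAX_ASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# sp2 / aromatic / carboxyl-amide side-chain carbons assigned the smaller
# 1.76 Å radius; all other carbons are 1.87 Å (NACCESS convention).
_SP2_CARBONS: frozenset[tuple[str, str]] = frozenset(
    [("*", "C")]  # backbone carbonyl carbon of every residue
    + [("PHE", a) for a in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")]
    + [("TYR", a) for a in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")]
    + [("TRP", a) for a in ("CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")]
    + [("HIS", a) for a in ("CG", "CD2", "CE1")]
    + [("ARG", "CZ"), ("ASP", "CG"), ("GLU", "CD"),
       ("ASN", "CG"), ("GLN", "CD")]
)

_ELEMENT_RADIUS: dict[str, float] = {
    "N": 1.65, "O": 1.40, "S": 1.85, "P": 1.90, "C": 1.87,
}


def atom_radius(res_name: str, atom_name: str, element: str) -> float:
    """Van der Waals radius (Å) of a heavy atom, NACCESS-compatible."""
    element = element.upper()
    if element == "C":
        if atom_name == "C" or (res_name, atom_name) in _SP2_CARBONS:
            return 1.76
        return 1.87
    return _ELEMENT_RADIUS.get(element, 1.80)
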
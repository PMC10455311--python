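"""Shared residue-level constants: alphabets, groupings, maximum ASA."""

from __future__ import annotations

# Canonical one-letter codes, alphabetical. All feature layouts iterate
# in this order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

AA_SET = frozenset(AMINO_ACIDS)

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Seven-state secondary structure alphabet (alpha helix, 3-10 helix,
# pi helix, extended strand, isolated bridge, turn, coil).
SS7_STATES = ("H", "G", "I", "E", "B", "T", "C")

# Maximum accessible surface area per residue (theoretical, A^2),
# Tien et al. 2013, used to normalise ASA into RSA.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# Residue classes used for the five sequence-window composition
# features.  These are overlapping views, not a partition.
WINDOW_GROUPS = {
    "NonPolarAA": frozenset("GAVLIPFMW"),
    "PolarAA": frozenset("STCYNQ"),
    "ChargedAA": frozenset("DEKRH"),
    "PosAA": frozenset("KRH"),
    "NegAA": frozenset("DE"),
}

# Default six-way physicochemical partition for the 6x6 variation-type
# matrix.  g2 (negatively charged) and g6 (other) are pinned by the
# published feature names; the rest follow standard property classes.
# Overridable via a JSON config (features/data/residue_groups.json).
SIX_GROUPS = {
    "g1": frozenset("ILMV"),   # nonpolar aliphatic
    "g2": frozenset("DE"),     # negatively charged
    "g3": frozenset("FWY"),    # aromatic
    "g4": frozenset("NQSC"),   # polar uncharged
    "g5": frozenset("HKR"),    # positively charged
    "g6": frozenset("AGPT"),   # other
}

# Van der Waals radii (A) for the solvent accessibility computation.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
    "P": 1.80, "SE": 1.90,
}
DEFAULT_VDW_RADIUS = 1.80

PROBE_RADIUS = 1.4


def six_group_of(aa: str, groups=None) -> str:
    """Return the group id of ``aa`` under a six-way partition."""
    groups = SIX_GROUPS if groups is None else groups
    for name, members in groups.items():
        if aa in members:
            return name
    raise KeyError(f"residue {aa!r} is not covered by the group partition")
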
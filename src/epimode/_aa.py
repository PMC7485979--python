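"""Amino-acid lookup tables shared across modules."""

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# Coarse physicochemical classes; used by the disruption proxy and the
# residue-level contact potential.
AA_CLASS = {
    "A": "hydrophobic", "V": "hydrophobic", "L": "hydrophobic",
    "I": "hydrophobic", "M": "hydrophobic", "C": "hydrophobic",
    "F": "aromatic", "W": "aromatic", "Y": "aromatic",
    "S": "polar", "T": "polar", "N": "polar", "Q": "polar", "H": "polar",
    "K": "positive", "R": "positive",
    "D": "negative", "E": "negative",
    "G": "special", "P": "special",
}


def aa_class(one_letter: str) -> str:
    return AA_CLASS[one_letter.upper()]


def default_substitution(wt: str) -> str:
    """Default binding-disruptive substitution for a wild-type residue.

    Charge reversal for charged residues, lysine otherwise: charged and
    bulky-polar replacements are the classic way to break an interface
    without hollowing out the protein core.
    """
    wt = wt.upper()
    return "E" if wt in "KR" else "K"
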
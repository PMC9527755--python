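"""Chemical formulas of amino-acid residues in a peptide chain.

Each entry gives the element counts of the residue (free amino acid minus one
water) with all exchangeable sites protonated and side chains in their neutral
form, plus the number of labile hydrogens (bound to N, O or S) for the
H/D-exchange bookkeeping.  Chain termini (extra H and OH) are not counted.
"""

# name -> (C, H, N, O, S, labile_H)
RESIDUE_FORMULAS: dict[str, tuple[int, int, int, int, int, int]] = {
    "GLY": (2, 3, 1, 1, 0, 1),
    "ALA": (3, 5, 1, 1, 0, 1),
    "VAL": (5, 9, 1, 1, 0, 1),
    "LEU": (6, 11, 1, 1, 0, 1),
    "ILE": (6, 11, 1, 1, 0, 1),
    "PRO": (5, 7, 1, 1, 0, 0),
    "PHE": (9, 9, 1, 1, 0, 1),
    "TRP": (11, 10, 2, 1, 0, 2),
    "MET": (5, 9, 1, 1, 1, 1),
    "SER": (3, 5, 1, 2, 0, 2),
    "THR": (4, 7, 1, 2, 0, 2),
    "CYS": (3, 5, 1, 1, 1, 2),
    "TYR": (9, 9, 1, 2, 0, 2),
    "ASN": (4, 6, 2, 2, 0, 3),
    "GLN": (5, 8, 2, 2, 0, 3),
    "ASP": (4, 5, 1, 3, 0, 2),
    "GLU": (5, 7, 1, 3, 0, 2),
    "LYS": (6, 12, 2, 1, 0, 3),
    "ARG": (6, 12, 4, 1, 0, 5),
    "HIS": (6, 7, 3, 1, 0, 2),
}

ELEMENT_ORDER = ("C", "H", "N", "O", "S")
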
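"""Physical constants and canonical sequences used across the package.

All masses are monoisotopic and in daltons. Residue masses are the standard
amino-acid *residue* masses (peptide-bond water already removed), computed
from CODATA/AME elemental monoisotopic masses so that derived peptide
masses carry full precision; a free peptide is the residue sum plus one
water.
"""

from __future__ import annotations

# monoisotopic element masses (Da)
_H = 1.00782503207
_C = 12.0
_N = 14.0030740048
_O = 15.99491461956
_S = 31.97207100

#: Elemental composition (C, H, N, O, S) of each amino-acid residue.
RESIDUE_COMPOSITIONS: dict[str, tuple[int, int, int, int, int]] = {
    "G": (2, 3, 1, 1, 0),
    "A": (3, 5, 1, 1, 0),
    "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0),
    "V": (5, 9, 1, 1, 0),
    "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1),
    "L": (6, 11, 1, 1, 0),
    "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0),
    "D": (4, 5, 1, 3, 0),
    "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0),
    "E": (5, 7, 1, 3, 0),
    "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0),
    "F": (9, 9, 1, 1, 0),
    "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0),
    "W": (11, 10, 2, 1, 0),
}


def _mass(c: int, h: int, n: int, o: int, s: int) -> float:
    return c * _C + h * _H + n * _N + o * _O + s * _S


#: Monoisotopic residue masses for the 20 proteinogenic amino acids (Da).
MONOISOTOPIC_RESIDUE_MASSES: dict[str, float] = {
    aa: _mass(*comp) for aa, comp in RESIDUE_COMPOSITIONS.items()
}

#: Monoisotopic mass of water (Da); one dehydration removes exactly this.
WATER_MONO = _mass(0, 2, 0, 1, 0)  # 18.0105646...

#: Monoisotopic proton mass (Da), for charge-state m/z arithmetic.
PROTON_MASS = 1.00727646688

#: Monoisotopic mass of one N-ethylmaleimide adduct on a free Cys thiol
#: (C6H7NO2, Da). Reported nominally as a +125 Da shift.
NEM_ADDUCT_MONO = _mass(6, 7, 1, 2, 0)  # 125.0476784...
NEM_ADDUCT_NOMINAL = 125

#: Nisin activity unit conversion: 40 international units per microgram.
IU_PER_MICROGRAM = 40.0

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Conserved N-terminal motif of nisin-like core peptides; lowercase 'x'
#: matches any residue.
CORE_MOTIF = "SxSLCTPGCxTG"

#: Canonical NisA leader peptide. External constant (not derivable from the
#: packaged data); every leader-fusion entry point accepts an override.
NISIN_LEADER = "MSTKDFNLDLVSVSKKDSGASPR"

#: Core peptide of nisin Z (N27 natural variant of nisin A).
NISIN_Z_CORE = "ITSISLCTPGCKTGALMGCNMKTATCNCSIHVSK"

#: Positions of nisin Z core residues in non-conserved regions targeted by
#: saturation mutagenesis (1-based on the core peptide).
SATURATION_POSITIONS = (4, 12, 15, 24, 29)
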
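"""Physical constants and the monoisotopic residue mass table.

All masses are monoisotopic and in Daltons (unified atomic mass units).
The residue table covers the 20 canonical amino acids plus selenocysteine
(U).  Ambiguity codes (B, J, X, Z) and pyrrolysine (O) are deliberately
absent: peptides spanning them have no single defined mass and are skipped
during digestion rather than assigned a fabricated value.
"""

from __future__ import annotations

# Monoisotopic residue (amino-acid minus water) masses, Da.
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146372057,
    "A": 71.03711378471,
    "S": 87.03202840427,
    "P": 97.05276384885,
    "V": 99.06841391299,
    "T": 101.04767846841,
    "C": 103.00918478471,
    "L": 113.08406397713,
    "I": 113.08406397713,
    "N": 114.04292744114,
    "D": 115.02694302383,
    "Q": 128.05857750528,
    "K": 128.09496301400,
    "E": 129.04259308797,
    "M": 131.04048491299,
    "H": 137.05891185845,
    "F": 147.06841391299,
    "R": 156.10111102360,
    "Y": 163.06332853255,
    "W": 186.07931294986,
    "U": 150.95363508471,  # selenocysteine
}

#: Monoisotopic mass of one water molecule, Da (added once per peptide).
WATER_MASS = 18.0105646837

#: Mass of a proton, Da (charge carrier for m/z conversions and ions).
PROTON_MASS = 1.00727646677

#: The 20 canonical residues (used as the default synthetic alphabet).
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
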
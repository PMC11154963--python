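"""Physical constants and small chemical lookup tables.

Monoisotopic atomic masses are hard-coded to six decimals from the standard
(most abundant isotope) atomic-mass table; electrospray charging uses the
proton mass, not the hydrogen atom mass.
"""

from __future__ import annotations

#: Monoisotopic mass of the most abundant isotope, Da (6 decimals).
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.000000,
    "H": 1.007825,
    "N": 14.003074,
    "O": 15.994915,
    "S": 31.972071,
    "P": 30.973762,
    "Cl": 34.968853,
    "F": 18.998403,
    "Br": 78.918338,
    "Na": 22.989770,
    "I": 126.904473,
}

PROTON_MASS = 1.007276  # Da
ELECTRON_MASS = 0.000549  # Da

#: 13C - 12C mass difference, Da; spacing of carbon isotopologue satellites.
C13_DELTA = 1.003355

#: Natural 13C abundance per carbon atom (approximate M+1/M intensity ratio
#: contribution per carbon).
C13_ABUNDANCE = 0.011

# Common ESI adduct mass deltas (Da) relative to the neutral molecule.
# Charging adds/removes a proton; metal adducts lose one electron.
ADDUCT_DELTAS: dict[str, tuple[float, int]] = {
    "[M+H]+": (PROTON_MASS, +1),
    "[M+Na]+": (MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS, +1),
    "[M+NH4]+": (
        MONOISOTOPIC_MASS["N"] + 4 * MONOISOTOPIC_MASS["H"] + PROTON_MASS,
        +1,
    ),
    "[M-H]-": (-PROTON_MASS, -1),
}

# Neutral losses diagnostic of phase-II conjugates (Da).
GLUCURONIDE_LOSS = 176.032090  # C6H8O6
SULFATE_LOSS = 79.956816  # SO3
DEFAULT_NEUTRAL_LOSSES: list[tuple[str, float]] = [
    ("glucuronide", GLUCURONIDE_LOSS),
    ("sulfate", SULFATE_LOSS),
]

# Negative-mode diagnostic fragment ions for conjugate classes, m/z.
# Values computed from elemental composition with the mass table above
# (anion mass = neutral fragment + one electron):
#   glucuronide: C6H7O6-  (deprotonated dehydrated glucuronic acid) and
#                C5H5O3-  (further loss of CH2O3)
#   glutathione: deprotonated glutathione C10H16N3O6S-
DEFAULT_DIAGNOSTIC_FRAGMENTS: list[tuple[str, float]] = [
    ("glucuronide", 175.024814),
    ("glucuronide", 113.024419),
    ("glutathione", 306.076530),
]

# Biotransformation formula deltas (element -> count change) and the
# metabolism phase of the reaction class.  Functionalization reactions are
# phase I; conjugations are phase II.
TRANSFORMATIONS: dict[str, tuple[dict[str, int], str]] = {
    "hydroxylation": ({"O": +1}, "I"),
    "carboxylation": ({"O": +2, "H": -2}, "I"),  # methyl -> carboxylic acid
    "demethylation": ({"C": -1, "H": -2}, "I"),
    "o_dealkylation": ({"C": -1, "H": -2}, "I"),
    "n_dealkylation": ({"C": -1, "H": -2}, "I"),
    "deacetylation": ({"C": -2, "H": -2, "O": -1}, "I"),
    "glucuronidation": ({"C": +6, "H": +8, "O": +6}, "II"),
    "sulfation": ({"S": +1, "O": +3}, "II"),
}
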
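"""Physical constants for accurate-mass arithmetic.

Single point of truth: every m/z computed anywhere in the package reads
from these tables, so an audit of the mass arithmetic is a one-file job.
Monoisotopic masses are the CODATA/IUPAC values in Da.
"""

from __future__ import annotations

#: Monoisotopic atomic masses (Da) of the element symbols accepted in
#: elemental formulas.  C-12 defines the scale and is exact.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.99491461956,
    "Na": 22.9897692809,
    "S": 31.97207100,
    "P": 30.97376163,
}

#: Mass of a proton (Da) — the charge carrier of [M+H]+ / [M-H]-.
PROTON_MASS: float = 1.00727646688

#: Electron rest mass (Da) — accounts for the electron gained or lost on
#: ionization of non-protonated adducts.
ELECTRON_MASS: float = 0.00054857991

# Acetate (CH3COO, i.e. C2H3O2) neutral-fragment monoisotopic mass.
_ACETATE_MASS: float = (
    2 * MONOISOTOPIC_MASS["C"]
    + 3 * MONOISOTOPIC_MASS["H"]
    + 2 * MONOISOTOPIC_MASS["O"]
)

#: m/z offsets (Th) from the neutral monoisotopic mass for the singly
#: charged quasi-molecular ions used in annotation.  Charge carrier and
#: electron mass are both included: e.g. [M+Na]+ loses one electron,
#: [M+CH3COO]- gains one.
ADDUCT_MASS_DELTA: dict[str, float] = {
    "[M+H]+": PROTON_MASS,
    "[M-H]-": -PROTON_MASS,
    "[M+Na]+": MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS,
    "[M+CH3COO]-": _ACETATE_MASS + ELECTRON_MASS,
}

#: Polarity of each standard adduct.
ADDUCT_POLARITY: dict[str, str] = {
    "[M+H]+": "positive",
    "[M-H]-": "negative",
    "[M+Na]+": "positive",
    "[M+CH3COO]-": "negative",
}
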
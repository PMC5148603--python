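"""Physical constants shared by every module.

All isotope masses are in daltons (Da); abundances are mole fractions.
Values are pinned here so that envelope synthesis, deconvolution and the
test oracles agree to the last digit.
"""

from __future__ import annotations

#: Mass added per H -> D substitution (Da).
DEUTERIUM_MASS_SHIFT = 1.00628

#: Proton mass used for m/z conversion (Da).
PROTON_MASS = 1.00728

#: Stable-isotope masses (Da) and representative abundances for the five
#: elements of unmodified peptides, IUPAC representative values.  Each entry
#: is ordered by mass; the first isotope is the monoisotopic species.
ISOTOPES: dict[str, tuple[tuple[float, float], ...]] = {
    "C": ((12.0, 0.9893), (13.003355, 0.0107)),
    "H": ((1.007825032, 0.999885), (2.014101778, 0.000115)),
    "N": ((14.003074005, 0.99636), (15.000108898, 0.00364)),
    "O": ((15.994914622, 0.99757), (16.999131757, 0.00038), (17.999159613, 0.00205)),
    "S": ((31.972070690, 0.9499), (32.971458500, 0.0075), (33.967866830, 0.0425),
          (35.967080880, 0.0001)),
}

#: Average atomic masses (Da) derived from :data:`ISOTOPES`.
AVERAGE_MASS: dict[str, float] = {
    el: sum(m * p for m, p in isos) for el, isos in ISOTOPES.items()
}

#: Monoisotopic masses (Da) of the first-listed isotope of each element.
MONOISOTOPIC_MASS: dict[str, float] = {el: isos[0][0] for el, isos in ISOTOPES.items()}

#: Elemental composition of one water molecule (peptide termini).
WATER: dict[str, int] = {"H": 2, "O": 1}

#: Residue (dehydrated) elemental compositions of the 20 standard amino acids.
RESIDUE_COMPOSITIONS: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

#: Averagine model unit: the average elemental composition of one residue of
#: a typical protein, used as a stand-in composition when only the peptide
#: mass is known.
AVERAGINE_UNIT: dict[str, float] = {
    "C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417,
}

#: Average mass of one averagine unit (Da).
AVERAGINE_UNIT_MASS = 111.1254
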
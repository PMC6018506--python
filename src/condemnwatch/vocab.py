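"""Closed category vocabularies for US federally inspected cattle slaughter data.

Postmortem inspection records carry one of nine cattle-type categories and one
of 35 condemnation-reason categories (FSIS disposition codes).  Both sets are
closed: rows with values outside them are rejected at parse time.
"""

from __future__ import annotations

#: The nine cattle types distinguished at federally inspected slaughter.
CATTLE_TYPES: tuple[str, ...] = (
    "beef_cow",
    "bob_veal",
    "bull_stag",
    "dairy_cow",
    "formula_fed_veal",
    "heavy_calf",
    "heifer",
    "non_formula_fed_veal",
    "steer",
)

#: The 35 postmortem condemnation-reason categories.
CONDEMNATION_REASONS: tuple[str, ...] = (
    "abscess_pyemia",
    "anaplasmosis",
    "anasarca",
    "arthritis",
    "carcinoma",
    "caseous_lymphadenitis",
    "cns_disorder",
    "coccidioidal_granuloma",
    "contamination",
    "cysticercosis",
    "emaciation",
    "eosinophilic_myositis",
    "epithelioma",
    "icterus",
    "injuries",
    "malignant_lymphoma",
    "mastitis",
    "melanoma",
    "metritis",
    "misc_degenerative",
    "misc_infectious",
    "misc_inflammatory",
    "moribund",
    "necrosis",
    "nephritis_pyelitis",
    "pericarditis",
    "peritonitis",
    "pneumonia",
    "residue",
    "sarcoma",
    "septicemia",
    "sexual_odor",
    "tetanus",
    "toxemia",
    "tuberculosis",
)

#: Number of monthly samples in one year.
SAMPLES_PER_YEAR: int = 12


def theoretical_periods(T: int = SAMPLES_PER_YEAR, n: int = 6) -> tuple[float, ...]:
    """Theoretical seasonal periods T/j, j = 1..n, in months per cycle.

    For monthly data (T = 12) these are 12, 6, 4, 3, 2.4 and 2 months/cycle:
    the annual cycle and its harmonics up to the Nyquist period.
    """
    return tuple(round(T / j, 10) for j in range(1, n + 1))
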
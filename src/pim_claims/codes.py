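"""Default ICD-10 prefix lists and the default drug dictionary.

These lists are representative, configurable stand-ins for full
claims-algorithm code sets: condition detection matches on code prefixes
(dotless uppercase), so "M15-M19" means any code whose first three
characters fall in that range.  Every list can be overridden through the
relevant config object.
"""

from __future__ import annotations

import pandas as pd

# Osteoarthritis, any site (hip, knee, other).
OA_PREFIXES = ("M15", "M16", "M17", "M18", "M19")

# Table-1-style GI risk conditions.
GI_CONDITION_PREFIXES: dict[str, tuple[str, ...]] = {
    "complicated_peptic_ulcer": (
        "K250", "K251", "K252", "K254", "K255", "K256",
        "K260", "K261", "K262", "K264", "K265", "K266",
    ),
    "uncomplicated_peptic_ulcer": ("K253", "K257", "K259", "K263", "K267", "K269", "K27"),
    "dyspepsia": ("K30",),
    "gerd": ("K21",),
}

# Table-1-style CV risk conditions.
CV_CONDITION_PREFIXES: dict[str, tuple[str, ...]] = {
    "angina": ("I20",),
    "stroke": ("I63", "I64"),
    "myocardial_infarction": ("I21", "I22", "I252"),
    "congestive_heart_failure": ("I50",),
}

# Drug classes whose >=7-day concomitant use with an NSAID confers GI risk.
GI_COMED_CLASSES = ("corticosteroid", "antiplatelet", "ssri", "aspirin", "anticoagulant")

# Baseline chronic-condition features (need factors plus obesity).
CONDITION_PREFIXES: dict[str, tuple[str, ...]] = {
    "asthma": ("J45",),
    "cancer": ("C18", "C34", "C50", "C61", "C64"),
    "cardiac_arrhythmia": ("I47", "I48", "I49"),
    "copd": ("J44",),
    "dementia": ("F01", "F02", "F03", "G30"),
    "anxiety": ("F40", "F41"),
    "depression": ("F32", "F33"),
    "diabetes": ("E10", "E11"),
    "hyperlipidemia": ("E78",),
    "hypertension": ("I10", "I11", "I12", "I13"),
    "substance_abuse": ("F10", "F11", "F12", "F13", "F14", "F19"),
    # Non-OA arthritis/joint pain, headache/migraine, back/neck and neuropathic pain.
    "other_pain": ("M05", "M06", "M54", "G43", "G89", "M79"),
    # Pain in joints commonly affected by OA (hip, knee).
    "oa_pain": ("M2555", "M2556"),
    "obesity": ("E66",),
}

# Drug dictionary: code, ingredient, class.  Codes are opaque synthetic
# identifiers; real NDC dictionaries plug in through the same schema.
_DRUGS = [
    ("D-NAP", "naproxen", "nsaid_nonselective"),
    ("D-IBU", "ibuprofen", "nsaid_nonselective"),
    ("D-DIC", "diclofenac", "nsaid_nonselective"),
    ("D-MEL", "meloxicam", "nsaid_nonselective"),
    ("D-CEL", "celecoxib", "nsaid_selective"),
    ("D-PRE", "prednisone", "corticosteroid"),
    ("D-CLO", "clopidogrel", "antiplatelet"),
    ("D-SER", "sertraline", "ssri"),
    ("D-ASA", "aspirin", "aspirin"),
    ("D-WAR", "warfarin", "anticoagulant"),
    ("D-OXY", "oxycodone", "opioid"),
    ("D-HYD", "hydrocodone", "opioid"),
    ("D-ACE", "acetaminophen", "other"),
]


def default_drug_dictionary() -> pd.DataFrame:
    return pd.DataFrame(_DRUGS, columns=["drug_code", "ingredient", "drug_class"])


CODE_BY_INGREDIENT = {ing: code for code, ing, _ in _DRUGS}

# (unit strength mg, plausible units/day choices) per ingredient.
DOSE_TABLE: dict[str, tuple[float, tuple[float, ...]]] = {
    "naproxen": (500.0, (1.0, 2.0)),          # 500 (dose-exempt) or 1000 mg/day
    "ibuprofen": (400.0, (2.0, 3.0, 6.0)),     # 800 (exempt), 1200, 2400 mg/day
    "diclofenac": (50.0, (2.0, 3.0)),
    "meloxicam": (15.0, (1.0,)),
    "celecoxib": (200.0, (1.0, 2.0)),
    "prednisone": (10.0, (1.0,)),
    "clopidogrel": (75.0, (1.0,)),
    "sertraline": (50.0, (1.0, 2.0)),
    "aspirin": (81.0, (1.0,)),
    "warfarin": (5.0, (1.0,)),
    "oxycodone": (5.0, (2.0, 4.0)),
    "hydrocodone": (5.0, (2.0, 4.0)),
    "acetaminophen": (500.0, (2.0, 6.0)),
}
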
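"""Feature assembly: the per-person modelling table.

Thirty-one features organised along Andersen's healthcare-utilization
groupings — predisposing (age, sex), enabling (insurance type,
fragmentation-of-care index, pain-related treatment counts), need
(14 chronic-condition flags, baseline NSAID duration and type), life
style (obesity, in the condition block), external environment (region)
— plus the four-level CV/GI risk category, one-hot encoded to 36 binary
indicators alongside the continuous columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import codes
from .cohort import has_prefix
from .episodes import total_exposure_days
from .intervals import DateInterval

CONDITION_FLAGS = tuple(codes.CONDITION_PREFIXES)

CONTINUOUS_COLUMNS = (
    "age",
    "fci",
    "n_opioid_rx",
    "n_ia_corticosteroid",
    "n_ia_hyaluronic",
    "n_physical_therapy",
    "baseline_nonselective_days",
    "baseline_selective_days",
)

BINARY_COLUMNS = CONDITION_FLAGS + ("any_nonselective_use", "any_selective_use")

DEFAULT_CATEGORICAL_SPEC: dict[str, tuple[str, ...]] = {
    "sex": ("female", "male"),
    "insurance_type": ("hmo", "other"),
    "region": ("northeast", "midwest", "south", "west"),
    "category": ("high_cv_high_gi", "high_cv_low_gi", "low_cv_high_gi", "low_cv_low_gi"),
}


def compute_fci(provider_counts: dict[str, int] | pd.Series) -> float:
    """Fragmentation-of-care index: 1 minus the Bice-Boxerman concentration.

    With ``N`` total encounters spread over providers as counts ``n_j``,

        FCI = 1 - (sum(n_j^2) - N) / (N (N - 1))

    giving 0 when every encounter is with the same provider and 1 when
    each encounter is with a different provider.  N <= 1 returns 0 by
    convention (no fragmentation is observable).
    """
    counts = np.asarray(list(provider_counts.values()) if isinstance(provider_counts, dict)
                        else provider_counts, dtype=float)
    n = counts.sum()
    if n <= 1:
        return 0.0
    coc = (np.sum(counts**2) - n) / (n * (n - 1))
    return float(1.0 - coc)


@dataclass
class FeatureCodeConfig:
    condition_prefixes: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(codes.CONDITION_PREFIXES)
    )


def assemble_features(
    bundle,
    cohort: pd.DataFrame,
    profiles: pd.DataFrame,
    pim_results: pd.DataFrame,
    baseline: DateInterval,
    config: FeatureCodeConfig | None = None,
) -> pd.DataFrame:
    """One feature row per cohort member, joined with the binary target.

    Counts come from baseline claim service types and opioid-class
    fills; condition flags from baseline ICD prefix matches; NSAID day
    totals from the unbridged covered-day union; the FCI from the
    distribution of baseline encounters over providers.
    """
    config = config or FeatureCodeConfig()
    persons = bundle.persons.set_index("person_id")
    prof = profiles.set_index("person_id")
    pim = pim_results.set_index("person_id")
    missing = set(cohort["person_id"]) - set(prof.index)
    if missing:
        raise ValueError(f"cohort members without a risk profile: {sorted(missing)[:5]}")
    missing = set(cohort["person_id"]) - set(pim.index)
    if missing:
        raise ValueError(f"cohort members without a target: {sorted(missing)[:5]}")

    from .claims import drug_lookup, rows_in_period

    base_claims = rows_in_period(bundle.medical_claims, "service_date", baseline)
    claims_by_person = (
        dict(tuple(base_claims.groupby("person_id", sort=True))) if not base_claims.empty else {}
    )
    empty_claims = base_claims.iloc[0:0]

    base_fills = rows_in_period(bundle.fills, "fill_date", baseline)

    lookup = drug_lookup(bundle.drug_dictionary)
    fills_by_person = dict(tuple(base_fills.groupby("person_id", sort=True)))
    empty_fills = base_fills.iloc[0:0]

    rows = []
    for r in cohort.itertuples():
        pid = r.person_id
        person = persons.loc[pid]
        pclaims = claims_by_person.get(pid, empty_claims)
        pfills = fills_by_person.get(pid, empty_fills)

        provider_counts = pclaims["provider_id"].value_counts()
        service = pclaims["service_type"].value_counts()
        n_opioid = sum(1 for c in pfills["drug_code"] if lookup[c].drug_class == "opioid")

        nonsel_days = total_exposure_days(pfills, bundle.drug_dictionary, "nsaid_nonselective", baseline)
        sel_days = total_exposure_days(pfills, bundle.drug_dictionary, "nsaid_selective", baseline)

        row = {
            "person_id": pid,
            "age": int(r.age),
            "sex": person["sex"],
            "region": person["region"],
            "insurance_type": person["insurance_type"],
            "fci": compute_fci(provider_counts.to_dict()),
            "n_opioid_rx": int(n_opioid),
            "n_ia_corticosteroid": int(service.get("ia_corticosteroid", 0)),
            "n_ia_hyaluronic": int(service.get("ia_hyaluronic_acid", 0)),
            "n_physical_therapy": int(service.get("physical_therapy", 0)),
            "baseline_nonselective_days": nonsel_days,
            "baseline_selective_days": sel_days,
            "any_nonselective_use": int(nonsel_days > 0),
            "any_selective_use": int(sel_days > 0),
            "category": prof.loc[pid, "category"],
            "pim": int(bool(pim.loc[pid, "pim"])),
        }
        diag_lists = list(pclaims["diagnosis_codes"])
        for cond, prefixes in config.condition_prefixes.items():
            row[cond] = int(
                any(has_prefix(code, prefixes) for codes_ in diag_lists for code in codes_)
            )
        rows.append(row)

    columns = (
        ["person_id", "age", "sex", "region", "insurance_type", "fci",
         "n_opioid_rx", "n_ia_corticosteroid", "n_ia_hyaluronic", "n_physical_therapy"]
        + list(CONDITION_FLAGS)
        + ["baseline_nonselective_days", "baseline_selective_days",
           "any_nonselective_use", "any_selective_use", "category", "pim"]
    )
    return pd.DataFrame(rows, columns=columns)


def one_hot(
    features: pd.DataFrame,
    categorical_spec: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Expand each k-level categorical into k binary indicator columns.

    The default spec expands sex, insurance type, region and risk
    category, yielding 36 model-matrix columns (8 continuous + 16 binary
    flags + 12 categorical indicators).  An unseen level raises.
    """
    spec = categorical_spec or DEFAULT_CATEGORICAL_SPEC
    out = features.drop(columns=["person_id", "pim"], errors="ignore").copy()
    for col, levels in spec.items():
        unseen = set(out[col]) - set(levels)
        if unseen:
            raise ValueError(f"column {col!r} has unseen levels {sorted(unseen)}")
        for level in levels:
            out[f"{col}_{level}"] = (out[col] == level).astype(int)
        out = out.drop(columns=[col])
    return out.astype(float)
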
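"""CV/GI risk stratification from baseline diagnoses and co-medication.

Because the cohort is restricted to older adults — age itself being a
minor GI risk factor — a single additional GI factor (peptic ulcer
disease, dyspepsia, GERD, or >= 7 consecutive days of an ulcerogenic
co-medication taken concomitantly with an NSAID) places a person in the
high-GI category.  One CV factor (angina, stroke, myocardial
infarction, congestive heart failure) places them in high-CV.  The two
flags combine into the four-level category used by the inappropriate-use
rules.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd

from . import codes
from .claims import NSAID_CLASSES
from .cohort import has_prefix
from .episodes import DEFAULT_GAP_DAYS, build_episodes, max_concomitant_run
from .intervals import DateInterval


class RiskCategory(str, enum.Enum):
    HIGH_CV_HIGH_GI = "high_cv_high_gi"
    HIGH_CV_LOW_GI = "high_cv_low_gi"
    LOW_CV_HIGH_GI = "low_cv_high_gi"
    LOW_CV_LOW_GI = "low_cv_low_gi"


CATEGORY_ORDER = (
    RiskCategory.HIGH_CV_HIGH_GI,
    RiskCategory.HIGH_CV_LOW_GI,
    RiskCategory.LOW_CV_HIGH_GI,
    RiskCategory.LOW_CV_LOW_GI,
)


@dataclass
class RiskCodeConfig:
    gi_condition_prefixes: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(codes.GI_CONDITION_PREFIXES)
    )
    cv_condition_prefixes: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(codes.CV_CONDITION_PREFIXES)
    )
    gi_comed_classes: tuple[str, ...] = codes.GI_COMED_CLASSES
    concomitant_min_days: int = 7
    # If False, >=7 consecutive days of the co-medication alone (no NSAID
    # overlap) confers the GI factor — the alternative reading.
    require_nsaid_overlap: bool = True


def assign_category(gi_high: bool, cv_high: bool) -> RiskCategory:
    if cv_high:
        return RiskCategory.HIGH_CV_HIGH_GI if gi_high else RiskCategory.HIGH_CV_LOW_GI
    return RiskCategory.LOW_CV_HIGH_GI if gi_high else RiskCategory.LOW_CV_LOW_GI


def _condition_factors(
    diagnosis_lists, prefix_map: dict[str, tuple[str, ...]]
) -> list[str]:
    found = []
    for name, prefixes in prefix_map.items():
        if any(
            has_prefix(code, prefixes) for codes_ in diagnosis_lists for code in codes_
        ):
            found.append(name)
    return found


def detect_cv_high(person_claims: pd.DataFrame, config: RiskCodeConfig) -> tuple[bool, list[str]]:
    """>=1 CV condition code in baseline claims."""
    factors = _condition_factors(person_claims["diagnosis_codes"], config.cv_condition_prefixes)
    return bool(factors), factors


def detect_gi_high(
    person_claims: pd.DataFrame,
    nsaid_intervals: list[DateInterval],
    comed_intervals_by_class: dict[str, list[DateInterval]],
    config: RiskCodeConfig,
) -> tuple[bool, list[str]]:
    """>=1 GI condition code, or >=7-day concomitant ulcerogenic co-medication.

    All inputs must already be restricted to the baseline period.
    """
    factors = _condition_factors(person_claims["diagnosis_codes"], config.gi_condition_prefixes)
    for cls in config.gi_comed_classes:
        comed = comed_intervals_by_class.get(cls, [])
        if not comed:
            continue
        if config.require_nsaid_overlap:
            run = max_concomitant_run(nsaid_intervals, comed)
        else:
            run = max((iv.length for iv in comed), default=0)
        if run >= config.concomitant_min_days:
            factors.append(f"concomitant_{cls}")
    return bool(factors), factors


def profile_cohort(
    bundle,
    cohort_ids,
    baseline: DateInterval,
    config: RiskCodeConfig | None = None,
    gap: int = DEFAULT_GAP_DAYS,
) -> pd.DataFrame:
    """Assign one RiskProfile row per cohort member.

    Returns a DataFrame (person_id, gi_high, cv_high, category, factors).
    """
    config = config or RiskCodeConfig()
    cohort_ids = sorted(cohort_ids)
    from .claims import rows_in_period

    base_claims = rows_in_period(bundle.medical_claims, "service_date", baseline)
    classes = set(NSAID_CLASSES) | set(config.gi_comed_classes)
    episodes = build_episodes(
        bundle.fills, bundle.drug_dictionary, classes=classes, gap=gap, period=baseline
    )
    by_person: dict[str, dict[str, list[DateInterval]]] = {}
    for ep in episodes:
        by_person.setdefault(ep.person_id, {}).setdefault(ep.drug_class, []).append(ep.interval)

    claims_by_person = dict(tuple(base_claims.groupby("person_id", sort=True)))
    empty = base_claims.iloc[0:0]
    rows = []
    for pid in cohort_ids:
        pclaims = claims_by_person.get(pid, empty)
        pintervals = by_person.get(pid, {})
        nsaid = [iv for cls in NSAID_CLASSES for iv in pintervals.get(cls, [])]
        cv_high, cv_factors = detect_cv_high(pclaims, config)
        gi_high, gi_factors = detect_gi_high(pclaims, nsaid, pintervals, config)
        rows.append(
            {
                "person_id": pid,
                "gi_high": gi_high,
                "cv_high": cv_high,
                "category": assign_category(gi_high, cv_high).value,
                "factors": ";".join(gi_factors + cv_factors),
            }
        )
    return pd.DataFrame(rows, columns=["person_id", "gi_high", "cv_high", "category", "factors"])
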
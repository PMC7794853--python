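"""Analytic cohort: older adults with osteoarthritis, continuously enrolled.

A person enters the cohort when all three gates pass:

* osteoarthritis at baseline — one inpatient claim, or two outpatient
  claims at least 30 days apart, carrying an OA-prefix diagnosis code;
* continuous enrollment with both medical and pharmacy benefits over the
  full 24-month baseline + follow-up window, with zero uncovered days;
* age >= 65 at the start of the baseline year (baseline_year - birth_year).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import codes
from .intervals import DateInterval, covers_every_day, year_interval


@dataclass
class CohortConfig:
    baseline_year: int = 2015
    followup_year: int = 2016
    oa_code_prefixes: tuple[str, ...] = codes.OA_PREFIXES
    min_age: int = 65
    outpatient_min_separation: int = 30

    @property
    def baseline(self) -> DateInterval:
        return year_interval(self.baseline_year)

    @property
    def followup(self) -> DateInterval:
        return year_interval(self.followup_year)

    @property
    def study_window(self) -> DateInterval:
        return DateInterval(self.baseline.start, self.followup.end)


def has_prefix(code: str, prefixes: tuple[str, ...]) -> bool:
    return any(code.startswith(p) for p in prefixes)


def identify_oa(medical_claims: pd.DataFrame, config: CohortConfig) -> dict[str, str]:
    """Persons with claims-identified OA at baseline.

    Returns ``{person_id: entry_reason}`` with reason ``inpatient`` or
    ``outpatient_pair`` (inpatient wins when both apply).
    """
    base = config.baseline
    out: dict[str, str] = {}
    if medical_claims.empty:
        return out
    mask = pd.Series(
        [(base.start <= d <= base.end) for d in medical_claims["service_date"]],
        index=medical_claims.index,
    )
    in_base = medical_claims[mask]
    oa_mask = pd.Series(
        [any(has_prefix(c, config.oa_code_prefixes) for c in codes_)
         for codes_ in in_base["diagnosis_codes"]],
        index=in_base.index,
    )
    oa = in_base[oa_mask]
    if oa.empty:
        return out
    for pid, group in oa.groupby("person_id", sort=True):
        if (group["setting"] == "inpatient").any():
            out[pid] = "inpatient"
            continue
        dates = sorted(set(group.loc[group["setting"] == "outpatient", "service_date"]))
        if len(dates) >= 2 and (dates[-1] - dates[0]).days >= config.outpatient_min_separation:
            out[pid] = "outpatient_pair"
    return out


def continuously_enrolled(enrollment: pd.DataFrame, study_window: DateInterval) -> set[str]:
    """Persons whose medical+pharmacy spans cover every day of the window."""
    if enrollment.empty:
        return set()
    both = enrollment[(enrollment["medical"]) & (enrollment["pharmacy"])]
    eligible = set()
    for pid, group in both.groupby("person_id", sort=True):
        spans = [DateInterval(r.start_date, r.end_date) for r in group.itertuples()]
        if covers_every_day(spans, study_window):
            eligible.add(pid)
    return eligible


def build_cohort(bundle, config: CohortConfig | None = None) -> pd.DataFrame:
    """Intersect the OA, enrollment and age gates.

    Returns a DataFrame (person_id, age, cohort_entry_reason) sorted by
    person_id; age is referenced to January 1 of the baseline year.
    """
    config = config or CohortConfig()
    oa = identify_oa(bundle.medical_claims, config)
    enrolled = continuously_enrolled(bundle.enrollment, config.study_window)
    persons = bundle.persons.set_index("person_id")
    rows = []
    for pid in sorted(set(oa) & enrolled):
        age = config.baseline_year - int(persons.loc[pid, "birth_year"])
        if age >= config.min_age:
            rows.append({"person_id": pid, "age": age, "cohort_entry_reason": oa[pid]})
    return pd.DataFrame(rows, columns=["person_id", "age", "cohort_entry_reason"])
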
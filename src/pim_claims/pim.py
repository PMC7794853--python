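"""Potentially inappropriate NSAID use: the four-rule target classifier.

Follow-up NSAID exposure is judged against the person's baseline CV/GI
risk category:

* R1 — low CV/low GI: any NSAID (selective or non-selective) episode of
  >= 90 consecutive days (7-day refill-gap allowance), inappropriate on
  account of advanced age alone.
* R2 — high CV/high GI: any NSAID episode of >= 60 consecutive days.
* R3 — high CV/low GI: >= 60 consecutive days of NSAID use, except that
  naproxen below 1000 mg/day and ibuprofen below 1200 mg/day are dose-
  exempt (their CV risk profile is acceptable at those doses); exempt
  fills are removed before rebuilding the exposure run.
* R4 — low CV/high GI: non-selective NSAID use >= 60 consecutive days
  (selective NSAIDs carry an acceptable GI profile).

All duration thresholds are inclusive (>=).  A person with no follow-up
NSAID use is not inappropriate but stays in the denominator.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

from .claims import NSAID_CLASSES
from .episodes import (
    DEFAULT_GAP_DAYS,
    ExposureEpisode,
    episodes_from_fill_frame,
    fill_daily_dose,
)
from .risk import RiskCategory


class PimRule(str, enum.Enum):
    R1_LOWLOW_90_ANY = "R1_lowlow_90_any"
    R2_HIGHHIGH_60_ANY = "R2_highhigh_60_any"
    R3_HIGHCV_LOWGI_60_NONEXEMPT = "R3_highcv_lowgi_60_nonexempt"
    R4_LOWCV_HIGHGI_60_NONSELECTIVE = "R4_lowcv_highgi_60_nonselective"
    NONE = "none"


@dataclass
class PimRuleConfig:
    threshold_low_risk: int = 90
    threshold_at_risk: int = 60
    naproxen_exempt_below: float = 1000.0
    ibuprofen_exempt_below: float = 1200.0
    gap: int = DEFAULT_GAP_DAYS
    # Literal reading leaves selective use >= 90 days unflagged for low
    # CV/high GI persons; this switch additionally applies the 90-day
    # any-NSAID floor in every category.
    apply_90d_floor_to_all: bool = False


@dataclass
class PimResult:
    person_id: str
    pim: bool
    rule_id: PimRule
    triggering_episode: ExposureEpisode | None = None


def is_exempt_fill(row, config: PimRuleConfig) -> bool:
    """Dose exemption at the fill level (rule R3 only)."""
    dose = fill_daily_dose(row)
    if row.ingredient == "naproxen" and dose < config.naproxen_exempt_below:
        return True
    if row.ingredient == "ibuprofen" and dose < config.ibuprofen_exempt_below:
        return True
    return False


def _earliest_at_threshold(
    episodes: list[ExposureEpisode], threshold: int
) -> ExposureEpisode | None:
    hits = [ep for ep in episodes if ep.length >= threshold]
    return min(hits, key=lambda ep: (ep.interval.start, ep.drug_class)) if hits else None


def _nonexempt_episodes(
    person_id: str, episodes: list[ExposureEpisode], config: PimRuleConfig
) -> list[ExposureEpisode]:
    """Rebuild NSAID exposure runs from non-exempt fills only."""
    frames = [ep.fills for ep in episodes if not ep.fills.empty]
    if not frames:
        return []
    fills = pd.concat(frames).drop_duplicates()
    keep = [not is_exempt_fill(r, config) for r in fills.itertuples()]
    fills = fills.loc[keep]
    if fills.empty:
        return []
    return episodes_from_fill_frame(person_id, "nsaid_any_nonexempt", fills, config.gap)


def classify_person(
    person_id: str,
    category: RiskCategory | str,
    followup_episodes: list[ExposureEpisode],
    config: PimRuleConfig | None = None,
) -> PimResult:
    """Apply the rule matching the person's risk category.

    ``followup_episodes`` are the person's follow-up-period NSAID
    episodes; episodes of other drug classes are ignored.  Ties are
    resolved by reporting the earliest-start triggering episode.
    """
    config = config or PimRuleConfig()
    category = RiskCategory(category)
    nsaid = [ep for ep in followup_episodes if ep.drug_class in NSAID_CLASSES]

    trigger: ExposureEpisode | None = None
    rule = PimRule.NONE
    if category is RiskCategory.LOW_CV_LOW_GI:
        trigger = _earliest_at_threshold(nsaid, config.threshold_low_risk)
        rule = PimRule.R1_LOWLOW_90_ANY
    elif category is RiskCategory.HIGH_CV_HIGH_GI:
        trigger = _earliest_at_threshold(nsaid, config.threshold_at_risk)
        rule = PimRule.R2_HIGHHIGH_60_ANY
    elif category is RiskCategory.HIGH_CV_LOW_GI:
        rebuilt = _nonexempt_episodes(person_id, nsaid, config)
        trigger = _earliest_at_threshold(rebuilt, config.threshold_at_risk)
        rule = PimRule.R3_HIGHCV_LOWGI_60_NONEXEMPT
    elif category is RiskCategory.LOW_CV_HIGH_GI:
        nonsel = [ep for ep in nsaid if ep.drug_class == "nsaid_nonselective"]
        trigger = _earliest_at_threshold(nonsel, config.threshold_at_risk)
        rule = PimRule.R4_LOWCV_HIGHGI_60_NONSELECTIVE
    else:  # pragma: no cover - RiskCategory() already rejects unknowns
        raise ValueError(f"unknown risk category {category!r}")

    if trigger is None and config.apply_90d_floor_to_all and category is not RiskCategory.LOW_CV_LOW_GI:
        trigger = _earliest_at_threshold(nsaid, config.threshold_low_risk)
        rule = PimRule.R1_LOWLOW_90_ANY

    if trigger is None:
        return PimResult(person_id, False, PimRule.NONE, None)
    return PimResult(person_id, True, rule, trigger)


def classify_cohort(
    profiles: pd.DataFrame,
    episodes_by_person: dict[str, list[ExposureEpisode]],
    config: PimRuleConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Classify every profiled person; return results plus a prevalence summary.

    Summary keys: ``prevalence_pct`` (flagged / all profiled persons);
    ``flagged_distribution_pct`` (share of flagged persons in each risk
    category, summing to ~100); ``within_category_rate_pct`` (flagged /
    category size).
    """
    config = config or PimRuleConfig()
    unknown = set(episodes_by_person) - set(profiles["person_id"])
    if unknown:
        raise ValueError(f"episodes for persons without a risk profile: {sorted(unknown)[:5]}")
    rows = []
    for r in profiles.itertuples():
        res = classify_person(r.person_id, r.category, episodes_by_person.get(r.person_id, []), config)
        ep = res.triggering_episode
        rows.append(
            {
                "person_id": r.person_id,
                "pim": res.pim,
                "rule_id": res.rule_id.value,
                "category": r.category,
                "episode_start": ep.interval.start.isoformat() if ep else "",
                "episode_end": ep.interval.end.isoformat() if ep else "",
                "episode_len": ep.length if ep else 0,
            }
        )
    results = pd.DataFrame(
        rows,
        columns=["person_id", "pim", "rule_id", "category", "episode_start", "episode_end", "episode_len"],
    )
    summary = summarize_pim(results)
    return results, summary


def summarize_pim(results: pd.DataFrame) -> dict:
    n = len(results)
    n_flagged = int(results["pim"].sum()) if n else 0
    flagged = results[results["pim"]] if n else results
    dist = {}
    rates = {}
    for cat in ("high_cv_high_gi", "high_cv_low_gi", "low_cv_high_gi", "low_cv_low_gi"):
        in_cat = results[results["category"] == cat] if n else results
        flagged_in_cat = int(in_cat["pim"].sum()) if len(in_cat) else 0
        dist[cat] = 100.0 * flagged_in_cat / n_flagged if n_flagged else 0.0
        rates[cat] = 100.0 * flagged_in_cat / len(in_cat) if len(in_cat) else 0.0
    return {
        "n": n,
        "n_flagged": n_flagged,
        "prevalence_pct": 100.0 * n_flagged / n if n else 0.0,
        "flagged_distribution_pct": dist,
        "within_category_rate_pct": rates,
    }
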
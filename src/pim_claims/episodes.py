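"""Drug exposure episodes from pharmacy fills.

An exposure episode is a maximal run of drug-covered days for one person
and one drug class after bridging refill gaps of at most ``gap``
uncovered days (default 7).  A fill dispensed on day *d* with supply *s*
covers days ``d .. d+s-1``; overlapping supplies are truncated (union of
covered days), not stockpiled.  Episodes are attributed to an analysis
period by the dispense date of their fills: a fill dispensed inside the
period contributes its full supply even if it spills past the period
end, while a fill dispensed before the period does not seed an episode
unless carry-over is explicitly enabled.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import pandas as pd

from .claims import NSAID_CLASSES, drug_lookup
from .intervals import DateInterval, clip, intersect, merge_with_gap, total_days

DEFAULT_GAP_DAYS = 7


@dataclass
class ExposureEpisode:
    """One maximal gap-bridged run of covered days for a person and class."""

    person_id: str
    drug_class: str
    interval: DateInterval
    fills: pd.DataFrame = field(repr=False)
    ingredient_daily_doses: dict[str, float] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.interval.length


def fill_coverage(fill_date: datetime.date, days_supply: int) -> DateInterval:
    return DateInterval(fill_date, fill_date + datetime.timedelta(days=int(days_supply) - 1))


def fill_daily_dose(row) -> float:
    """mg/day for one fill: quantity x unit strength / days supply."""
    return float(row.quantity) * float(row.unit_strength_mg) / float(row.days_supply)


def _resolve(fills: pd.DataFrame, dictionary: pd.DataFrame) -> pd.DataFrame:
    lookup = drug_lookup(dictionary)
    unknown = sorted(set(fills["drug_code"]) - set(lookup))
    if unknown:
        raise KeyError(f"fills reference drug codes absent from the dictionary: {unknown}")
    resolved = fills.copy()
    resolved["ingredient"] = [lookup[c].ingredient for c in resolved["drug_code"]]
    resolved["drug_class"] = [lookup[c].drug_class for c in resolved["drug_code"]]
    return resolved


def _select_period_fills(
    fills: pd.DataFrame, period: DateInterval | None, carry_over: bool
) -> pd.DataFrame:
    if period is None:
        return fills
    if carry_over:
        keep = [
            fill_coverage(r.fill_date, r.days_supply).intersects(period)
            for r in fills.itertuples()
        ]
    else:
        keep = [(period.start <= d <= period.end) for d in fills["fill_date"]]
    return fills.loc[keep]


def episodes_from_fill_frame(
    person_id: str,
    drug_class: str,
    fills: pd.DataFrame,
    gap: int = DEFAULT_GAP_DAYS,
) -> list[ExposureEpisode]:
    """Build episodes for one person+class from already-resolved fills."""
    coverages = [fill_coverage(r.fill_date, r.days_supply) for r in fills.itertuples()]
    episodes = []
    for iv in merge_with_gap(coverages, gap):
        mask = [c.intersects(iv) for c in coverages]
        contributing = fills.loc[mask]
        doses: dict[str, float] = {}
        for r in contributing.itertuples():
            d = fill_daily_dose(r)
            doses[r.ingredient] = max(doses.get(r.ingredient, 0.0), d)
        episodes.append(ExposureEpisode(person_id, drug_class, iv, contributing, doses))
    return episodes


def build_episodes(
    fills: pd.DataFrame,
    dictionary: pd.DataFrame,
    classes: set[str] | tuple[str, ...] = NSAID_CLASSES,
    gap: int = DEFAULT_GAP_DAYS,
    period: DateInterval | None = None,
    carry_over: bool = False,
) -> list[ExposureEpisode]:
    """Build per-person, per-class exposure episodes.

    Parameters
    ----------
    fills, dictionary
        The pharmacy-fill and drug-dictionary tables of a bundle.
    classes
        Drug classes to build episodes for.
    gap
        Maximum bridgeable run of uncovered days between refills.
    period
        If given, restrict to fills dispensed within the period
        (or, with ``carry_over=True``, fills whose coverage intersects it).
    """
    if fills.empty:
        return []
    resolved = _resolve(fills, dictionary)
    resolved = resolved[resolved["drug_class"].isin(classes)]
    resolved = _select_period_fills(resolved, period, carry_over)
    episodes: list[ExposureEpisode] = []
    for (pid, cls), group in resolved.groupby(["person_id", "drug_class"], sort=True):
        episodes.extend(episodes_from_fill_frame(pid, cls, group, gap))
    return episodes


def total_exposure_days(
    fills: pd.DataFrame,
    dictionary: pd.DataFrame,
    drug_class: str,
    period: DateInterval | None = None,
) -> int:
    """Union of covered days (no gap bridging) for one class, clipped to period.

    This is the baseline duration-of-use feature: days actually covered
    inside the period, counting overlapping supplies once.
    """
    if fills.empty:
        return 0
    resolved = _resolve(fills, dictionary)
    resolved = resolved[resolved["drug_class"] == drug_class]
    if period is not None:
        resolved = _select_period_fills(resolved, period, carry_over=False)
    coverages = [fill_coverage(r.fill_date, r.days_supply) for r in resolved.itertuples()]
    if period is not None:
        coverages = clip(coverages, period)
    return total_days(coverages)


def max_concomitant_run(
    nsaid_episodes: list[DateInterval], comed_episodes: list[DateInterval]
) -> int:
    """Longest single consecutive-day overlap between two interval lists."""
    overlap = intersect(merge_with_gap(nsaid_episodes, 0), merge_with_gap(comed_episodes, 0))
    return max((iv.length for iv in overlap), default=0)


def episodes_to_frame(episodes: list[ExposureEpisode]) -> pd.DataFrame:
    """Flatten episodes for CSV export."""
    rows = []
    for ep in episodes:
        max_dose = max(ep.ingredient_daily_doses.values(), default=0.0)
        rows.append(
            {
                "person_id": ep.person_id,
                "drug_class": ep.drug_class,
                "start": ep.interval.start.isoformat(),
                "end": ep.interval.end.isoformat(),
                "length_days": ep.length,
                "ingredients": ";".join(sorted(ep.ingredient_daily_doses)),
                "max_daily_dose_mg": round(max_dose, 4),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "person_id",
            "drug_class",
            "start",
            "end",
            "length_days",
            "ingredients",
            "max_daily_dose_mg",
        ],
    )
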
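"""Shared fixtures: day-number helpers, tiny fill builders and oracles."""

from __future__ import annotations

import datetime

import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from pim_claims import codes
from pim_claims.intervals import DateInterval

EPOCH = datetime.date(2016, 1, 1)


def day(n: int) -> datetime.date:
    """Day number -> calendar date; day(1) = 2016-01-01."""
    return EPOCH + datetime.timedelta(days=n - 1)


def iv(a: int, b: int) -> DateInterval:
    return DateInterval(day(a), day(b))


def dayset_merge(intervals: list[DateInterval], gap: int) -> list[DateInterval]:
    """Brute-force oracle: mark covered days in a boolean array, bridge runs
    of <= gap uncovered days between covered runs, read off maximal runs."""
    if not intervals:
        return []
    lo = min(i.start.toordinal() for i in intervals)
    hi = max(i.end.toordinal() for i in intervals)
    covered = [False] * (hi - lo + 1)
    for i in intervals:
        for d in range(i.start.toordinal(), i.end.toordinal() + 1):
            covered[d - lo] = True
    # bridge interior uncovered runs of length <= gap
    bridged = covered[:]
    run_start = None
    for pos in range(len(covered)):
        if not covered[pos]:
            if run_start is None:
                run_start = pos
        else:
            if run_start is not None and run_start > 0:
                if pos - run_start <= gap:
                    for q in range(run_start, pos):
                        bridged[q] = True
            run_start = None
    out = []
    start = None
    for pos, c in enumerate(bridged):
        if c and start is None:
            start = pos
        elif not c and start is not None:
            out.append(DateInterval(datetime.date.fromordinal(lo + start),
                                    datetime.date.fromordinal(lo + pos - 1)))
            start = None
    if start is not None:
        out.append(DateInterval(datetime.date.fromordinal(lo + start),
                                datetime.date.fromordinal(hi)))
    return out


def make_fills(person_id: str, fills: list[tuple]) -> pd.DataFrame:
    """fills: (ingredient, fill_date, days_supply, quantity, unit_strength_mg)."""
    rows = [
        {
            "person_id": person_id,
            "drug_code": codes.CODE_BY_INGREDIENT[ing],
            "fill_date": d,
            "days_supply": int(ds),
            "quantity": float(q),
            "unit_strength_mg": float(s),
        }
        for ing, d, ds, q, s in fills
    ]
    return pd.DataFrame(
        rows,
        columns=["person_id", "drug_code", "fill_date", "days_supply", "quantity",
                 "unit_strength_mg"],
    )


@pytest.fixture(scope="session")
def dictionary() -> pd.DataFrame:
    return codes.default_drug_dictionary()


@pytest.fixture(scope="session")
def small_bundle():
    """A 50-person default-config bundle reused across IO tests."""
    from pim_claims.synth import SimulationConfig, generate

    return generate(SimulationConfig(n_persons=50, seed=11))
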
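"""Exposure-episode construction: gap bridging, doses, day totals, overlap."""

import numpy as np
import pytest

from pim_claims.episodes import (
    build_episodes,
    fill_coverage,
    max_concomitant_run,
    total_exposure_days,
)
from pim_claims.intervals import merge_with_gap, total_days

from conftest import day, dayset_merge, iv, make_fills


class TestBuildEpisodes:
    def test_bridges_refill_gap_into_one_episode(self, dictionary):
        fills = make_fills("A", [
            ("naproxen", day(1), 30, 60, 500),
            ("naproxen", day(31), 30, 60, 500),
            ("naproxen", day(68), 30, 60, 500),
        ])
        eps = build_episodes(fills, dictionary, gap=7)
        assert len(eps) == 1
        assert eps[0].drug_class == "nsaid_nonselective"
        assert eps[0].interval == iv(1, 97)
        assert eps[0].length == 97

    def test_single_fill_single_episode(self, dictionary):
        fills = make_fills("A", [("celecoxib", day(10), 30, 30, 200)])
        eps = build_episodes(fills, dictionary)
        assert len(eps) == 1
        assert eps[0].drug_class == "nsaid_selective"
        assert eps[0].length == 30

    def test_daily_dose_attached_per_ingredient(self, dictionary):
        # 60 x 500 mg tablets over 30 days -> 1000 mg/day
        fills = make_fills("A", [("naproxen", day(1), 30, 60, 500)])
        eps = build_episodes(fills, dictionary)
        assert eps[0].ingredient_daily_doses == {"naproxen": 1000.0}

    def test_classes_kept_separate(self, dictionary):
        fills = make_fills("A", [
            ("naproxen", day(1), 30, 60, 500),
            ("celecoxib", day(1), 30, 30, 200),
        ])
        eps = build_episodes(fills, dictionary)
        assert {e.drug_class for e in eps} == {"nsaid_nonselective", "nsaid_selective"}

    def test_period_restriction_by_dispense_date(self, dictionary):
        fills = make_fills("A", [("naproxen", day(360), 30, 60, 500)])
        eps = build_episodes(fills, dictionary, period=iv(1, 365))
        assert len(eps) == 1 and eps[0].length == 30  # supply spills past the period
        assert build_episodes(fills, dictionary, period=iv(366, 731)) == []
        carried = build_episodes(fills, dictionary, period=iv(366, 731), carry_over=True)
        assert len(carried) == 1

    def test_unknown_drug_code_raises(self, dictionary):
        fills = make_fills("A", [("naproxen", day(1), 30, 60, 500)])
        fills.loc[0, "drug_code"] = "D-XXX"
        with pytest.raises(KeyError):
            build_episodes(fills, dictionary)

    def test_matches_dayset_oracle_on_random_fill_sets(self, dictionary):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = rng.integers(1, 11)
            gap = int(rng.choice([0, 7, 30]))
            rows = [
                ("naproxen", day(int(rng.integers(1, 700))), int(rng.integers(1, 61)), 30, 500)
                for _ in range(n)
            ]
            fills = make_fills("A", rows)
            eps = build_episodes(fills, dictionary, gap=gap)
            expected = dayset_merge(
                [fill_coverage(d, s) for _, d, s, _, _ in rows], gap
            )
            assert [e.interval for e in eps] == expected


class TestTotalExposureDays:
    def test_overlapping_fills_counted_once(self, dictionary):
        fills = make_fills("A", [
            ("naproxen", day(1), 30, 60, 500),
            ("naproxen", day(15), 30, 60, 500),
        ])
        assert total_exposure_days(fills, dictionary, "nsaid_nonselective") == 44

    def test_no_fills(self, dictionary):
        assert total_exposure_days(make_fills("A", []), dictionary, "nsaid_selective") == 0

    def test_clipped_to_period(self, dictionary):
        fills = make_fills("A", [("naproxen", day(350), 30, 60, 500)])
        assert total_exposure_days(fills, dictionary, "nsaid_nonselective", iv(1, 365)) == 16

    def test_union_of_episode_days_exceeds_covered_only_by_bridged_days(self, dictionary):
        rng = np.random.default_rng(7)
        for _ in range(50):
            rows = [
                ("naproxen", day(int(rng.integers(1, 300))), int(rng.integers(1, 40)), 30, 500)
                for _ in range(rng.integers(1, 8))
            ]
            fills = make_fills("A", rows)
            eps = build_episodes(fills, dictionary, gap=7)
            covered = [fill_coverage(d, s) for _, d, s, _, _ in rows]
            episode_days = total_days([e.interval for e in eps])
            covered_days = total_days(covered)
            assert episode_days >= covered_days
            # with gap=0 the two unions coincide exactly
            eps0 = build_episodes(fills, dictionary, gap=0)
            assert total_days([e.interval for e in eps0]) == covered_days


class TestMaxConcomitantRun:
    def test_overlap_below_and_above_bar(self):
        assert max_concomitant_run([iv(1, 60)], [iv(55, 70)]) == 6
        assert max_concomitant_run([iv(1, 60)], [iv(50, 70)]) == 11

    def test_no_comedication(self):
        assert max_concomitant_run([iv(1, 60)], []) == 0

    def test_longest_single_interval_not_total(self):
        # two 4-day overlaps do not make an 8-day run
        assert max_concomitant_run([iv(1, 4), iv(10, 13)], [iv(1, 20)]) == 4
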
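"""The four-rule inappropriate-use classifier: boundaries, exemptions, summary."""

import pandas as pd
import pytest

from pim_claims.episodes import build_episodes
from pim_claims.pim import PimRule, PimRuleConfig, classify_cohort, classify_person, summarize_pim
from pim_claims.risk import RiskCategory

from conftest import day, make_fills


def episodes_for(dictionary, fills_spec, gap=7):
    return build_episodes(make_fills("A", fills_spec), dictionary, gap=gap)


def run_of(dictionary, ingredient, daily_dose, length, strength):
    """One continuous run of `length` days at `daily_dose` mg/day in 30-day fills."""
    fills = []
    start = 1
    remaining = length
    while remaining > 0:
        supply = min(30, remaining)
        fills.append((ingredient, day(start), supply, supply * daily_dose / strength, strength))
        start += supply
        remaining -= supply
    return episodes_for(dictionary, fills)


class TestRuleBoundaries:
    @pytest.mark.parametrize("length,expected", [(89, False), (90, True)])
    def test_low_low_90_day_threshold(self, dictionary, length, expected):
        eps = run_of(dictionary, "diclofenac", 100, length, 50)
        res = classify_person("A", RiskCategory.LOW_CV_LOW_GI, eps)
        assert res.pim is expected
        if expected:
            assert res.rule_id is PimRule.R1_LOWLOW_90_ANY
            assert res.triggering_episode.length == 90

    @pytest.mark.parametrize("length,expected", [(59, False), (60, True)])
    def test_high_high_60_day_threshold_any_class(self, dictionary, length, expected):
        eps = run_of(dictionary, "celecoxib", 200, length, 200)
        res = classify_person("A", RiskCategory.HIGH_CV_HIGH_GI, eps)
        assert res.pim is expected

    def test_high_high_has_no_dose_exemption(self, dictionary):
        eps = run_of(dictionary, "naproxen", 500, 60, 500)
        assert classify_person("A", RiskCategory.HIGH_CV_HIGH_GI, eps).pim


class TestDoseExemption:
    def test_low_dose_naproxen_exempt_for_high_cv_low_gi(self, dictionary):
        eps = run_of(dictionary, "naproxen", 990, 70, 500)
        assert not classify_person("A", RiskCategory.HIGH_CV_LOW_GI, eps).pim

    def test_naproxen_at_exactly_1000_not_exempt(self, dictionary):
        eps = run_of(dictionary, "naproxen", 1000, 70, 500)
        res = classify_person("A", RiskCategory.HIGH_CV_LOW_GI, eps)
        assert res.pim and res.rule_id is PimRule.R3_HIGHCV_LOWGI_60_NONEXEMPT

    def test_ibuprofen_below_1200_exempt(self, dictionary):
        eps = run_of(dictionary, "ibuprofen", 800, 70, 400)
        assert not classify_person("A", RiskCategory.HIGH_CV_LOW_GI, eps).pim

    def test_exempt_fills_removed_before_episode_rebuild(self, dictionary):
        # 30 d low-dose naproxen splits two 25-day celecoxib runs: without the
        # low-dose bridge the non-exempt run never reaches 60 days
        fills = (
            [("celecoxib", day(1), 25, 25, 200)]
            + [("naproxen", day(26), 30, 30, 500)]  # 500 mg/day, exempt
            + [("celecoxib", day(56), 25, 25, 200)]
        )
        eps = episodes_for(dictionary, fills)
        assert not classify_person("A", RiskCategory.HIGH_CV_LOW_GI, eps).pim


class TestNonselectiveRule:
    def test_selective_only_use_unflagged_for_low_cv_high_gi(self, dictionary):
        eps = run_of(dictionary, "celecoxib", 200, 75, 200)
        assert not classify_person("A", RiskCategory.LOW_CV_HIGH_GI, eps).pim

    def test_nonselective_60_days_flagged(self, dictionary):
        eps = run_of(dictionary, "meloxicam", 15, 60, 15)
        res = classify_person("A", RiskCategory.LOW_CV_HIGH_GI, eps)
        assert res.pim and res.rule_id is PimRule.R4_LOWCV_HIGHGI_60_NONSELECTIVE

    def test_optional_90_day_floor_flags_long_selective_use(self, dictionary):
        eps = run_of(dictionary, "celecoxib", 200, 95, 200)
        cfg = PimRuleConfig(apply_90d_floor_to_all=True)
        res = classify_person("A", RiskCategory.LOW_CV_HIGH_GI, eps, cfg)
        assert res.pim and res.rule_id is PimRule.R1_LOWLOW_90_ANY


class TestMonotonicity:
    def test_lengthening_never_unflags(self, dictionary):
        for cat in RiskCategory:
            flagged_lengths = [
                length
                for length in (50, 60, 70, 90, 120)
                if classify_person("A", cat, run_of(dictionary, "diclofenac", 100, length, 50)).pim
            ]
            # once flagged at some length, flagged at every longer length
            assert flagged_lengths == sorted(flagged_lengths)
            if flagged_lengths:
                threshold = min(flagged_lengths)
                assert all(l in flagged_lengths for l in (90, 120) if l >= threshold)

    def test_raising_naproxen_dose_never_unflags(self, dictionary):
        flagged = [
            dose
            for dose in (500, 990, 1000, 1500)
            if classify_person(
                "A", RiskCategory.HIGH_CV_LOW_GI, run_of(dictionary, "naproxen", dose, 70, 500)
            ).pim
        ]
        assert flagged == [1000, 1500]


class TestClassifyCohort:
    def test_no_followup_use_stays_in_denominator(self):
        profiles = pd.DataFrame(
            {"person_id": ["A", "B"], "gi_high": [False] * 2, "cv_high": [False] * 2,
             "category": ["low_cv_low_gi"] * 2, "factors": [""] * 2}
        )
        results, summary = classify_cohort(profiles, {})
        assert len(results) == 2
        assert summary["prevalence_pct"] == 0.0

    def test_unprofiled_person_with_episodes_rejected(self, dictionary):
        profiles = pd.DataFrame(
            {"person_id": ["A"], "gi_high": [False], "cv_high": [False],
             "category": ["low_cv_low_gi"], "factors": [""]}
        )
        eps = run_of(dictionary, "naproxen", 1000, 90, 500)
        with pytest.raises(ValueError):
            classify_cohort(profiles, {"Z": eps})

    def test_flagged_distribution_sums_to_100(self):
        results = pd.DataFrame(
            {
                "person_id": [str(i) for i in range(8)],
                "pim": [True, True, True, False, True, False, True, False],
                "category": ["high_cv_high_gi", "high_cv_low_gi", "low_cv_high_gi",
                             "low_cv_high_gi", "low_cv_low_gi", "low_cv_low_gi",
                             "low_cv_low_gi", "high_cv_high_gi"],
            }
        )
        summary = summarize_pim(results)
        assert sum(summary["flagged_distribution_pct"].values()) == pytest.approx(100.0)

    def test_prevalence_from_printed_cohort_counts(self):
        # 5,772 flagged of 44,990 -> 12.8%
        results = pd.DataFrame(
            {
                "person_id": [str(i) for i in range(44990)],
                "pim": [i < 5772 for i in range(44990)],
                "category": ["low_cv_low_gi"] * 44990,
            }
        )
        summary = summarize_pim(results)
        assert round(summary["prevalence_pct"], 1) == 12.8
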
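"""Fragmentation-of-care index, feature assembly and one-hot encoding."""

import datetime

import numpy as np
import pytest

from pim_claims.cohort import CohortConfig, build_cohort
from pim_claims.features import (
    DEFAULT_CATEGORICAL_SPEC,
    assemble_features,
    compute_fci,
    one_hot,
)
from pim_claims.pipeline import classify_bundle
from pim_claims.synth import PlantedScenario, generate_planted


class TestComputeFci:
    def test_single_provider_any_count_is_zero(self):
        for k in (1, 2, 3, 10):
            assert compute_fci({"A": k}) == 0.0

    def test_all_distinct_providers_is_one(self):
        for k in (2, 3, 7):
            counts = {f"P{i}": 1 for i in range(k)}
            assert compute_fci(counts) == pytest.approx(1.0)

    def test_two_providers_two_each(self):
        assert compute_fci({"A": 2, "B": 2}) == pytest.approx(2 / 3)

    def test_zero_or_one_encounter_is_zero(self):
        assert compute_fci({}) == 0.0
        assert compute_fci({"A": 1}) == 0.0

    def test_permutation_invariant(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            counts = rng.integers(1, 9, size=rng.integers(2, 7))
            base = compute_fci({f"P{i}": int(c) for i, c in enumerate(counts)})
            shuffled = rng.permutation(counts)
            assert compute_fci({f"Q{i}": int(c) for i, c in enumerate(shuffled)}) == pytest.approx(base)

    def test_moving_encounter_from_modal_to_new_provider_increases(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            counts = list(rng.integers(1, 9, size=rng.integers(1, 6)))
            if sum(counts) < 2:
                continue
            before = compute_fci({f"P{i}": int(c) for i, c in enumerate(counts)})
            modal = int(np.argmax(counts))
            counts[modal] -= 1
            counts.append(1)
            after = compute_fci(
                {f"P{i}": int(c) for i, c in enumerate(counts) if c > 0}
            )
            assert after > before


@pytest.fixture(scope="module")
def assembled():
    """Planted bundle driven through the full pipeline into a feature table."""
    from pim_claims.synth import PlantedEpisode

    scenarios = [
        PlantedScenario("flagged", episodes=[
            PlantedEpisode("naproxen", "nsaid_nonselective", 1000.0, 90, "baseline"),
            PlantedEpisode("naproxen", "nsaid_nonselective", 1000.0, 95, "followup"),
        ], expected_pim=True, expected_rule="R1_lowlow_90_any"),
        PlantedScenario("clean"),
    ]
    bundle, truth = generate_planted(scenarios, seed=0)
    cfg = CohortConfig()
    cohort, profiles, results, _ = classify_bundle(bundle)
    table = assemble_features(bundle, cohort, profiles, results, cfg.baseline)
    return bundle, table


class TestAssembleFeatures:
    def test_counts_and_day_totals(self, assembled):
        _, table = assembled
        row = table.set_index("person_id").loc["S00000"]
        assert row["baseline_nonselective_days"] == 90
        assert row["any_nonselective_use"] == 1
        assert row["any_selective_use"] == 0
        assert row["pim"] == 1

    def test_person_without_baseline_exposure(self, assembled):
        _, table = assembled
        row = table.set_index("person_id").loc["S00001"]
        assert row["baseline_nonselective_days"] == 0
        assert row["n_opioid_rx"] == 0
        assert row["pim"] == 0

    def test_no_missing_values(self, assembled):
        _, table = assembled
        assert not table.isna().any().any()

    def test_service_counts_from_planted_claims(self):
        import pandas as pd

        bundle, truth = generate_planted([PlantedScenario("p")], seed=0)
        extra = pd.DataFrame(
            [
                {"person_id": "S00000", "service_date": datetime.date(2015, 6, d),
                 "setting": "outpatient", "provider_id": "S00000-PR0",
                 "diagnosis_codes": ["R52"], "service_type": stype}
                for d, stype in ((1, "physical_therapy"), (2, "physical_therapy"),
                                 (3, "ia_corticosteroid"))
            ]
        )
        bundle.medical_claims = pd.concat([bundle.medical_claims, extra], ignore_index=True)
        opioids = pd.DataFrame(
            [
                {"person_id": "S00000", "drug_code": "D-OXY",
                 "fill_date": datetime.date(2015, 7, d), "days_supply": 10,
                 "quantity": 20.0, "unit_strength_mg": 5.0}
                for d in (1, 15, 28)
            ]
        )
        frames = [f for f in (bundle.fills, opioids) if not f.empty]
        bundle.fills = pd.concat(frames, ignore_index=True)
        cohort, profiles, results, _ = classify_bundle(bundle)
        table = assemble_features(bundle, cohort, profiles, results, CohortConfig().baseline)
        row = table.set_index("person_id").loc["S00000"]
        assert row["n_physical_therapy"] == 2
        assert row["n_ia_corticosteroid"] == 1
        assert row["n_opioid_rx"] == 3


class TestOneHot:
    def test_default_spec_yields_36_columns(self, assembled):
        _, table = assembled
        X = one_hot(table)
        assert X.shape[1] == 36

    def test_region_indicators(self, assembled):
        _, table = assembled
        X = one_hot(table)
        row = X.iloc[0]
        assert row["region_south"] == 1
        assert row["region_northeast"] == row["region_midwest"] == row["region_west"] == 0

    def test_each_categorical_block_sums_to_one(self, assembled):
        _, table = assembled
        X = one_hot(table)
        for col, levels in DEFAULT_CATEGORICAL_SPEC.items():
            block = X[[f"{col}_{lv}" for lv in levels]]
            assert (block.sum(axis=1) == 1).all()

    def test_unseen_level_rejected(self, assembled):
        _, table = assembled
        bad = table.copy()
        bad.loc[bad.index[0], "region"] = "atlantis"
        with pytest.raises(ValueError, match="unseen"):
            one_hot(bad)
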
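"""Odds ratios, hand-checkable metrics, rank AUROC and the fit protocol."""

import numpy as np
import pandas as pd
import pytest

from pim_claims.model_eval import (
    TrainConfig,
    TwoByTwo,
    auroc_score,
    compute_metrics,
    fit_and_evaluate,
    odds_ratio,
)


def pairwise_auroc(labels, scores):
    """O(n^2) oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestOddsRatio:
    def test_symmetric_table_gives_unity(self):
        or_, lo, hi = odds_ratio(TwoByTwo(10, 10, 10, 10))
        assert or_ == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_reconstructed_cohort_tables(self):
        # cells reconstructed from the category sizes and the flagged-person
        # distribution of a 44,990-person cohort with 5,772 flagged
        or_low, *_ = odds_ratio(TwoByTwo(323, 3910, 2367, 22862))
        assert or_low == pytest.approx(0.80, abs=0.01)
        or_high, *_ = odds_ratio(TwoByTwo(508, 2875, 2367, 22862))
        assert 1.70 <= or_high <= 1.72

    def test_reciprocal_under_group_swap(self):
        t = TwoByTwo(12, 34, 56, 78)
        a, *_ = odds_ratio(t)
        b, *_ = odds_ratio(TwoByTwo(56, 78, 12, 34))
        assert a * b == pytest.approx(1.0)

    def test_zero_cell_raises_unless_haldane(self):
        with pytest.raises(ValueError):
            odds_ratio(TwoByTwo(0, 5, 5, 5))
        or_, *_ = odds_ratio(TwoByTwo(0, 5, 5, 5), haldane=True)
        assert or_ > 0


class TestComputeMetrics:
    def test_hand_confusion_matrix(self):
        # TP=3 FP=1 FN=2 TN=4
        labels = [1, 1, 1, 0, 1, 1, 0, 0, 0, 0]
        scores = [0.9, 0.9, 0.9, 0.9, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]
        m = compute_metrics(labels, scores, threshold=0.5)
        assert m.accuracy == pytest.approx(0.7)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.6)
        assert m.specificity == pytest.approx(0.8)
        assert m.f1 == pytest.approx(2 / 3, abs=1e-4)
        assert m.kappa == pytest.approx(0.4)

    def test_perfect_separation(self):
        labels = [0] * 5 + [1] * 5
        scores = [0.1] * 5 + [0.9] * 5
        m = compute_metrics(labels, scores)
        assert (m.accuracy, m.precision, m.recall, m.specificity, m.f1, m.kappa, m.auroc) == (
            1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_f1_is_harmonic_mean(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 500)
        scores = rng.random(500)
        m = compute_metrics(labels, scores)
        assert m.f1 == pytest.approx(
            2 * m.precision * m.recall / (m.precision + m.recall)
        )

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([1, 1, 1], [0.1, 0.5, 0.9])

    def test_auroc_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(10, 200))
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            scores = rng.choice([0.1, 0.3, 0.3, 0.7, 0.9], size=n)
            assert auroc_score(labels, scores) == pytest.approx(pairwise_auroc(labels, scores))

    def test_null_scores_auroc_near_half(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, 10_000)
        scores = rng.random(10_000)
        assert abs(auroc_score(labels, scores) - 0.5) < 0.02

    def test_kappa_zero_for_label_independent_predictions(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(0, 2, 20_000)
        scores = rng.choice([0.2, 0.8], size=20_000, p=[0.7, 0.3])
        m = compute_metrics(labels, scores)
        assert abs(m.kappa) < 0.02


class TestFitAndEvaluate:
    @staticmethod
    def _planted(n=800, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 6)), columns=[f"f{i}" for i in range(6)])
        logit = 2.5 * X["f0"] - 2.0 * X["f1"]
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        return X, y

    def test_recovers_planted_signal_features(self):
        X, y = self._planted()
        res = fit_and_evaluate(X, y, TrainConfig(seed=0))
        assert res["gbt"]["metrics"].auroc > 0.85
        assert res["cvlr"]["metrics"].auroc > 0.85
        for backend in ("gbt", "cvlr"):
            assert set(res[backend]["ranking"]["feature"].head(2)) == {"f0", "f1"}

    def test_same_seed_reproduces_split_and_metrics(self):
        X, y = self._planted(seed=3)
        a = fit_and_evaluate(X, y, TrainConfig(seed=7))
        b = fit_and_evaluate(X, y, TrainConfig(seed=7))
        assert a["split"]["test_index"] == b["split"]["test_index"]
        assert a["gbt"]["metrics"].as_dict() == b["gbt"]["metrics"].as_dict()
        assert a["cvlr"]["metrics"].as_dict() == b["cvlr"]["metrics"].as_dict()

    def test_split_is_stratified_70_30(self):
        X, y = self._planted(seed=2)
        res = fit_and_evaluate(X, y, TrainConfig(seed=1))
        n = len(X)
        assert res["split"]["n_train"] == pytest.approx(0.7 * n, abs=1)
        test_rate = y[res["split"]["test_index"]].mean()
        assert test_rate == pytest.approx(y.mean(), abs=0.03)

    def test_non_binary_target_rejected(self):
        X, _ = self._planted(n=50)
        with pytest.raises(ValueError):
            fit_and_evaluate(X, np.arange(50), TrainConfig())
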
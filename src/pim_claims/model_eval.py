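"""Association estimates, native performance metrics and the ML protocol.

Unadjusted odds ratios come from 2x2 tables with Woolf (log-normal)
confidence intervals.  Classification metrics — accuracy, precision,
recall, specificity, F1, Cohen's kappa and the rank-based (Mann-Whitney)
AUROC with tie midranks — are computed here directly so their exact
definitions are pinned down, and are cross-checked against independent
oracles in the test suite.  Model fitting itself is delegated:
L2-regularized logistic regression with the penalty chosen by k-fold
cross-validation (scikit-learn) and gradient-boosted trees (xgboost)
with the fixed hyperparameters below; this module owns the protocol —
stratified 70/30 split, held-out evaluation, mean-|contribution|
feature ranking — not the optimizers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata


@dataclass
class TwoByTwo:
    """Counts: a = exposed-flagged, b = exposed-unflagged, c/d = reference."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 cells must be nonnegative")


def odds_ratio(
    t: TwoByTwo, alpha: float = 0.05, haldane: bool = False
) -> tuple[float, float, float]:
    """Odds ratio with a Woolf confidence interval.

    OR = (a/b)/(c/d); CI = exp(ln OR +/- z * sqrt(1/a+1/b+1/c+1/d)).
    A zero cell raises unless ``haldane`` adds 0.5 to every cell.
    """
    a, b, c, d = (float(x) for x in (t.a, t.b, t.c, t.d))
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) == 0:
        raise ValueError("zero cell; enable the Haldane correction for a finite estimate")
    or_ = (a / b) / (c / d)
    z = norm.ppf(1 - alpha / 2)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (or_, or_ * np.exp(-z * se), or_ * np.exp(z * se))


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    kappa: float
    auroc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
            "kappa": self.kappa,
            "auroc": self.auroc,
        }


def auroc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank (Mann-Whitney) AUROC with midranks for tied scores."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes in labels")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def compute_metrics(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Confusion-matrix metrics at ``threshold`` plus kappa and rank AUROC.

    Kappa uses the marginal-product chance agreement
    ``p_e = p_yes_true * p_yes_pred + p_no_true * p_no_pred``.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    n = tp + fp + fn + tn
    accuracy = (tp + tn) / n
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    p_o = accuracy
    p_e = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / (n * n)
    kappa = (p_o - p_e) / (1 - p_e) if p_e < 1 else 0.0
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f1,
        kappa=kappa,
        auroc=auroc_score(labels, scores),
    )


@dataclass
class TrainConfig:
    train_fraction: float = 0.70
    cv_folds: int = 3
    seed: int = 0
    threshold: float = 0.5
    gbt_params: dict = field(
        default_factory=lambda: {
            "n_estimators": 800,
            "learning_rate": 0.01,
            "gamma": 0.0,
            "max_depth": 4,
            "subsample": 0.75,
            "colsample_bytree": 0.6,
            "min_child_weight": 1,
        }
    )

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def _logistic_ranking(model, X_train: pd.DataFrame) -> pd.DataFrame:
    clf = model.named_steps["clf"]
    # Features are standardized, so |coef| is the contribution per SD.
    contrib = np.abs(clf.coef_[0])
    direction = np.sign(clf.coef_[0])
    return pd.DataFrame(
        {
            "feature": X_train.columns,
            "mean_abs_contribution": contrib,
            "direction": direction,
        }
    ).sort_values("mean_abs_contribution", ascending=False, ignore_index=True)


def _gbt_ranking(model, X_test: pd.DataFrame) -> pd.DataFrame:
    import xgboost as xgb

    booster = model.get_booster()
    dm = xgb.DMatrix(X_test, feature_names=list(X_test.columns))
    contribs = booster.predict(dm, pred_contribs=True)[:, :-1]  # drop bias column
    mean_abs = np.abs(contribs).mean(axis=0)
    direction = np.sign(
        [np.corrcoef(X_test.iloc[:, j], contribs[:, j])[0, 1] if X_test.iloc[:, j].std() > 0 else 0.0
         for j in range(X_test.shape[1])]
    )
    return pd.DataFrame(
        {
            "feature": X_test.columns,
            "mean_abs_contribution": mean_abs,
            "direction": direction,
        }
    ).sort_values("mean_abs_contribution", ascending=False, ignore_index=True)


def fit_and_evaluate(
    X: pd.DataFrame, y, config: TrainConfig | None = None
) -> dict:
    """Run the full protocol for both backends.

    Stratified 70/30 split; 3-fold cross-validation inside the training
    set selects the logistic regularization strength; gradient-boosted
    trees use the fixed hyperparameters.  Metrics are computed on the
    held-out 30% with :func:`compute_metrics`; features are ranked by
    mean absolute per-observation contribution (TreeSHAP values for the
    boosted model, |standardized coefficient| for logistic).

    Returns ``{"cvlr": {...}, "gbt": {...}, "split": {...}}`` where each
    backend dict has ``metrics`` (MetricsReport) and ``ranking``
    (DataFrame).
    """
    from sklearn.linear_model import LogisticRegressionCV
    from sklearn.model_selection import train_test_split
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler
    import xgboost as xgb

    config = config or TrainConfig()
    y = np.asarray(y).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("target must be binary 0/1")
    X_train, X_test, y_train, y_test = train_test_split(
        X,
        y,
        train_size=config.train_fraction,
        stratify=y,
        random_state=config.seed,
    )

    cvlr = Pipeline(
        [
            ("scaler", StandardScaler()),
            (
                "clf",
                LogisticRegressionCV(
                    Cs=10,
                    cv=config.cv_folds,
                    l1_ratios=(0.0,),  # pure L2, penalty chosen by CV
                    scoring="roc_auc",
                    max_iter=2000,
                    use_legacy_attributes=False,
                    random_state=config.seed,
                ),
            ),
        ]
    )
    cvlr.fit(X_train, y_train)
    cvlr_scores = cvlr.predict_proba(X_test)[:, 1]

    gbt = xgb.XGBClassifier(
        **config.gbt_params,
        objective="binary:logistic",
        tree_method="hist",
        n_jobs=1,
        random_state=config.seed,
    )
    gbt.fit(X_train, y_train)
    gbt_scores = gbt.predict_proba(X_test)[:, 1]

    return {
        "cvlr": {
            "metrics": compute_metrics(y_test, cvlr_scores, config.threshold),
            "ranking": _logistic_ranking(cvlr, X_train),
        },
        "gbt": {
            "metrics": compute_metrics(y_test, gbt_scores, config.threshold),
            "ranking": _gbt_ranking(gbt, X_test),
        },
        "split": {
            "n_train": len(X_train),
            "n_test": len(X_test),
            "train_index": list(X_train.index),
            "test_index": list(X_test.index),
        },
    }
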
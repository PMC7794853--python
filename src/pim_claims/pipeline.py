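"""End-to-end pipeline: simulate -> cohort -> episodes -> risk -> classify
-> features -> fit -> report.

One global seed fans out deterministically to the generator and the
model stage, so a fixed seed reproduces the full report bundle byte for
byte.  Every report percentage is recomputable from the CSVs the
pipeline writes; an attrition log records input/output row counts per
stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
import yaml

from .claims import ClaimsBundle, NSAID_CLASSES
from .cohort import CohortConfig, build_cohort
from .episodes import build_episodes, episodes_to_frame
from .features import FeatureCodeConfig, assemble_features, one_hot, CONDITION_FLAGS
from .model_eval import TrainConfig, TwoByTwo, fit_and_evaluate, odds_ratio
from .pim import PimRuleConfig, classify_cohort
from .risk import CATEGORY_ORDER, RiskCodeConfig, profile_cohort
from .synth import EffectLogit, EpisodeLengthDistribution, SimulationConfig, generate

log = logging.getLogger("pim_claims")


def round_pct(x: float, digits: int = 1) -> float:
    """Half-up rounding for presentation percentages."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    risk: RiskCodeConfig = field(default_factory=RiskCodeConfig)
    pim: PimRuleConfig = field(default_factory=PimRuleConfig)
    features: FeatureCodeConfig = field(default_factory=FeatureCodeConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0
    fit_models: bool = True

    def __post_init__(self) -> None:
        # one global seed fans out to the stage seeds
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)
        self.train = dataclasses.replace(self.train, seed=(self.seed + 1) % (2**31))

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.get("simulation", {})
        for key, sub in (("episode_length_distribution", EpisodeLengthDistribution),
                         ("effect_logit", EffectLogit)):
            if key in sim_raw and isinstance(sim_raw[key], dict):
                sim_raw[key] = sub(**sim_raw[key])
        return cls(
            simulation=SimulationConfig(**sim_raw),
            cohort=CohortConfig(**raw.get("cohort", {})),
            risk=RiskCodeConfig(**raw.get("risk", {})),
            pim=PimRuleConfig(**raw.get("pim", {})),
            features=FeatureCodeConfig(**raw.get("features", {})),
            train=TrainConfig(**raw.get("train", {})),
            seed=int(raw.get("seed", 0)),
            fit_models=bool(raw.get("fit_models", True)),
        )


def _mean_sd(series: pd.Series) -> dict:
    if len(series) == 0:
        return {"mean": 0.0, "sd": 0.0}
    return {"mean": round(float(series.mean()), 4),
            "sd": round(float(series.std(ddof=1)) if len(series) > 1 else 0.0, 4)}


def report_summary(
    cohort: pd.DataFrame,
    profiles: pd.DataFrame,
    pim_results: pd.DataFrame,
    features: pd.DataFrame,
) -> dict:
    """Descriptive statistics, prevalences, flagged distribution and UORs.

    Percentages are half-up rounded to one decimal.  Unadjusted odds
    ratios compare each risk category against low CV/low GI with Woolf
    95% confidence intervals (skipped when a cell is empty).
    """
    n = len(cohort)
    summary: dict = {"n": n}
    if n == 0:
        summary.update({"pct": {}, "continuous": {}, "pim": {
            "n_flagged": 0, "prevalence_pct": 0.0,
            "flagged_distribution_pct": {}, "within_category_rate_pct": {}},
            "unadjusted_or": {}})
        return summary

    pct = {"age_mean": round(float(cohort["age"].mean()), 1)}
    pct["female"] = round_pct(100.0 * (features["sex"] == "female").mean())
    for region in ("northeast", "midwest", "south", "west"):
        pct[f"region_{region}"] = round_pct(100.0 * (features["region"] == region).mean())
    pct["hmo"] = round_pct(100.0 * (features["insurance_type"] == "hmo").mean())
    for cond in CONDITION_FLAGS:
        pct[cond] = round_pct(100.0 * features[cond].mean())
    any_use = ((features["any_nonselective_use"] + features["any_selective_use"]) > 0)
    pct["any_nsaid_use"] = round_pct(100.0 * any_use.mean())
    for cat in CATEGORY_ORDER:
        pct[cat.value] = round_pct(100.0 * (profiles["category"] == cat.value).mean())
    summary["pct"] = pct

    summary["continuous"] = {
        col: _mean_sd(features[col])
        for col in ("fci", "n_opioid_rx", "n_ia_corticosteroid", "n_ia_hyaluronic",
                    "n_physical_therapy", "baseline_nonselective_days",
                    "baseline_selective_days")
    }

    from .pim import summarize_pim

    pim_summary = summarize_pim(pim_results)
    summary["pim"] = {
        "n_flagged": pim_summary["n_flagged"],
        "prevalence_pct": round_pct(pim_summary["prevalence_pct"]),
        "flagged_distribution_pct": {
            k: round_pct(v) for k, v in pim_summary["flagged_distribution_pct"].items()
        },
        "within_category_rate_pct": {
            k: round_pct(v) for k, v in pim_summary["within_category_rate_pct"].items()
        },
    }

    summary["unadjusted_or"] = unadjusted_category_ors(pim_results)
    return summary


def unadjusted_category_ors(pim_results: pd.DataFrame, reference: str = "low_cv_low_gi") -> dict:
    """UOR of inappropriate use for each category vs the reference."""
    out = {}
    ref = pim_results[pim_results["category"] == reference]
    c = int(ref["pim"].sum())
    d = len(ref) - c
    for cat in CATEGORY_ORDER:
        if cat.value == reference:
            continue
        grp = pim_results[pim_results["category"] == cat.value]
        a = int(grp["pim"].sum())
        b = len(grp) - a
        if min(a, b, c, d) == 0:
            out[cat.value] = None
            continue
        or_, lo, hi = odds_ratio(TwoByTwo(a, b, c, d))
        out[cat.value] = {"or": round(or_, 2), "ci_low": round(lo, 2), "ci_high": round(hi, 2)}
    return out


def classify_bundle(
    bundle: ClaimsBundle,
    cohort_cfg: CohortConfig | None = None,
    risk_cfg: RiskCodeConfig | None = None,
    pim_cfg: PimRuleConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Run cohort -> episodes -> risk -> classify on an existing bundle.

    Returns (cohort, profiles, pim_results, pim_summary).
    """
    cohort_cfg = cohort_cfg or CohortConfig()
    risk_cfg = risk_cfg or RiskCodeConfig()
    pim_cfg = pim_cfg or PimRuleConfig()
    cohort = build_cohort(bundle, cohort_cfg)
    ids = set(cohort["person_id"])
    profiles = profile_cohort(bundle, ids, cohort_cfg.baseline, risk_cfg, gap=pim_cfg.gap)
    eps = build_episodes(
        bundle.fills[bundle.fills["person_id"].isin(ids)],
        bundle.drug_dictionary,
        classes=NSAID_CLASSES,
        gap=pim_cfg.gap,
        period=cohort_cfg.followup,
    )
    by_person: dict[str, list] = {}
    for ep in eps:
        by_person.setdefault(ep.person_id, []).append(ep)
    results, summary = classify_cohort(profiles, by_person, pim_cfg)
    return cohort, profiles, results, summary


def run_all(config: PipelineConfig, outdir: Path | str, bundle: ClaimsBundle | None = None) -> dict:
    """Run every stage, writing artifacts under ``outdir``.

    A pre-built bundle (e.g. planted scenarios) can substitute for the
    generator.  Returns the report dictionary that is also written as
    ``report.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    attrition = []

    if bundle is None:
        log.info("simulate: generating %d persons (seed %d)",
                 config.simulation.n_persons, config.simulation.seed)
        bundle = generate(config.simulation)
    from .claims import write_bundle

    write_bundle(bundle, outdir / "bundle")
    attrition.append({"stage": "simulate", "rows_out": len(bundle.persons)})

    cohort = build_cohort(bundle, config.cohort)
    cohort.to_csv(outdir / "cohort.csv", index=False)
    attrition.append({"stage": "cohort", "rows_in": len(bundle.persons), "rows_out": len(cohort)})
    log.info("cohort: %d of %d persons eligible", len(cohort), len(bundle.persons))

    cohort_ids = set(cohort["person_id"])
    cohort_fills = bundle.fills[bundle.fills["person_id"].isin(cohort_ids)]
    followup_eps = build_episodes(
        cohort_fills, bundle.drug_dictionary, classes=NSAID_CLASSES,
        gap=config.pim.gap, period=config.cohort.followup,
    )
    episodes_to_frame(followup_eps).to_csv(outdir / "episodes_followup.csv", index=False)
    attrition.append({"stage": "episodes", "rows_in": len(cohort_fills), "rows_out": len(followup_eps)})

    profiles = profile_cohort(bundle, cohort_ids, config.cohort.baseline, config.risk,
                              gap=config.pim.gap)
    profiles.to_csv(outdir / "risk_profiles.csv", index=False)
    attrition.append({"stage": "risk", "rows_in": len(cohort), "rows_out": len(profiles)})

    eps_by_person: dict[str, list] = {}
    for ep in followup_eps:
        eps_by_person.setdefault(ep.person_id, []).append(ep)
    pim_results, pim_summary = classify_cohort(profiles, eps_by_person, config.pim)
    pim_results.to_csv(outdir / "pim_results.csv", index=False)
    attrition.append({"stage": "classify", "rows_in": len(profiles), "rows_out": len(pim_results)})
    log.info("classify: %.1f%% flagged", pim_summary["prevalence_pct"])

    features = assemble_features(bundle, cohort, profiles, pim_results,
                                 config.cohort.baseline, config.features)
    features.to_csv(outdir / "features.csv", index=False)
    attrition.append({"stage": "features", "rows_in": len(cohort), "rows_out": len(features)})

    report = {"summary": report_summary(cohort, profiles, pim_results, features)}

    if config.fit_models and features["pim"].nunique() == 2:
        X = one_hot(features)
        fit = fit_and_evaluate(X, features["pim"], config.train)
        metrics = {name: fit[name]["metrics"].as_dict() for name in ("cvlr", "gbt")}
        with open(outdir / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True)
        fit["gbt"]["ranking"].to_csv(outdir / "ranking_gbt.csv", index=False)
        fit["cvlr"]["ranking"].to_csv(outdir / "ranking_cvlr.csv", index=False)
        report["metrics"] = metrics
        report["top_features_gbt"] = list(fit["gbt"]["ranking"]["feature"].head(10))
        attrition.append({"stage": "fit", "rows_in": len(features),
                          "rows_out": fit["split"]["n_test"]})

    report["attrition"] = attrition
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
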
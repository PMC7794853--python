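"""Seeded synthetic claims generator.

Emulates a 24-month Medicare-Advantage-style claims stream for an
osteoarthritis population: demographics and condition prevalences match
configurable marginals, NSAID users realize a mixture of short and long
exposure episodes decomposed into 30-day fills with refill dates
jittered inside the 7-day gap allowance, and the probability of a long
follow-up exposure run depends on baseline exposure, risk category,
opioid use and care fragmentation through a configurable logistic link
— the recoverable signal for the modelling stage.

A planted-truth mode (:func:`generate_planted`) builds one person per
hand-specified scenario with no jitter, so cohort eligibility, risk
category and the inappropriate-use flag are exactly derivable and the
pipeline can be tested for perfect recovery.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import codes
from .claims import ClaimsBundle, validate_bundle
from .risk import RiskCategory

DAY = datetime.timedelta(days=1)


class ConfigError(ValueError):
    pass


# Representative claim codes used when planting each condition; chosen so
# no planted code matches another condition's prefix list.
PLANT_CODES = {
    "asthma": "J4520",
    "cancer": "C50911",
    "cardiac_arrhythmia": "I4891",
    "copd": "J449",
    "dementia": "G309",
    "anxiety": "F411",
    "depression": "F329",
    "diabetes": "E119",
    "hyperlipidemia": "E785",
    "hypertension": "I10",
    "substance_abuse": "F1120",
    "other_pain": "M542",
    "oa_pain": "M25561",
    "obesity": "E669",
}
GI_PLANT_CODES = ("K219", "K30", "K259", "K2511")
CV_PLANT_CODES = ("I209", "I639", "I219", "I509")
OA_PLANT_CODES = ("M1711", "M1712", "M160", "M179", "M1990")
GENERIC_VISIT_CODE = "R52"  # pain, unspecified — never matches a condition list

# Table-2-style marginals used as generator defaults.
DEFAULT_CONDITION_PREVALENCES = {
    "asthma": 0.08,
    "cancer": 0.15,
    "cardiac_arrhythmia": 0.15,
    "copd": 0.12,
    "dementia": 0.07,
    "anxiety": 0.140,
    "depression": 0.169,
    "diabetes": 0.27,
    "hyperlipidemia": 0.55,
    "hypertension": 0.70,
    "substance_abuse": 0.075,
    "other_pain": 0.35,
    "oa_pain": 0.553,
    "obesity": 0.17,
}


@dataclass
class EpisodeLengthDistribution:
    """Mixture of short and long exposure runs (covered days)."""

    p_long: float = 0.35
    short_range: tuple[int, int] = (7, 30)
    long_range: tuple[int, int] = (60, 300)


@dataclass
class EffectLogit:
    """Logistic link from baseline features to P(long follow-up run)."""

    intercept: float = -2.2
    per_baseline_nsaid_day: float = 0.01
    category: dict[str, float] = field(
        default_factory=lambda: {
            "high_cv_high_gi": 0.1,
            "high_cv_low_gi": 0.2,
            "low_cv_high_gi": 0.3,
            "low_cv_low_gi": 0.0,
        }
    )
    per_opioid_rx: float = 0.05
    per_fci: float = -0.5


@dataclass
class SimulationConfig:
    n_persons: int = 2000
    baseline_year: int = 2015
    followup_year: int = 2016
    condition_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_PREVALENCES)
    )
    cv_factor_prevalence: float = 0.169   # 7.5% + 9.4% high-CV marginal
    gi_factor_prevalence: float = 0.345   # 7.5% + 27.0% high-GI marginal
    nsaid_user_fraction: float = 0.216
    episode_length_distribution: EpisodeLengthDistribution = field(
        default_factory=EpisodeLengthDistribution
    )
    followup_long_range: tuple[int, int] = (90, 300)
    short_followup_prob: float = 0.15
    selective_fraction: float = 0.20
    dose_table: dict[str, tuple[float, tuple[float, ...]]] = field(
        default_factory=lambda: dict(codes.DOSE_TABLE)
    )
    effect_logit: EffectLogit = field(default_factory=EffectLogit)
    female_fraction: float = 0.664
    hmo_fraction: float = 0.363
    region_probs: dict[str, float] = field(
        default_factory=lambda: {"northeast": 0.134, "midwest": 0.241, "south": 0.365, "west": 0.260}
    )
    age_bracket_probs: tuple[float, ...] = (0.229, 0.252, 0.199, 0.320)
    age_brackets: tuple[tuple[int, int], ...] = ((65, 69), (70, 74), (75, 79), (80, 94))
    oa_fraction: float = 0.95
    under_65_fraction: float = 0.02
    enrollment_gap_fraction: float = 0.03
    # Per-person provider pool sizes controlling the FCI distribution
    # (mean FCI ~ 1 - E[1/k] ~ 0.44 for these weights).
    provider_pool_sizes: tuple[int, ...] = (1, 2, 3, 4, 6)
    provider_pool_probs: tuple[float, ...] = (0.30, 0.30, 0.20, 0.10, 0.10)
    visit_mean: float = 8.0
    pt_user_prob: float = 0.30
    pt_mean: float = 14.0
    ia_cort_user_prob: float = 0.40
    ia_cort_mean: float = 2.0
    ia_ha_user_prob: float = 0.10
    ia_ha_mean: float = 2.0
    opioid_user_prob: float = 0.50
    opioid_extra_mean: float = 3.0
    refill_jitter_max: int = 7
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        probs = {
            "cv_factor_prevalence": self.cv_factor_prevalence,
            "gi_factor_prevalence": self.gi_factor_prevalence,
            "nsaid_user_fraction": self.nsaid_user_fraction,
            "selective_fraction": self.selective_fraction,
            "female_fraction": self.female_fraction,
            "hmo_fraction": self.hmo_fraction,
            "oa_fraction": self.oa_fraction,
            "under_65_fraction": self.under_65_fraction,
            "enrollment_gap_fraction": self.enrollment_gap_fraction,
            **{f"condition:{k}": v for k, v in self.condition_prevalences.items()},
            **{f"region:{k}": v for k, v in self.region_probs.items()},
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} = {p} is not a probability")
        if self.followup_year != self.baseline_year + 1:
            raise ConfigError("baseline and follow-up years must be consecutive")
        if self.n_persons < 1:
            raise ConfigError("n_persons must be positive")
        return self


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _fci_from_counts(counts: dict[str, int]) -> float:
    n = sum(counts.values())
    if n <= 1:
        return 0.0
    s = sum(v * v for v in counts.values())
    return 1.0 - (s - n) / (n * (n - 1))


class _Builder:
    """Accumulates table rows; shared by the random and planted generators."""

    def __init__(self) -> None:
        self.persons: list[dict] = []
        self.enrollment: list[dict] = []
        self.claims: list[dict] = []
        self.fills: list[dict] = []

    def add_person(self, pid, birth_year, sex, region, insurance):
        self.persons.append(
            {"person_id": pid, "birth_year": birth_year, "sex": sex,
             "region": region, "insurance_type": insurance}
        )

    def add_span(self, pid, start, end, medical=True, pharmacy=True):
        self.enrollment.append(
            {"person_id": pid, "start_date": start, "end_date": end,
             "medical": medical, "pharmacy": pharmacy}
        )

    def add_claim(self, pid, date, setting, provider, codes_, service_type="visit"):
        self.claims.append(
            {"person_id": pid, "service_date": date, "setting": setting,
             "provider_id": provider, "diagnosis_codes": list(codes_),
             "service_type": service_type}
        )

    def add_fill(self, pid, drug_code, date, days_supply, quantity, strength):
        self.fills.append(
            {"person_id": pid, "drug_code": drug_code, "fill_date": date,
             "days_supply": int(days_supply), "quantity": float(quantity),
             "unit_strength_mg": float(strength)}
        )

    def bundle(self, dictionary: pd.DataFrame) -> ClaimsBundle:
        from .claims import COLUMNS

        bundle = ClaimsBundle(
            persons=pd.DataFrame(self.persons, columns=COLUMNS["persons"]),
            enrollment=pd.DataFrame(self.enrollment, columns=COLUMNS["enrollment"]),
            medical_claims=pd.DataFrame(self.claims, columns=COLUMNS["medical_claims"]),
            fills=pd.DataFrame(self.fills, columns=COLUMNS["fills"]),
            drug_dictionary=dictionary.copy(),
        )
        return validate_bundle(bundle)


def _plant_fills(
    builder: _Builder,
    pid: str,
    ingredient: str,
    units_per_day: float,
    strength: float,
    length: int,
    start: datetime.date,
    rng: np.random.Generator | None,
    jitter_max: int,
) -> datetime.date:
    """Decompose a covered run into 30-day fills; returns the run's end date.

    With ``rng`` given, 0..jitter_max uncovered days are inserted between
    refills (the run still bridges under the 7-day gap allowance when
    jitter_max <= 7); without it, refills abut exactly.
    """
    code = codes.CODE_BY_INGREDIENT[ingredient]
    remaining = length
    date = start
    while remaining > 0:
        supply = min(30, remaining)
        builder.add_fill(pid, code, date, supply, supply * units_per_day, strength)
        remaining -= supply
        date = date + supply * DAY
        if remaining > 0 and rng is not None and jitter_max > 0:
            date = date + int(rng.integers(0, jitter_max + 1)) * DAY
    return date - DAY


def _random_day(rng: np.random.Generator, year: int, first: int = 0, last: int = 364) -> datetime.date:
    return datetime.date(year, 1, 1) + int(rng.integers(first, last + 1)) * DAY


def generate(config: SimulationConfig | None = None) -> ClaimsBundle:
    """Generate a validated bundle realizing the configured marginals."""
    config = (config or SimulationConfig()).validate()
    rng = np.random.default_rng(config.seed)
    b = _Builder()
    by0, fy0 = config.baseline_year, config.followup_year
    dist = config.episode_length_distribution
    regions = list(config.region_probs)
    region_p = np.array([config.region_probs[r] for r in regions])
    region_p = region_p / region_p.sum()

    for i in range(config.n_persons):
        pid = f"P{i:06d}"
        # demographics
        if rng.random() < config.under_65_fraction:
            age = int(rng.integers(60, 65))
        else:
            k = rng.choice(len(config.age_brackets), p=np.array(config.age_bracket_probs) /
                           np.sum(config.age_bracket_probs))
            lo, hi = config.age_brackets[k]
            age = int(rng.integers(lo, hi + 1))
        sex = "female" if rng.random() < config.female_fraction else "male"
        region = regions[rng.choice(len(regions), p=region_p)]
        insurance = "hmo" if rng.random() < config.hmo_fraction else "other"
        b.add_person(pid, by0 - age, sex, region, insurance)

        # enrollment: full 24 months, or a one-month hole for a small fraction
        w_start = datetime.date(by0, 1, 1)
        w_end = datetime.date(fy0, 12, 31)
        if rng.random() < config.enrollment_gap_fraction:
            hole_start = datetime.date(fy0, 7, 1)
            b.add_span(pid, w_start, hole_start - DAY)
            b.add_span(pid, datetime.date(fy0, 8, 1), w_end)
        else:
            b.add_span(pid, w_start, w_end)

        # provider pool for all of this person's medical claims
        claims_start = len(b.claims)
        pool_k = int(rng.choice(config.provider_pool_sizes, p=config.provider_pool_probs))
        providers = [f"{pid}-PR{j}" for j in range(pool_k)]
        pick = lambda: providers[int(rng.integers(0, pool_k))]

        # osteoarthritis qualification
        if rng.random() < config.oa_fraction:
            oa_code = OA_PLANT_CODES[int(rng.integers(0, len(OA_PLANT_CODES)))]
            if rng.random() < 0.3:
                b.add_claim(pid, _random_day(rng, by0), "inpatient", pick(), [oa_code])
            else:
                d1 = _random_day(rng, by0, 0, 200)
                sep = int(rng.integers(30, 141))
                b.add_claim(pid, d1, "outpatient", pick(), [oa_code])
                b.add_claim(pid, d1 + sep * DAY, "outpatient", pick(), [oa_code])

        # chronic-condition flags
        for cond, prev in config.condition_prevalences.items():
            if rng.random() < prev:
                b.add_claim(pid, _random_day(rng, by0), "outpatient", pick(),
                            [PLANT_CODES.get(cond, cond)])

        cv_high = rng.random() < config.cv_factor_prevalence
        gi_high = rng.random() < config.gi_factor_prevalence
        if cv_high:
            b.add_claim(pid, _random_day(rng, by0), "outpatient", pick(),
                        [CV_PLANT_CODES[int(rng.integers(0, len(CV_PLANT_CODES)))]])
        category = (
            RiskCategory.HIGH_CV_HIGH_GI if cv_high and gi_high
            else RiskCategory.HIGH_CV_LOW_GI if cv_high
            else RiskCategory.LOW_CV_HIGH_GI if gi_high
            else RiskCategory.LOW_CV_LOW_GI
        )

        # baseline NSAID exposure
        baseline_days = 0
        first_episode: tuple[datetime.date, int] | None = None
        is_user = rng.random() < config.nsaid_user_fraction
        if is_user:
            n_ep = 1 + (rng.random() < 0.3)
            cursor = 0
            for _ in range(n_ep):
                if rng.random() < dist.p_long:
                    length = int(rng.integers(dist.long_range[0], dist.long_range[1] + 1))
                else:
                    length = int(rng.integers(dist.short_range[0], dist.short_range[1] + 1))
                span = length + config.refill_jitter_max * max(0, math.ceil(length / 30) - 1)
                latest = 364 - span
                if latest <= cursor:
                    break
                start_day = int(rng.integers(cursor, latest + 1))
                start = datetime.date(by0, 1, 1) + start_day * DAY
                selective = rng.random() < config.selective_fraction
                ingredient = (
                    "celecoxib" if selective
                    else ("naproxen", "ibuprofen", "diclofenac", "meloxicam")[
                        int(rng.choice(4, p=[0.4, 0.3, 0.2, 0.1]))
                    ]
                )
                strength, upd_options = config.dose_table[ingredient]
                upd = float(upd_options[int(rng.integers(0, len(upd_options)))])
                end = _plant_fills(b, pid, ingredient, upd, strength, length, start,
                                   rng, config.refill_jitter_max)
                baseline_days += length
                if first_episode is None:
                    first_episode = (start, length)
                cursor = (end - datetime.date(by0, 1, 1)).days + 30

        # GI factor: condition code, or (for NSAID users) a >=7-day
        # concomitant ulcerogenic co-medication
        if gi_high:
            use_comed = is_user and first_episode is not None and rng.random() < 0.2
            if use_comed:
                cls = codes.GI_COMED_CLASSES[int(rng.integers(0, len(codes.GI_COMED_CLASSES)))]
                ingredient = {
                    "corticosteroid": "prednisone", "antiplatelet": "clopidogrel",
                    "ssri": "sertraline", "aspirin": "aspirin", "anticoagulant": "warfarin",
                }[cls]
                strength, upd_options = config.dose_table[ingredient]
                start, ep_len = first_episode
                supply = max(7, min(14, ep_len))
                b.add_fill(pid, codes.CODE_BY_INGREDIENT[ingredient], start, supply,
                           supply * upd_options[0], strength)
            else:
                b.add_claim(pid, _random_day(rng, by0), "outpatient", pick(),
                            [GI_PLANT_CODES[int(rng.integers(0, len(GI_PLANT_CODES)))]])

        # other service utilization (baseline)
        n_visits = int(rng.poisson(config.visit_mean))
        for _ in range(n_visits):
            b.add_claim(pid, _random_day(rng, by0), "outpatient", pick(), [GENERIC_VISIT_CODE])
        for prob, mean, stype in (
            (config.pt_user_prob, config.pt_mean, "physical_therapy"),
            (config.ia_cort_user_prob, config.ia_cort_mean, "ia_corticosteroid"),
            (config.ia_ha_user_prob, config.ia_ha_mean, "ia_hyaluronic_acid"),
        ):
            if rng.random() < prob:
                for _ in range(int(rng.poisson(mean))):
                    b.add_claim(pid, _random_day(rng, by0), "outpatient", pick(),
                                [GENERIC_VISIT_CODE], service_type=stype)

        n_opioid = 0
        if rng.random() < config.opioid_user_prob:
            n_opioid = 1 + int(rng.poisson(config.opioid_extra_mean))
            for _ in range(n_opioid):
                ingredient = ("oxycodone", "hydrocodone")[int(rng.integers(0, 2))]
                strength, upd_options = config.dose_table[ingredient]
                supply = int(rng.integers(5, 31))
                upd = float(upd_options[int(rng.integers(0, len(upd_options)))])
                b.add_fill(pid, codes.CODE_BY_INGREDIENT[ingredient],
                           _random_day(rng, by0), supply, supply * upd, strength)

        # follow-up exposure: long-run propensity via the logistic link
        person_claims = b.claims[claims_start:]
        provider_counts: dict[str, int] = {}
        for c in person_claims:
            provider_counts[c["provider_id"]] = provider_counts.get(c["provider_id"], 0) + 1
        fci = _fci_from_counts(provider_counts)
        el = config.effect_logit
        logit = (
            el.intercept
            + el.per_baseline_nsaid_day * baseline_days
            + el.category.get(category.value, 0.0)
            + el.per_opioid_rx * n_opioid
            + el.per_fci * fci
        )
        if config.nsaid_user_fraction == 0:
            pass  # an NSAID-free population has no follow-up exposure either
        elif rng.random() < _expit(logit):
            length = int(rng.integers(config.followup_long_range[0],
                                      config.followup_long_range[1] + 1))
            span = length + config.refill_jitter_max * max(0, math.ceil(length / 30) - 1)
            start = datetime.date(fy0, 1, 1) + int(rng.integers(0, max(1, 364 - span))) * DAY
            selective = rng.random() < config.selective_fraction
            ingredient = (
                "celecoxib" if selective
                else ("naproxen", "ibuprofen", "diclofenac", "meloxicam")[
                    int(rng.choice(4, p=[0.4, 0.3, 0.2, 0.1]))
                ]
            )
            strength, upd_options = config.dose_table[ingredient]
            upd = float(upd_options[int(rng.integers(0, len(upd_options)))])
            _plant_fills(b, pid, ingredient, upd, strength, length, start, rng,
                         config.refill_jitter_max)
        elif rng.random() < config.short_followup_prob and config.nsaid_user_fraction > 0:
            length = int(rng.integers(dist.short_range[0], dist.short_range[1] + 1))
            start = _random_day(rng, fy0, 0, 364 - length)
            selective = rng.random() < config.selective_fraction
            ingredient = "celecoxib" if selective else "naproxen"
            strength, upd_options = config.dose_table[ingredient]
            upd = float(upd_options[int(rng.integers(0, len(upd_options)))])
            _plant_fills(b, pid, ingredient, upd, strength, length, start, rng,
                         config.refill_jitter_max)

    return b.bundle(codes.default_drug_dictionary())


@dataclass
class PlantedEpisode:
    ingredient: str
    drug_class: str
    daily_dose_mg: float
    length_days: int
    period: str = "followup"  # "baseline" | "followup"


@dataclass
class PlantedScenario:
    """One hand-specified person with exactly derivable pipeline outputs."""

    label: str
    category: RiskCategory | str = RiskCategory.LOW_CV_LOW_GI
    episodes: list[PlantedEpisode] = field(default_factory=list)
    expected_pim: bool = False
    expected_rule: str = "none"
    age: int = 70
    oa_mode: str = "inpatient"  # inpatient | outpatient_pair | outpatient_close | none
    enrollment: str = "full"    # full | gap
    gi_via_comed: bool = False  # realize the GI factor as a co-medication overlap

    @property
    def cohort_eligible(self) -> bool:
        return (
            self.oa_mode in ("inpatient", "outpatient_pair")
            and self.enrollment == "full"
            and self.age >= 65
        )


def strong_signal_config(n_persons: int = 5000, seed: int = 0) -> SimulationConfig:
    """Study conditions with a strong planted logistic signal.

    Large coefficients on baseline NSAID days, risk category, opioid
    count and the FCI make follow-up long-term use nearly deterministic
    in those features, so a correctly wired modelling stage must recover
    them as the leading predictors with high held-out discrimination.
    """
    return SimulationConfig(
        n_persons=n_persons,
        seed=seed,
        effect_logit=EffectLogit(
            intercept=-5.0,
            per_baseline_nsaid_day=0.05,
            category={
                "high_cv_high_gi": 0.5,
                "high_cv_low_gi": 1.0,
                "low_cv_high_gi": 1.5,
                "low_cv_low_gi": 0.0,
            },
            per_opioid_rx=0.3,
            per_fci=-2.0,
        ),
    )


#: Features that carry the planted signal under :func:`strong_signal_config`
#: (the any-use indicators are deterministic functions of the day counts).
STRONG_SIGNAL_FEATURES = frozenset(
    {
        "baseline_nonselective_days",
        "baseline_selective_days",
        "any_nonselective_use",
        "any_selective_use",
        "n_opioid_rx",
        "fci",
        "category_high_cv_high_gi",
        "category_high_cv_low_gi",
        "category_low_cv_high_gi",
        "category_low_cv_low_gi",
    }
)


def null_signal_config(n_persons: int = 5000, seed: int = 0) -> SimulationConfig:
    """Conditions under which the target is independent of every feature.

    The logistic link is flat, and the exposure mix is restricted to
    non-selective NSAIDs at non-exempt doses so that every long
    follow-up run is flagged regardless of risk category — otherwise the
    class/dose exemptions would leak category information into the
    target.  A flat link at a higher event rate keeps the sampling noise
    of the held-out rank AUROC small.
    """
    dose = dict(codes.DOSE_TABLE)
    dose["naproxen"] = (500.0, (2.0,))   # 1000 mg/day: never dose-exempt
    dose["ibuprofen"] = (400.0, (3.0,))  # 1200 mg/day: never dose-exempt
    return SimulationConfig(
        n_persons=n_persons,
        seed=seed,
        selective_fraction=0.0,
        dose_table=dose,
        effect_logit=EffectLogit(
            intercept=-1.0,
            per_baseline_nsaid_day=0.0,
            category={},
            per_opioid_rx=0.0,
            per_fci=0.0,
        ),
    )


#: Drug variants spanning the rule dimensions: a selective NSAID, a
#: non-selective NSAID with no dose exemption, and dose-exempt naproxen.
GRID_VARIANTS = (
    ("celecoxib", "nsaid_selective", 200.0),
    ("diclofenac", "nsaid_nonselective", 100.0),
    ("naproxen", "nsaid_nonselective", 500.0),
)
GRID_LENGTHS = (59, 60, 61, 89, 90, 91)


def pim_rule_grid() -> list[PlantedScenario]:
    """The 72-cell planted grid: 4 risk categories x 3 drug variants x 6
    boundary durations, each with its hand-derived expected flag.

    Expected flags follow the rule table directly: low CV/low GI flags any
    NSAID run of >= 90 days; high CV/high GI any run >= 60; high CV/low GI
    any run >= 60 except dose-exempt naproxen (< 1000 mg/day); low CV/high
    GI a non-selective run >= 60 (the 500 mg/day naproxen run still flags —
    the dose exemption belongs to the high-CV rule only).
    """
    from .pim import PimRule

    scenarios = []
    for category in RiskCategory:
        for ingredient, drug_class, dose in GRID_VARIANTS:
            for length in GRID_LENGTHS:
                if category is RiskCategory.LOW_CV_LOW_GI:
                    pim = length >= 90
                    rule = PimRule.R1_LOWLOW_90_ANY
                elif category is RiskCategory.HIGH_CV_HIGH_GI:
                    pim = length >= 60
                    rule = PimRule.R2_HIGHHIGH_60_ANY
                elif category is RiskCategory.HIGH_CV_LOW_GI:
                    exempt = ingredient == "naproxen" and dose < 1000.0
                    pim = length >= 60 and not exempt
                    rule = PimRule.R3_HIGHCV_LOWGI_60_NONEXEMPT
                else:  # LOW_CV_HIGH_GI
                    pim = length >= 60 and drug_class == "nsaid_nonselective"
                    rule = PimRule.R4_LOWCV_HIGHGI_60_NONSELECTIVE
                scenarios.append(
                    PlantedScenario(
                        label=f"{category.value}|{ingredient}{dose:g}|{length}d",
                        category=category,
                        episodes=[PlantedEpisode(ingredient, drug_class, dose, length)],
                        expected_pim=pim,
                        expected_rule=rule.value if pim else PimRule.NONE.value,
                    )
                )
    return scenarios


def generate_planted(
    scenarios: list[PlantedScenario],
    seed: int = 0,
    baseline_year: int = 2015,
) -> tuple[ClaimsBundle, pd.DataFrame]:
    """Realize scenarios exactly (no jitter); returns (bundle, truth table).

    The truth table has one row per scenario: person_id, label,
    category, cohort_eligible, expected_pim, expected_rule.
    """
    del seed  # realization is fully deterministic; kept for interface symmetry
    by0, fy0 = baseline_year, baseline_year + 1
    b = _Builder()
    truth_rows = []
    for i, sc in enumerate(scenarios):
        for ep in sc.episodes:
            if ep.length_days < 1:
                raise ConfigError(f"scenario {sc.label!r}: episode length must be >= 1 day")
        pid = f"S{i:05d}"
        category = RiskCategory(sc.category)
        b.add_person(pid, by0 - sc.age, "female", "south", "other")
        w_start, w_end = datetime.date(by0, 1, 1), datetime.date(fy0, 12, 31)
        if sc.enrollment == "gap":
            b.add_span(pid, w_start, datetime.date(fy0, 6, 30))
            b.add_span(pid, datetime.date(fy0, 8, 1), w_end)
        else:
            b.add_span(pid, w_start, w_end)

        provider = f"{pid}-PR0"
        if sc.oa_mode == "inpatient":
            b.add_claim(pid, datetime.date(by0, 2, 1), "inpatient", provider, ["M1711"])
        elif sc.oa_mode == "outpatient_pair":
            b.add_claim(pid, datetime.date(by0, 2, 1), "outpatient", provider, ["M1711"])
            b.add_claim(pid, datetime.date(by0, 3, 3), "outpatient", provider, ["M1711"])
        elif sc.oa_mode == "outpatient_close":
            b.add_claim(pid, datetime.date(by0, 2, 1), "outpatient", provider, ["M1711"])
            b.add_claim(pid, datetime.date(by0, 3, 2), "outpatient", provider, ["M1711"])

        if category in (RiskCategory.HIGH_CV_HIGH_GI, RiskCategory.HIGH_CV_LOW_GI):
            b.add_claim(pid, datetime.date(by0, 4, 1), "outpatient", provider, ["I219"])
        if category in (RiskCategory.HIGH_CV_HIGH_GI, RiskCategory.LOW_CV_HIGH_GI):
            if sc.gi_via_comed:
                # >=7-day SSRI run overlapping a baseline NSAID run
                b.add_fill(pid, codes.CODE_BY_INGREDIENT["naproxen"],
                           datetime.date(by0, 5, 1), 14, 28, 500.0)
                b.add_fill(pid, codes.CODE_BY_INGREDIENT["sertraline"],
                           datetime.date(by0, 5, 1), 10, 10, 50.0)
            else:
                b.add_claim(pid, datetime.date(by0, 4, 2), "outpatient", provider, ["K30"])

        cursor = {"baseline": datetime.date(by0, 1, 15), "followup": datetime.date(fy0, 1, 15)}
        for ep in sc.episodes:
            strength = codes.DOSE_TABLE[ep.ingredient][0]
            upd = ep.daily_dose_mg / strength
            start = cursor[ep.period]
            end = _plant_fills(b, pid, ep.ingredient, upd, strength, ep.length_days,
                               start, rng=None, jitter_max=0)
            # keep >gap uncovered days between planted runs of the same person
            cursor[ep.period] = end + 20 * DAY

        truth_rows.append(
            {
                "person_id": pid,
                "label": sc.label,
                "category": category.value,
                "cohort_eligible": sc.cohort_eligible,
                "expected_pim": sc.expected_pim,
                "expected_rule": sc.expected_rule,
            }
        )
    bundle = b.bundle(codes.default_drug_dictionary())
    return bundle, pd.DataFrame(truth_rows)
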
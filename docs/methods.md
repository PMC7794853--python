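# Methods

## Study design emulated by the pipeline

The pipeline operationalizes a retrospective two-year cohort analysis of
administrative claims: a baseline calendar year supplies cohort entry,
risk stratification and all predictors; the following calendar year
supplies the outcome (potentially inappropriate NSAID use). The units of
analysis are persons continuously enrolled with medical and pharmacy
benefits across both years, aged ≥ 65 at the start of baseline, with
claims-identified osteoarthritis at baseline.

All date arithmetic uses closed intervals of calendar days. A pharmacy
fill dispensed on day *d* with a days-supply of *s* covers days
*d … d + s − 1*; overlapping supplies are truncated to the union of
covered days rather than shifted forward ("no stockpiling"), which is the
conservative convention and the one a day-marking oracle computes.

## Exposure episodes and "consecutive days"

An exposure episode is a maximal run of covered days for one person and
one drug class after bridging runs of at most `gap` uncovered days
between refills (default 7). "Use for 90 consecutive days" then means an
episode of length ≥ 90, where bridged gap days count toward the length.
Two consequences worth noting:

- the union of episode days is a superset of the union of covered days,
  and they differ exactly by the bridged gap days; with `gap = 0` the two
  coincide (asserted as a property test);
- baseline duration *features* use the unbridged covered-day union
  clipped to the baseline year, so a supply spilling into the follow-up
  year does not inflate baseline day counts.

Episodes are attributed to an analysis period by dispense date: a fill
dispensed inside the period contributes its full supply even if the
supply runs past the period's end, while a fill dispensed before the
period does not seed an episode in it. The data carry no instruction on
the alternative (carry-over) reading, so it is exposed as a config flag
(`carry_over=True`) and off by default.

## Risk stratification

GI-high requires at least one baseline GI condition claim (complicated or
uncomplicated peptic ulcer disease, dyspepsia, GERD) **or** at least 7
consecutive days of an ulcerogenic co-medication (corticosteroid,
antiplatelet, SSRI, aspirin, anticoagulant) overlapping NSAID exposure
during baseline. Only one additional factor is required because the
cohort is restricted to older adults and advanced age is itself a minor
GI risk factor. CV-high requires one baseline claim for angina, stroke,
myocardial infarction or congestive heart failure. One claim in any
setting suffices for a condition factor; no two-claim confirmation rule
is applied to risk factors.

The concomitancy reading — that the co-medication run must overlap NSAID
coverage, not merely last ≥ 7 days — follows from "concomitant use … with
NSAIDs"; the alternative is available via
`RiskCodeConfig(require_nsaid_overlap=False)`. Prescription aspirin is
observable in fills; over-the-counter aspirin (and OTC NSAID use
generally) is not, a known sensitivity of any claims-based GI profile.

ICD-10 matching is by dotless uppercase prefix, so a condition configured
as prefixes M15–M19 matches any code whose first three characters fall in
that range. The shipped code lists are representative and configurable,
not authoritative.

## The four-rule target

With L the episode length in consecutive covered days:

| category          | rule                                                   |
|-------------------|--------------------------------------------------------|
| low CV / low GI   | any NSAID episode, L ≥ 90                               |
| high CV / high GI | any NSAID episode, L ≥ 60                               |
| high CV / low GI  | L ≥ 60 after removing dose-exempt fills                 |
| low CV / high GI  | any non-selective episode, L ≥ 60                       |

All thresholds are inclusive. The dose exemption (naproxen < 1000 mg/day,
ibuprofen < 1200 mg/day; daily dose = quantity × unit strength /
days-supply per fill) applies only to the high CV / low GI rule, as
written; it is deliberately not applied to high CV / high GI. Exempt
fills are removed *before* episodes are rebuilt, so a person alternating
low-dose naproxen with celecoxib is flagged only if the non-exempt
exposure alone sustains a ≥ 60-day run. Two literal oddities are kept and
exposed as switches rather than silently "fixed": selective-NSAID use of
≥ 90 days in low CV / high GI persons is unflagged by the literal rules
(`apply_90d_floor_to_all=True` adds the 90-day any-NSAID floor to every
category), and persons with no follow-up NSAID use remain in the
denominator.

The cohort summary reports both readings of the category breakdown: the
share of flagged persons falling in each category (sums to 100%) and the
within-category flagged rate.

## Fragmentation of care

The FCI is one minus the Bice–Boxerman continuity-of-care concentration:
FCI = 1 − (Σnⱼ² − N)/(N(N−1)) over baseline provider-encounter counts nⱼ,
N = Σnⱼ. It is 0 when all encounters are with one provider, 1 when every
encounter is with a different provider, and 0 by convention for N ≤ 1
(no fragmentation is observable from a single encounter). "Encounters"
are all baseline medical claims carrying a provider id, in any setting.

## Feature set

31 features expanding to 36 model-matrix columns: 8 continuous (age, FCI,
opioid-fill count, intra-articular corticosteroid and hyaluronic-acid
injection counts, physical-therapy visit count, baseline non-selective
and selective NSAID day totals), 14 chronic-condition flags, 2 binary
type-of-use flags (any baseline non-selective / selective use), and
one-hot blocks for sex (2), insurance type (2), region (4) and risk
category (4). Age enters continuously, referenced to January 1 of the
baseline year from birth year alone (the synthetic data carry no birth
month). Each one-hot block row-sums to 1; the table has no missing values
by construction.

## Models and metrics

Stratified 70/30 train/test split (stratification on the ~13%-prevalence
target keeps test-set positive counts stable). The logistic baseline is
L2-regularized with the penalty strength chosen by 3-fold
cross-validation on AUROC inside the training set, features standardized.
The boosted model uses fixed hyperparameters: 800 trees, learning rate
0.01, γ = 0, depth 4, subsample 0.75, colsample-by-tree 0.6, minimum
child weight 1 (no grid search is performed). Classification metrics are
computed at threshold 0.5; κ uses marginal-product chance agreement;
AUROC is the rank (Mann–Whitney) statistic with tie midranks, checked
against an O(n²) pairwise oracle in tests. Feature ranking is by mean
absolute per-observation additive contribution — TreeSHAP values from the
boosted model, |standardized coefficient| for the logistic baseline.
Unadjusted odds ratios use Woolf (log-normal) confidence intervals, with
an optional Haldane 0.5 correction for zero cells (off by default, zero
cells raise).

## The synthetic generator

The generator emulates the study's data-generating process, not its
licensed data. Per person it draws demographics (66.4% female, 36.3% HMO,
the four-region and four-age-bracket mixes), chronic-condition indicators
at configured prevalences (the conditions with published cohort
prevalences use them: anxiety 14.0%, depression 16.9%, substance abuse
7.5%, other pain 35%, OA pain 55.3%; the remainder — asthma 8%, cancer
15%, arrhythmia 15%, COPD 12%, dementia 7%, diabetes 27%, hyperlipidemia
55%, hypertension 70%, obesity 17% — are fixed once at values typical of
a Medicare-Advantage OA population), independent CV-high (16.9%) and
GI-high (34.5%) factor indicators, and a 21.6% baseline NSAID-user
fraction. Episode lengths are a short/long mixture (7–30 d vs 60–300 d,
35% long) decomposed into 30-day fills with refill dates jittered by 0–7
uncovered days, so planted episodes *exercise* the gap-bridging logic
rather than avoiding it. Provider ids are drawn from per-person pools of
size 1–6 with weights chosen so the expected FCI (≈ 1 − E[1/k]) is near
0.44. Follow-up long-term use is Bernoulli with logit
−2.2 + 0.01·(baseline NSAID days) + category effect + 0.05·(opioid
fills) − 0.5·FCI, giving roughly a one-in-eight flagged rate under the
default marginals.

Deliberate simplifications: conditions co-occur independently; CV and GI
factors are independent (the published joint distribution is mildly
dependent); there is no billing detail, no ICD co-occurrence structure,
and no adherence behaviour (a filled supply is consumed as dispensed).
Passing tests on this generator therefore demonstrate that the pipeline's
logic is correct under its stated assumptions — not that the effect
estimates would transport to real claims.

Planted-truth mode realizes hand-specified scenarios exactly (no jitter):
per scenario one person with chosen age, enrollment continuity, OA entry
route, risk category (realized through condition codes, or through a
co-medication overlap when requested) and exposure episodes with exact
ingredient, daily dose, length and period. The 72-cell rule grid
(4 categories × {celecoxib 200, diclofenac 100, naproxen 500 mg/day} ×
{59, 60, 61, 89, 90, 91 days}) carries hand-derived expected flags and is
recovered at 100% end to end.

Two named scenarios support model-stage calibration. The *strong-signal*
scenario raises the link coefficients (intercept −5, 0.05 per baseline
day, category effects up to 1.5, 0.3 per opioid fill, −2.0 per FCI unit)
so follow-up long-term use is nearly deterministic in the planted
features; a correctly wired modelling stage recovers them as the top
contributors with held-out AUROC > 0.85. The *null* scenario makes the
target genuinely independent of every feature: the link is flat **and**
exposure is restricted to non-selective NSAIDs at non-exempt doses —
without that restriction the rule table itself leaks risk category into
the target through the class and dose exemptions. The null event rate is
set near 25% so the sampling noise of the held-out rank AUROC stays small
at n = 5,000.

## Problem sizes and numerics

Default simulations in tests and the acceptance script use 2,000 persons
for marginal-agreement checks (binomial 3-SE tolerance) and 5,000 persons
for model-recovery checks; oracle-equivalence suites use 1,000 random
fill sets over a two-year window with gaps {0, 7, 30}. Presentation
percentages are rounded half-up to one decimal. Seeds are explicit
everywhere: the pipeline's single seed fans out to the generator and the
model split, and regeneration under a fixed seed is byte-identical.

## Known limitations

Representative rather than authoritative code lists; a single simplified
service-type field instead of procedure/revenue coding; no washout or
new-user design (baseline inappropriate users cannot be excluded without
pre-baseline risk data, so they remain in the cohort); no gastroprotective
co-therapy logic (PPI co-prescription does not enter the target); OTC
exposure unobservable. Real-data performance metrics depend on the
licensed source data and are not reproduced here; the synthetic recovery
properties stand in for them.
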
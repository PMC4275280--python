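# Methods

## The instrument

The package encodes a 10-item questionnaire score that predicts school-age
asthma from symptoms reported around age 3. Items and integer weights:

| # | Item | Categories (points) |
|---|------|---------------------|
| 1 | Sex | female 0, male 1 |
| 2 | Age at assessment | 1y 0, 2y 1, 3y 1 |
| 3 | Wheeze without a cold (12m) | no 0, yes 1 |
| 4 | Wheeze attacks (12m) | 0–3 0, >3 2 |
| 5 | Wheeze interfering with activities | never 0, a little 1, a lot 2 |
| 6 | Wheeze causing shortness of breath | never 0, sometimes 2, always 3 |
| 7 | Exercise/excitement-induced wheeze or cough | no 0, yes 1 |
| 8 | Dust/grass/pet-triggered wheeze or cough | no 0, yes 1 |
| 9 | Eczema ever | no 0, yes 1 |
| 10 | Parental wheeze/asthma/bronchitis | mother +1, father +1 |

The total ranges 0–15; risk bands are low (≤5), medium (6–9) and high (≥10).
Item 10 is represented as two additive sub-flags so a child with both
parents affected scores 2. Answer codes are case-insensitive, trimmed, with
apostrophes dropped and spaces collapsed to underscores.

Validation cohorts answer in their own dialect; an `ItemMapping` per item
translates cohort answers into the canonical codes. The packaged mapping for
the German birth-cohort 3-year interview negates item 3 (the cohort asked
whether wheeze *accompanied* a cold, so "no/sometimes" maps to the scoring
"yes"), uses a sleep-disturbance proxy for item 5, maps the binary item-6
question to the 2-point "sometimes" category (the interview never offered
"always"), and declares item 8 absent (no comparable question existed).

## Cohort model and outcome rules

Data are long-format CSV rows `(participant_id, age, variable, value)` with
baseline variables at age 0. Wave age *n* covers the 12 months before the
age-*n* assessment; no calendar-date arithmetic is attempted.

The analysis set drops children missing either inclusion item (wheeze, dry
night cough at 3y) or either primary-outcome item (wheeze, asthma drugs at
8y). Inclusion sets: symptomatic (wheeze OR cough at 3y, the primary
sample), wheeze-only, cough-only, everyone assessed, and children of
non-allergic parents (baseline composite of parental asthma/rhinitis/eczema
— the questionnaire composite is the closest available analogue of the
"non-allergic parents" stratum).

Outcome definitions return `True`/`False`/`None`; `None` means the waves or
assays the definition needs were never collected, and such children leave
the scenario's denominator rather than being imputed. The longitudinal
"any asthma to 20y" rule requires, at some wave from age 3 on, at least 2 of
{physician diagnosis ever by that wave, asthma drugs in the last 12 months,
an indicative symptom (wheeze, shortness of breath, nocturnal dry cough) in
the last 12 months}. We read "at any follow-up" as quantifying the wave, so
the criteria must co-occur within one wave (diagnosis being cumulative);
`OutcomeSpec(same_wave=False)` switches to pooling criteria across waves.
Allergic asthma additionally requires specific IgE ≥ 0.35 kU/l to at least
one of dust mite, dog, cat, birch or timothy at any assay. Increased airway
responsiveness is a ≥ 20% FEV₁ drop under methacholine challenge at 20y.

## Missing-data strategies

* **Zero-fill** (primary): absent items contribute their 0-point baseline.
* **Complement from earlier waves**: item 9 becomes "eczema ever up to the
  scoring age" and item 10 pools the baseline parental history; a later "no"
  never overwrites an earlier "yes".
* **Random imputation**: the structurally missing answers (item 8 entirely;
  the "always" category of item 6) are drawn from the development cohort's
  published answer frequencies. Children answering the 2-point item-6
  category are reallocated between "sometimes" and "always" with
  probabilities proportional to the development marginals (29%/6%); this
  proportional reallocation is the minimal-assumption mechanics, since only
  marginals were published. 100 replicates by default.
* **Permutation null**: observed total scores are reshuffled between
  children, preserving the score multiset while destroying the score-outcome
  association; reported alongside real scenarios as a reference row.

Replicated strategies pool with Rubin's rules: the pooled estimate is the
replicate mean and the total variance is the mean within-replicate variance
plus (1 + 1/m) times the between-replicate variance; 95% CIs use ±1.96·√T.
The odds ratio is pooled on the log scale. Replicate *r* always draws from
the stream `(seed, r)`, so any single replicate is reproducible in
isolation.

## Statistical core

* **Logistic model**: logit P(Y=1) = a + b·score, fitted by Newton/IRLS;
  convergence when the largest coefficient step is < 1e-8, capped at 50
  iterations. Fits with |b| > 15, or that fail to converge (the signature of
  separation, where the information matrix collapses), are flagged and
  their CIs suppressed. A constant score vector collapses to the
  intercept-only model (slope exactly 0, intercept = logit prevalence).
* **Discrimination**: the c statistic is the Mann–Whitney concordance with
  ties counted ½, computed on the raw integer score (any strictly increasing
  transform, including the fitted probabilities, gives the identical value —
  asserted by test). The 95% CI uses DeLong's placement-value variance by
  default; a stratified bootstrap is available as a switch, since the
  original report does not name its method.
* **Performance**: Nagelkerke's R² (Cox–Snell rescaled by its maximum) and
  the maximum-rescaled Brier score 1 − Brier/(p̄(1−p̄)); both are 0 for the
  prevalence-only model and 1 for perfect prediction. The odds ratio per
  score point is exp(b) with a Wald interval.
* **Threshold table**: test-positivity is score ≥ cutoff (high score = high
  risk). Sensitivity, specificity, predictive values and likelihood ratios
  come from the observed 2×2 counts by default (`mode="model_based"`
  substitutes expected counts under the fitted model; which was used
  originally is ambiguous, so both exist and raw counts are the default).
  Undefined measures on empty margins are NaN-flagged, never exceptions.
* **Calibration**: children are sorted by fitted probability (stable sort;
  remainder to the lowest-index groups) into 8 nearly equal groups; each
  group reports mean predicted probability, observed frequency and an exact
  Clopper–Pearson 95% interval from beta quantiles. No smoother is fitted;
  the numeric table is the product.
* **Development-cohort score distribution**: from a published
  sensitivity/specificity table, P(S ≥ c) = prev·sens(c) +
  (1−prev)·(1−spec(c)); differencing over consecutive integer cutoffs
  recovers per-score masses (clip at −1e-9, total must reach 1 ± 1e-9).
* **Proportion CIs** use a percentile bootstrap (default 2,000 resamples).

## Synthetic cohort

The generator emulates the validation study's structure with known ground
truth; it makes no attempt to reproduce the confidential individual-level
data or its published metric values.

A single standard-normal liability per child induces item dependence:
each categorical item thresholds a latent normal with loading 0.5 on the
liability (0.6 for the 3y inclusion symptoms), so configured marginals are
hit exactly in expectation regardless of correlation. Scoring-item
marginals default to the validation interview's published frequencies;
collapsed answer groups are split into plausible sub-shares that sum to the
printed group totals (e.g. 0.53 for ">3 attacks" split 0.30/0.15/0.08), and
the dialect mapping collapses them back. 54% of children are male; wheeze
and nocturnal cough at 3y run at 9.6%/9.5%, giving ≈ 16% symptomatic.

The 8-year outcome is drawn per child as Bernoulli(expit(a + b·score)) on
the child's **true** score, with b = ln(1.7) and a = −4.75. The intercept is
the package's one calibrated constant: because symptomatic children score
higher through the shared liability (subsample mean score ≈ 5.7), −4.75
places outcome prevalence in the symptomatic subsample at ≈ 0.20 (probed
once on a 60k draw, then frozen). The 8y wheeze and drugs items equal the
outcome for cases; non-cases get mutually exclusive wheeze-only/drugs-only
noise (10% each) so that "wheeze AND drugs" reproduces the drawn outcome
exactly — this makes logistic-slope recovery a clean test.

Attrition: 64% retained to the 8y wave; 86% of the retained traced to 20y;
77% of the traced undergo lung-function testing; half of the untraced keep
the 13y wave. Later waves carry symptom/drug/diagnosis items from a per-wave
"active asthma" state (probability 0.6 given an 8y case, 0.025 otherwise —
chosen so the 2-of-3 rule yields ≈ 42% any-asthma among the traced
symptomatic, as in the study). Sensitization is drawn per child (84% of
cases, 38% of non-cases), then per allergen; IgE levels are log-normal with
elevated location for sensitized child-allergen pairs, assayed at nine
waves. FEV₁ drop at 20y is normal (26 ± 8 if active, 14 ± 7 otherwise),
clipped to [0, 80].

What the generator does **not** emulate: informative (non-MCAR) item
missingness, secular drift in questionnaire wording, within-family
clustering beyond the single liability factor, and measurement error in the
assays. Passing tests therefore demonstrate the pipeline's correctness and
calibration under the configured structure, not the published values of the
real cohort, whose individual-level data are confidential.

`plant_missingness` punches MCAR holes at configured per-variable rates to
exercise the imputation paths.

## Determinism and problem sizes

All randomness flows through `numpy` Generators seeded explicitly;
replicate r of any replicated strategy uses the stream `(seed, r)`.
Identical parameters and seed give byte-identical CSVs (canonical row order,
floats at 6 significant digits). The test suite works at n = 1,314 for
cohort-level checks, n = 10,000 for marginal/recovery checks, and 200
repetitions at n = 1,000 for CI coverage; the 16-scenario default grid on
the default cohort (two 100-replicate scenarios included) completes in a few
seconds on one CPU.

## Known limitations

* The development-cohort frequencies for item 10 are published as
  none/mother/father shares that overlap (both-parent families); they are
  stored as two independent sub-flag margins.
* The "regularly" category of the cohort's item-5 proxy collapses three raw
  categories whose individual frequencies were never published; the mapping
  exposes them as one code.
* The permutation-null scenario pools an odds ratio across replicates whose
  per-replicate fits occasionally flirt with flatness at small n; replicates
  with separated fits are dropped from the OR pool (never from the AUC
  pool) and the row is flagged if fewer than two remain.
* DeLong intervals are asymptotic; at the primary scenario's n ≈ 140 they
  can overshoot [0, 1] and are clipped.
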
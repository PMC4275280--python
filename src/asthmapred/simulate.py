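"""Synthetic birth-cohort generator with known ground truth.

Emulates the structure of a ~1,314-child birth cohort followed at yearly
waves to age 20: questionnaire answer marginals at the 3-year scoring
interview, symptom-based inclusion at 3 years, an 8-year asthma outcome
generated from the child's true score through a logistic link, attrition,
and later-wave outcomes (symptoms, drugs, physician diagnosis, specific IgE,
methacholine challenge) with persistence conditional on the 8-year outcome.

A single standard-normal latent liability per child induces correlation
between items via probit-style thresholds; the configured marginals are hit
exactly in expectation regardless of the loading.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri
from scipy.stats import norm

from .cohort import AERO_ALLERGENS, ParticipantRecord, WaveData
from .score import default_mas_mapping, default_score_definition

__all__ = ["GeneratorParams", "generate_cohort", "plant_missingness", "simulate_scores_outcomes"]

#: order in which scoring-item variables are drawn (fixed for determinism)
SCORING_VARIABLES = (
    "wheeze_with_cold",
    "wheeze_attacks_12m",
    "sleep_disturbed_wheeze",
    "breathless_after_words",
    "exercise_wheeze",
    "eczema_12m",
    "mother_asthma_12m",
    "father_asthma_12m",
)


def _default_marginals() -> dict[str, dict[str, float]]:
    with resources.files("asthmapred.data").joinpath("mas_marginals.json").open() as fh:
        return json.load(fh)["scoring_items"]


@dataclass(frozen=True)
class GeneratorParams:
    """Study-condition knobs of the synthetic cohort.

    Defaults reproduce the validation study's structure: 1,314 newborns, 54%
    male, 3-year scoring-item marginals from the validation interview, ~17%
    of retained children symptomatic at 3 years, outcome odds ratio 1.7 per
    score point with ~20% prevalence among the symptomatic, 64% retained to
    8 years, 86% of those traced to 20, and 77% of the traced undergoing
    lung-function testing.
    """

    n_children: int = 1314
    seed: int = 0
    item_marginals: Mapping[str, Mapping[str, float]] = field(default_factory=_default_marginals)
    male_fraction: float = 0.54
    item_loading: float = 0.5        # latent-liability loading of scoring items
    symptom_loading: float = 0.6     # loading of the 3y inclusion symptoms
    wheeze3_rate: float = 0.096
    cough3_rate: float = 0.095
    outcome_intercept: float = -4.75
    outcome_slope: float = math.log(1.7)
    retention_8y: float = 0.64
    trace_20y: float = 0.86
    wave13_if_untraced: float = 0.5
    lung_function_20y: float = 0.77
    wave_ages: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 16, 18, 20)
    ige_assay_ages: tuple[int, ...] = (1, 2, 3, 5, 7, 10, 13, 18, 20)
    later_waves: bool = True         # emit waves beyond the scoring age
    # persistence of asthma activity at waves other than 8y
    active_rate_case: float = 0.6
    active_rate_control: float = 0.025
    # item probabilities given active / inactive at a wave
    p_wheeze_active: float = 0.8
    p_sob_active: float = 0.5
    p_cough_active: float = 0.5
    p_drugs_active: float = 0.7
    p_dx_new_active: float = 0.6
    p_wheeze_inactive: float = 0.05
    p_sob_inactive: float = 0.03
    p_cough_inactive: float = 0.05
    p_drugs_inactive: float = 0.02
    p_dx_new_inactive: float = 0.005
    # 8y single-item noise for non-cases (mutually exclusive wheeze-/drugs-only)
    p_wheeze_only_8y: float = 0.10
    p_drugs_only_8y: float = 0.10
    p_dx_case_8y: float = 0.8
    # sensitization model
    p_sensitized_case: float = 0.84
    p_sensitized_control: float = 0.38
    allergen_probs: tuple[float, ...] = (0.6, 0.25, 0.35, 0.35, 0.35)  # mite, dog, cat, birch, timothy
    p_allergen_background: float = 0.03
    ige_mu_pos: float = math.log(3.0)
    ige_sigma_pos: float = 1.2
    ige_mu_neg: float = math.log(0.05)
    ige_sigma_neg: float = 1.0
    # methacholine challenge (percent FEV1 drop)
    fev1_mu_active: float = 26.0
    fev1_sd_active: float = 8.0
    fev1_mu_inactive: float = 14.0
    fev1_sd_inactive: float = 7.0
    # early childhood and baseline
    eczema_early_rate: float = 0.15
    mother_allergy_extra: float = 0.17
    father_allergy_extra: float = 0.16
    mother_asthma_ever_extra: float = 0.12
    father_asthma_ever_extra: float = 0.10
    cord_ige_mu: float = math.log(0.2)
    cord_ige_sigma: float = 1.6

    def validate(self) -> None:
        for var, dist in self.item_marginals.items():
            probs = list(dist.values())
            if any(not 0 <= p <= 1 for p in probs):
                raise ValueError(f"{var}: marginal probabilities must lie in [0,1]")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{var}: marginals sum to {sum(probs)}, not 1")
        for name in ("item_loading", "symptom_loading"):
            if not -1 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie strictly inside (-1, 1)")
        for name in ("male_fraction", "wheeze3_rate", "cough3_rate", "retention_8y",
                     "trace_20y", "lung_function_20y"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0,1]")
        if self.n_children < 1:
            raise ValueError("n_children must be positive")


def _raw_point_maps() -> dict[str, dict[str, int]]:
    """Per-variable raw-answer -> score-point lookup derived from the
    canonical definition and dialect mapping (keeps the vectorized scorer in
    lockstep with :func:`asthmapred.score.translate_responses`)."""
    definition = default_score_definition()
    maps: dict[str, dict[str, int]] = {}
    for mapping in default_mas_mapping():
        if mapping.comparability == "absent" or mapping.item_id in (1, 2):
            continue
        item = definition.item(mapping.item_id)
        if item.additive:
            for var in mapping.source_variables:
                maps[var] = {}
                for key, code in mapping.translation.items():
                    src, raw = key.split(":")
                    if src == var:
                        maps[var][raw] = item.score_answer(code) if code else 0
        else:
            (var,) = mapping.source_variables
            maps[var] = {raw: item.score_answer(code) for raw, code in mapping.translation.items()}
    return maps


def _latent_category(
    rng: np.random.Generator,
    liability: np.ndarray,
    loading: float,
    dist: Mapping[str, float],
) -> np.ndarray:
    """Draw one categorical item for every child via a thresholded latent
    normal correlated with the shared liability; marginals are preserved."""
    n = liability.size
    z = loading * liability + math.sqrt(1 - loading**2) * rng.standard_normal(n)
    u = norm.cdf(z)
    codes = list(dist)
    cum = np.cumsum([dist[c] for c in codes])
    cum[-1] = 1.0  # guard rounding
    idx = np.searchsorted(cum, u, side="left")
    return np.array(codes, dtype=object)[idx]


def _latent_flag(rng, liability, loading, rate) -> np.ndarray:
    n = liability.size
    z = loading * liability + math.sqrt(1 - loading**2) * rng.standard_normal(n)
    return z > ndtri(1 - rate)


def _draw_core(params: GeneratorParams) -> dict:
    """Vectorized draw of everything score- and outcome-related."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_children

    liability = rng.standard_normal(n)
    male = rng.random(n) < params.male_fraction

    items: dict[str, np.ndarray] = {}
    for var in SCORING_VARIABLES:
        items[var] = _latent_category(rng, liability, params.item_loading, params.item_marginals[var])

    wheeze3 = _latent_flag(rng, liability, params.symptom_loading, params.wheeze3_rate)
    cough3 = _latent_flag(rng, liability, params.symptom_loading, params.cough3_rate)

    # true score from the translated 3-year responses (item 8 zero-filled)
    point_maps = _raw_point_maps()
    scores = np.where(male, 1, 0) + 1  # sex + age-3 contribution
    for var in SCORING_VARIABLES:
        pm = point_maps[var]
        scores = scores + np.array([pm[c] for c in items[var]], dtype=int)

    p_outcome = expit(params.outcome_intercept + params.outcome_slope * scores)
    y8 = rng.random(n) < p_outcome

    retained8 = rng.random(n) < params.retention_8y
    traced20 = retained8 & (rng.random(n) < params.trace_20y)
    has13 = traced20 | (retained8 & (rng.random(n) < params.wave13_if_untraced))
    lungfunc = traced20 & (rng.random(n) < params.lung_function_20y)

    return {
        "rng": rng,
        "liability": liability,
        "male": male,
        "items": items,
        "wheeze3": wheeze3,
        "cough3": cough3,
        "scores": scores,
        "p_outcome": p_outcome,
        "y8": y8,
        "retained8": retained8,
        "traced20": traced20,
        "has13": has13,
        "lungfunc": lungfunc,
    }


def simulate_scores_outcomes(params: GeneratorParams) -> tuple[np.ndarray, np.ndarray]:
    """Fast path: (true score, 8-year outcome) arrays only, same draw core
    as the full generator."""
    core = _draw_core(params)
    return core["scores"], core["y8"]


def _yn(flag: bool) -> str:
    return "yes" if flag else "no"


def generate_cohort(params: GeneratorParams | None = None) -> tuple[list[ParticipantRecord], pd.DataFrame]:
    """Generate the cohort plus a ground-truth sidecar.

    Returns participant records (long-CSV writable via
    :func:`asthmapred.cohort.write_cohort`) and a sidecar data frame with
    each child's latent liability, true score, outcome probability and
    follow-up status. Identical params produce byte-identical output.
    """
    params = params or GeneratorParams()
    core = _draw_core(params)
    rng: np.random.Generator = core["rng"]
    n = params.n_children
    width = max(4, len(str(n)))
    ids = [f"C{i + 1:0{width}d}" for i in range(n)]

    male = core["male"]
    liability = core["liability"]
    items = core["items"]
    y8 = core["y8"]

    # baseline parental history; 12-month report at 3y implies "ever"
    mother_12m = items["mother_asthma_12m"] == "yes"
    father_12m = items["father_asthma_12m"] == "yes"
    mother_ever = mother_12m | (rng.random(n) < params.mother_asthma_ever_extra)
    father_ever = father_12m | (rng.random(n) < params.father_asthma_ever_extra)
    mother_allergy = mother_ever | (rng.random(n) < params.mother_allergy_extra)
    father_allergy = father_ever | (rng.random(n) < params.father_allergy_extra)
    cord_ige = np.exp(rng.normal(params.cord_ige_mu, params.cord_ige_sigma, size=n))

    eczema_early = {
        age: _latent_flag(rng, liability, params.item_loading, params.eczema_early_rate)
        for age in (0, 1, 2)
    }

    # sensitization: per-child, per-allergen flags
    sensitized = rng.random(n) < np.where(y8, params.p_sensitized_case, params.p_sensitized_control)
    allergen_flags = {}
    for a_idx, allergen in enumerate(AERO_ALLERGENS):
        p = np.where(sensitized, params.allergen_probs[a_idx], params.p_allergen_background)
        allergen_flags[allergen] = rng.random(n) < p

    later_ages = [a for a in params.wave_ages if a > 3]

    # per-wave asthma activity (8y pinned to the true outcome)
    active = {}
    for age in later_ages:
        if age == 8:
            active[age] = y8.copy()
        else:
            p = np.where(y8, params.active_rate_case, params.active_rate_control)
            active[age] = rng.random(n) < p

    def wave_flags(act: np.ndarray, p_act: float, p_inact: float) -> np.ndarray:
        return rng.random(n) < np.where(act, p_act, p_inact)

    wave_vars: dict[int, dict[str, np.ndarray]] = {}
    dx_ever = rng.random(n) < 0.0  # all False
    # 3y wave: inclusion symptoms already drawn; add drugs/dx/SOB for the 2-of-3 rule
    act3 = rng.random(n) < np.where(y8, 0.5, params.active_rate_control)
    sob3 = wave_flags(act3, params.p_sob_active, params.p_sob_inactive)
    drugs3 = wave_flags(act3, params.p_drugs_active, params.p_drugs_inactive)
    dx_ever = dx_ever | wave_flags(act3, 0.3, params.p_dx_new_inactive)
    wave_vars[3] = {
        "wheeze_12m": core["wheeze3"],
        "dry_cough_night_12m": core["cough3"],
        "shortness_of_breath_12m": sob3,
        "asthma_drugs_12m": drugs3,
        "physician_asthma_dx": dx_ever.copy(),
    }
    for age in later_ages:
        act = active[age]
        if age == 8:
            u = rng.random(n)
            wheeze = y8 | (u < params.p_wheeze_only_8y)
            drugs = y8 | ((u >= params.p_wheeze_only_8y) & (u < params.p_wheeze_only_8y + params.p_drugs_only_8y))
            dx_ever = dx_ever | wave_flags(y8, params.p_dx_case_8y, params.p_dx_new_inactive)
        else:
            wheeze = wave_flags(act, params.p_wheeze_active, params.p_wheeze_inactive)
            drugs = wave_flags(act, params.p_drugs_active, params.p_drugs_inactive)
            dx_ever = dx_ever | wave_flags(act, params.p_dx_new_active, params.p_dx_new_inactive)
        sob = wave_flags(act, params.p_sob_active, params.p_sob_inactive)
        cough = wave_flags(act, params.p_cough_active, params.p_cough_inactive)
        wave_vars[age] = {
            "wheeze_12m": wheeze,
            "dry_cough_night_12m": cough,
            "shortness_of_breath_12m": sob,
            "asthma_drugs_12m": drugs,
            "physician_asthma_dx": dx_ever.copy(),
        }

    # IgE levels at assay ages for all children/allergens (presence filtered later)
    ige_levels: dict[tuple[int, str], np.ndarray] = {}
    for age in params.ige_assay_ages:
        for allergen in AERO_ALLERGENS:
            flag = allergen_flags[allergen]
            mu = np.where(flag, params.ige_mu_pos, params.ige_mu_neg)
            sigma = np.where(flag, params.ige_sigma_pos, params.ige_sigma_neg)
            ige_levels[(age, allergen)] = np.exp(rng.normal(mu, sigma))

    active20 = active.get(20, y8)
    fev1 = np.clip(
        rng.normal(
            np.where(active20, params.fev1_mu_active, params.fev1_mu_inactive),
            np.where(active20, params.fev1_sd_active, params.fev1_sd_inactive),
        ),
        0.0, 80.0,
    )

    # which wave ages each child attended
    dropout_pre8 = rng.integers(4, 9, size=n)  # first missed age for the non-retained

    records: list[ParticipantRecord] = []
    for i in range(n):
        rec = ParticipantRecord(
            participant_id=ids[i],
            sex="male" if male[i] else "female",
            cord_blood_ige=float(cord_ige[i]),
        )
        rec.baseline["mother_allergy"] = _yn(mother_allergy[i])
        rec.baseline["father_allergy"] = _yn(father_allergy[i])
        rec.baseline["mother_asthma_ever"] = _yn(mother_ever[i])
        rec.baseline["father_asthma_ever"] = _yn(father_ever[i])

        ages = [a for a in params.wave_ages if a <= 3]
        if params.later_waves:
            if core["retained8"][i]:
                ages += [a for a in params.wave_ages if 3 < a <= 8]
                if core["traced20"][i]:
                    ages += [a for a in params.wave_ages if a > 8]
                elif core["has13"][i]:
                    ages += [a for a in params.wave_ages if 8 < a <= 13]
            else:
                ages += [a for a in params.wave_ages if 3 < a < dropout_pre8[i]]

        for age in ages:
            wave = WaveData(age=age)
            if age < 3:
                wave.answers["eczema_12m"] = _yn(eczema_early[age][i]) if age in eczema_early else "no"
            if age == 3:
                for var in SCORING_VARIABLES:
                    wave.answers[var] = str(items[var][i])
                for var, arr in wave_vars[3].items():
                    wave.answers[var] = _yn(arr[i])
            elif age in wave_vars:
                for var, arr in wave_vars[age].items():
                    wave.answers[var] = _yn(arr[i])
            if age in params.ige_assay_ages:
                for allergen in AERO_ALLERGENS:
                    wave.specific_ige[allergen] = float(ige_levels[(age, allergen)][i])
            if age == 20 and core["lungfunc"][i]:
                wave.fev1_drop_pct = float(fev1[i])
            rec.waves[age] = wave
        records.append(rec)

    sidecar = pd.DataFrame(
        {
            "participant_id": ids,
            "sex": np.where(male, "male", "female"),
            "liability": np.round(liability, 6),
            "true_score": core["scores"],
            "outcome_probability": np.round(core["p_outcome"], 6),
            "outcome_8y": y8.astype(int),
            "symptomatic_3y": (core["wheeze3"] | core["cough3"]).astype(int),
            "retained_8y": core["retained8"].astype(int),
            "traced_20y": core["traced20"].astype(int),
            "lung_function_20y": core["lungfunc"].astype(int),
        }
    )
    return records, sidecar


def plant_missingness(
    cohort: list[ParticipantRecord],
    rates: Mapping[str, float],
    seed: int = 0,
) -> list[ParticipantRecord]:
    """Punch missing-completely-at-random holes into wave answers.

    ``rates`` maps variable names to per-observation deletion probabilities.
    Returns new records; the input cohort is untouched."""
    for var, rate in rates.items():
        if not 0 <= rate <= 1:
            raise ValueError(f"rate for {var!r} must lie in [0,1]")
    rng = np.random.default_rng(seed)
    out = []
    for rec in sorted(cohort, key=lambda r: r.participant_id):
        new = ParticipantRecord(
            participant_id=rec.participant_id,
            sex=rec.sex,
            baseline=dict(rec.baseline),
            cord_blood_ige=rec.cord_blood_ige,
        )
        for age in sorted(rec.waves):
            w = rec.waves[age]
            answers = {}
            for var, val in w.answers.items():
                if var in rates and rng.random() < rates[var]:
                    continue
                answers[var] = val
            new.waves[age] = WaveData(
                age=age,
                answers=answers,
                specific_ige=dict(w.specific_ige),
                fev1_drop_pct=w.fev1_drop_pct,
            )
        out.append(new)
    return out
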
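"""Longitudinal birth-cohort data model: records, CSV round-trip, inclusion
criteria, the missing-data exclusion rule, and binary asthma outcome rules.

The cohort is stored long-format, one row per (participant, age, variable,
value). Children are assessed at nominal whole-year waves up to age 20; each
wave's symptom questions refer to the preceding 12 months. Specific-IgE
assays appear as numeric ``ige_<allergen>`` variables (kU/l) and the
methacholine challenge result at 20 years as ``fev1_drop_pct`` (percent fall
in FEV1 from baseline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .score import normalize_code

__all__ = [
    "WaveData",
    "ParticipantRecord",
    "InclusionSpec",
    "OutcomeSpec",
    "read_cohort",
    "write_cohort",
    "apply_inclusion",
    "exclude_missing",
    "evaluate_outcome",
]

INCLUSION_NAMES = (
    "primary_wheeze_or_cough",
    "all_available",
    "wheeze_only",
    "cough_only",
    "nonallergic_parents",
)

OUTCOME_NAMES = (
    "primary_wheeze_and_drugs_8y",
    "wheeze_8y",
    "drugs_8y",
    "physician_dx_ever_8y",
    "any_asthma_to_20y",
    "allergic_asthma_to_20y",
    "wheeze_or_meds_13y",
    "wheeze_or_meds_20y",
    "airway_responsiveness_20y",
)

#: allergens assayed regularly for specific IgE
AERO_ALLERGENS = ("mite", "dog", "cat", "birch", "timothy")

#: symptoms counting as "indicative" in the 2-of-3 longitudinal asthma rule
INDICATIVE_SYMPTOMS = ("wheeze_12m", "shortness_of_breath_12m", "dry_cough_night_12m")

BASELINE_VARIABLES = (
    "sex",
    "mother_allergy",
    "father_allergy",
    "mother_asthma_ever",
    "father_asthma_ever",
    "cord_blood_ige",
)

_NUMERIC_PREFIXES = ("ige_",)
_NUMERIC_VARIABLES = ("fev1_drop_pct", "cord_blood_ige")


def _is_numeric_variable(name: str) -> bool:
    return name in _NUMERIC_VARIABLES or any(name.startswith(p) for p in _NUMERIC_PREFIXES)


@dataclass
class WaveData:
    """One follow-up assessment: categorical answers plus optional assays."""

    age: int
    answers: dict[str, str] = field(default_factory=dict)
    specific_ige: dict[str, float] = field(default_factory=dict)
    fev1_drop_pct: float | None = None

    def __post_init__(self) -> None:
        if self.fev1_drop_pct is not None and not 0 <= self.fev1_drop_pct <= 100:
            raise ValueError(f"fev1_drop_pct must be in [0,100], got {self.fev1_drop_pct}")
        if any(v < 0 for v in self.specific_ige.values()):
            raise ValueError("IgE values must be >= 0")

    def answer(self, variable: str) -> str | None:
        v = self.answers.get(variable)
        if v is None or str(v).strip() == "":
            return None
        return normalize_code(v)


@dataclass
class ParticipantRecord:
    """One child: fixed baseline attributes plus a wave per follow-up age."""

    participant_id: str
    sex: str | None = None
    waves: dict[int, WaveData] = field(default_factory=dict)
    baseline: dict[str, str] = field(default_factory=dict)
    cord_blood_ige: float | None = None

    def __post_init__(self) -> None:
        if self.sex is not None and self.sex not in ("female", "male"):
            raise ValueError(f"sex must be female/male, got {self.sex!r}")
        for age in self.waves:
            if not 0 <= age <= 20:
                raise ValueError(f"wave age {age} outside 0..20")

    def wave(self, age: int) -> WaveData | None:
        return self.waves.get(age)

    def answer_at(self, age: int, variable: str) -> str | None:
        w = self.waves.get(age)
        return None if w is None else w.answer(variable)

    def baseline_flag(self, variable: str) -> bool:
        v = self.baseline.get(variable)
        return v is not None and normalize_code(v) == "yes"


@dataclass(frozen=True)
class InclusionSpec:
    """A named validation-sample definition applied at the scoring age."""

    name: str = "primary_wheeze_or_cough"

    def __post_init__(self) -> None:
        if self.name not in INCLUSION_NAMES:
            raise ValueError(f"unknown inclusion {self.name!r}; choose from {INCLUSION_NAMES}")


@dataclass(frozen=True)
class OutcomeSpec:
    """A named binary asthma outcome.

    ``ige_cut`` (kU/l) defines aero-allergen sensitization and
    ``fev1_cut_pct`` the positive methacholine challenge. ``same_wave``
    controls whether the 2-of-3 longitudinal rule requires its criteria to
    co-occur within one wave (default) or may be pooled across waves.
    """

    name: str = "primary_wheeze_and_drugs_8y"
    ige_cut: float = 0.35
    fev1_cut_pct: float = 20.0
    same_wave: bool = True

    def __post_init__(self) -> None:
        if self.name not in OUTCOME_NAMES:
            raise ValueError(f"unknown outcome {self.name!r}; choose from {OUTCOME_NAMES}")


class CohortFormatError(ValueError):
    pass


def read_cohort(path) -> list[ParticipantRecord]:
    """Read a long-format cohort CSV (participant_id, age, variable, value).

    Baseline variables live at age 0. Duplicate (participant, age, variable)
    rows are an error naming the offending line; unknown variables are kept
    as passthrough wave answers with a warning.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = ["participant_id", "age", "variable", "value"]
    if list(df.columns) != expected:
        raise CohortFormatError(f"expected columns {expected}, got {list(df.columns)}")

    records: dict[str, ParticipantRecord] = {}
    seen: set[tuple[str, int, str]] = set()
    known = set(BASELINE_VARIABLES) | set(INDICATIVE_SYMPTOMS) | {
        "asthma_drugs_12m", "physician_asthma_dx", "wheeze_with_cold",
        "wheeze_attacks_12m", "sleep_disturbed_wheeze", "breathless_after_words",
        "exercise_wheeze", "eczema_12m", "mother_asthma_12m", "father_asthma_12m",
        "fev1_drop_pct",
    }
    unknown_seen: set[str] = set()

    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        pid, age_s, var, val = row.participant_id, row.age, row.variable, row.value
        try:
            age = int(age_s)
        except ValueError as exc:
            raise CohortFormatError(f"line {i}: non-integer age {age_s!r}") from exc
        key = (pid, age, var)
        if key in seen:
            raise CohortFormatError(f"line {i}: duplicate entry for {key}")
        seen.add(key)
        if var not in known and not _is_numeric_variable(var) and var not in unknown_seen:
            unknown_seen.add(var)
            warnings.warn(f"unknown variable {var!r} preserved as passthrough", stacklevel=2)
        rec = records.setdefault(pid, ParticipantRecord(participant_id=pid))
        if val == "":
            continue  # explicit missing cell
        if var == "sex":
            rec.sex = normalize_code(val)
        elif var == "cord_blood_ige":
            rec.cord_blood_ige = float(val)
            rec.baseline[var] = val
        elif var in BASELINE_VARIABLES:
            rec.baseline[var] = val
        else:
            wave = rec.waves.setdefault(age, WaveData(age=age))
            if var.startswith("ige_"):
                wave.specific_ige[var[4:]] = float(val)
            elif var == "fev1_drop_pct":
                wave.fev1_drop_pct = float(val)
            else:
                wave.answers[var] = val
    return list(records.values())


def _fmt(value) -> str:
    if isinstance(value, float):
        return format(value, ".6g")
    return str(value)


def write_cohort(records: Iterable[ParticipantRecord], path) -> None:
    """Write records as canonical long CSV (sorted by id, age, variable)."""
    rows = []
    for rec in records:
        if rec.sex is not None:
            rows.append((rec.participant_id, 0, "sex", rec.sex))
        for var in BASELINE_VARIABLES:
            if var == "sex":
                continue
            if var == "cord_blood_ige" and rec.cord_blood_ige is not None:
                rows.append((rec.participant_id, 0, var, _fmt(rec.cord_blood_ige)))
            elif var in rec.baseline and var != "cord_blood_ige":
                rows.append((rec.participant_id, 0, var, rec.baseline[var]))
        for age in sorted(rec.waves):
            w = rec.waves[age]
            for var, val in w.answers.items():
                rows.append((rec.participant_id, age, var, val))
            for allergen, level in w.specific_ige.items():
                rows.append((rec.participant_id, age, f"ige_{allergen}", _fmt(level)))
            if w.fev1_drop_pct is not None:
                rows.append((rec.participant_id, age, "fev1_drop_pct", _fmt(w.fev1_drop_pct)))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    df = pd.DataFrame(rows, columns=["participant_id", "age", "variable", "value"])
    df.to_csv(path, index=False, lineterminator="\n")


def _yes(record: ParticipantRecord, age: int, variable: str) -> bool | None:
    v = record.answer_at(age, variable)
    return None if v is None else v == "yes"


def apply_inclusion(
    cohort: Iterable[ParticipantRecord],
    spec: InclusionSpec,
    scoring_age: int = 3,
) -> tuple[list[ParticipantRecord], dict[str, int]]:
    """Select the validation sample at the scoring age.

    Records without a wave at ``scoring_age`` are dropped first (counted in
    the returned log). The primary sample keeps children whose parents report
    wheeze or nocturnal dry cough in the 12 months before the scoring
    interview; ``wheeze_only``/``cough_only`` restrict to a single symptom;
    ``all_available`` applies no symptom filter; ``nonallergic_parents``
    keeps children with neither parent reporting asthma, rhinitis or eczema.
    """
    log = {"no_scoring_wave": 0}
    out: list[ParticipantRecord] = []
    for rec in cohort:
        if rec.wave(scoring_age) is None:
            log["no_scoring_wave"] += 1
            continue
        wheeze = _yes(rec, scoring_age, "wheeze_12m")
        cough = _yes(rec, scoring_age, "dry_cough_night_12m")
        if spec.name == "primary_wheeze_or_cough":
            keep = bool(wheeze) or bool(cough)
        elif spec.name == "wheeze_only":
            keep = bool(wheeze)
        elif spec.name == "cough_only":
            keep = bool(cough)
        elif spec.name == "all_available":
            keep = True
        else:  # nonallergic_parents
            keep = not rec.baseline_flag("mother_allergy") and not rec.baseline_flag("father_allergy")
        if keep:
            out.append(rec)
    return out, log


def exclude_missing(
    cohort: Iterable[ParticipantRecord],
    scoring_age: int = 3,
    outcome_age: int = 8,
) -> tuple[list[ParticipantRecord], dict[str, int]]:
    """Drop children missing any of the two inclusion items (wheeze, dry
    cough at the scoring age) or the two primary-outcome items (wheeze,
    asthma drugs at the outcome age). Returns the retained subset and a
    per-reason exclusion tally; idempotent."""
    log = {"inclusion_item_missing": 0, "outcome_item_missing": 0, "excluded_total": 0}
    out = []
    for rec in cohort:
        incl_missing = (
            _yes(rec, scoring_age, "wheeze_12m") is None
            or _yes(rec, scoring_age, "dry_cough_night_12m") is None
        )
        outc_missing = (
            _yes(rec, outcome_age, "wheeze_12m") is None
            or _yes(rec, outcome_age, "asthma_drugs_12m") is None
        )
        if incl_missing:
            log["inclusion_item_missing"] += 1
        if outc_missing:
            log["outcome_item_missing"] += 1
        if incl_missing or outc_missing:
            log["excluded_total"] += 1
        else:
            out.append(rec)
    return out, log


def _dx_ever_by(record: ParticipantRecord, age: int) -> bool:
    """Physician asthma diagnosis reported at any wave up to and including ``age``."""
    return any(
        record.answer_at(a, "physician_asthma_dx") == "yes"
        for a in record.waves
        if a <= age
    )


def _wave_criteria(record: ParticipantRecord, age: int) -> tuple[bool, bool, bool]:
    """The 2-of-3 rule's criteria at one wave: (dx ever by wave, drugs 12m,
    any indicative symptom 12m)."""
    drugs = record.answer_at(age, "asthma_drugs_12m") == "yes"
    symptom = any(record.answer_at(age, s) == "yes" for s in INDICATIVE_SYMPTOMS)
    return _dx_ever_by(record, age), drugs, symptom


def _any_asthma(record: ParticipantRecord, spec: OutcomeSpec, max_age: int = 20) -> bool:
    ages = [a for a in sorted(record.waves) if 3 <= a <= max_age]
    if spec.same_wave:
        return any(sum(_wave_criteria(record, a)) >= 2 for a in ages)
    crit = [False, False, False]
    for a in ages:
        for i, c in enumerate(_wave_criteria(record, a)):
            crit[i] = crit[i] or c
    return sum(crit) >= 2


def _sensitized(record: ParticipantRecord, cut: float) -> bool:
    return any(
        allergen in AERO_ALLERGENS and level >= cut
        for w in record.waves.values()
        for allergen, level in w.specific_ige.items()
    )


def evaluate_outcome(record: ParticipantRecord, spec: OutcomeSpec) -> bool | None:
    """Binary outcome for one child, or ``None`` when unobserved.

    ``None`` (rather than False) signals that the waves or assays the
    definition needs were never collected; scenario denominators count only
    observed children.
    """
    name = spec.name
    if name == "primary_wheeze_and_drugs_8y":
        wheeze, drugs = _yes(record, 8, "wheeze_12m"), _yes(record, 8, "asthma_drugs_12m")
        if wheeze is None or drugs is None:
            return None
        return wheeze and drugs
    if name == "wheeze_8y":
        return _yes(record, 8, "wheeze_12m")
    if name == "drugs_8y":
        return _yes(record, 8, "asthma_drugs_12m")
    if name == "physician_dx_ever_8y":
        if record.wave(8) is None or record.answer_at(8, "physician_asthma_dx") is None:
            return None
        return _dx_ever_by(record, 8)
    if name in ("any_asthma_to_20y", "allergic_asthma_to_20y"):
        if record.wave(20) is None:
            return None  # not traced to 20 years
        asthma = _any_asthma(record, spec)
        if name == "any_asthma_to_20y":
            return asthma
        return asthma and _sensitized(record, spec.ige_cut)
    if name in ("wheeze_or_meds_13y", "wheeze_or_meds_20y"):
        age = 13 if name == "wheeze_or_meds_13y" else 20
        wheeze, drugs = _yes(record, age, "wheeze_12m"), _yes(record, age, "asthma_drugs_12m")
        if wheeze is None and drugs is None:
            return None
        return bool(wheeze) or bool(drugs)
    if name == "airway_responsiveness_20y":
        w = record.wave(20)
        if w is None or w.fev1_drop_pct is None:
            return None
        return w.fev1_drop_pct >= spec.fev1_cut_pct
    raise AssertionError(f"unhandled outcome {name}")
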
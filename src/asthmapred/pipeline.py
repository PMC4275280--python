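"""Scenario orchestration: one (inclusion x scoring x outcome) cell at a
time, or the full sensitivity-analysis grid.

Each scenario applies the missing-data exclusion rule, selects the
validation sample, scores every child under the configured strategy
(replicated for random imputation and the permutation null), evaluates the
outcome on the per-scenario denominator of observed children, and computes
the discrimination/performance report. Replicated strategies pool AUC and
log-odds-ratio across replicates with Rubin's rules.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    InclusionSpec,
    OutcomeSpec,
    ParticipantRecord,
    apply_inclusion,
    evaluate_outcome,
    exclude_missing,
)
from .metrics import (
    LogisticFit,
    SingleClassError,
    auc,
    auc_variance_delong,
    calibration_table,
    fit_logistic,
    nagelkerke_r2,
    odds_ratio_per_point,
    scaled_brier,
    threshold_metrics,
)
from .missing import (
    complement_from_earlier,
    default_impute_targets,
    default_reference_frequencies,
    impute_random,
    pool_estimates,
    shuffle_scores,
)
from .score import compute_score, default_mas_mapping, default_score_definition, translate_responses

logger = logging.getLogger(__name__)

SCORING_STRATEGIES = ("primary_zero_fill", "complement_earlier", "impute_random", "shuffle_null")

__all__ = ["ScenarioConfig", "MetricsReport", "RunManifest", "run_scenario", "run_grid", "load_grid_config"]


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the sensitivity grid."""

    name: str = "primary"
    inclusion: InclusionSpec = field(default_factory=InclusionSpec)
    scoring: str = "primary_zero_fill"
    outcome: OutcomeSpec = field(default_factory=OutcomeSpec)
    n_reps: int = 100
    seed: int = 0
    scoring_age: int = 3

    def __post_init__(self) -> None:
        if self.scoring not in SCORING_STRATEGIES:
            raise ValueError(f"unknown scoring strategy {self.scoring!r}")
        if self.scoring in ("impute_random", "shuffle_null") and self.n_reps < 2:
            raise ValueError(f"{self.scoring} requires n_reps >= 2")

    @classmethod
    def from_dict(cls, d: Mapping, seed: int = 0) -> "ScenarioConfig":
        return cls(
            name=d.get("name", d.get("outcome", "scenario")),
            inclusion=InclusionSpec(d.get("inclusion", "primary_wheeze_or_cough")),
            scoring=d.get("scoring", "primary_zero_fill"),
            outcome=OutcomeSpec(
                d.get("outcome", "primary_wheeze_and_drugs_8y"),
                same_wave=bool(d.get("same_wave", True)),
            ),
            n_reps=int(d.get("n_reps", 100)),
            seed=int(d.get("seed", seed)),
            scoring_age=int(d.get("scoring_age", 3)),
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "inclusion": self.inclusion.name,
            "scoring": self.scoring,
            "outcome": self.outcome.name,
            "n_reps": self.n_reps,
            "seed": self.seed,
            "scoring_age": self.scoring_age,
        }


@dataclass
class MetricsReport:
    """One scenario's row: denominator, discrimination and performance."""

    scenario: str
    inclusion: str
    scoring: str
    outcome: str
    n: int
    cases: int
    auc: float = float("nan")
    auc_ci: tuple[float, float] = (float("nan"), float("nan"))
    r2: float = float("nan")
    brier: float = float("nan")
    odds_ratio: float = float("nan")
    or_ci: tuple[float, float] = (float("nan"), float("nan"))
    flags: tuple[str, ...] = ()
    n_reps: int = 1
    threshold_table: list[dict] = field(default_factory=list)
    calibration: list[dict] = field(default_factory=list)
    exclusions: dict[str, int] = field(default_factory=dict)

    @property
    def case_pct(self) -> float:
        return 100.0 * self.cases / self.n if self.n else float("nan")

    def to_row(self) -> dict:
        def sig(x):
            return float(f"{x:.6g}") if np.isfinite(x) else ""
        return {
            "scenario": self.scenario,
            "inclusion": self.inclusion,
            "scoring": self.scoring,
            "outcome": self.outcome,
            "n": self.n,
            "cases": self.cases,
            "case_pct": sig(self.case_pct),
            "auc": sig(self.auc),
            "auc_lo": sig(self.auc_ci[0]),
            "auc_hi": sig(self.auc_ci[1]),
            "nagelkerke_r2": sig(self.r2),
            "scaled_brier": sig(self.brier),
            "odds_ratio": sig(self.odds_ratio),
            "or_lo": sig(self.or_ci[0]),
            "or_hi": sig(self.or_ci[1]),
            "flags": ";".join(self.flags),
        }


@dataclass
class RunManifest:
    """Provenance of one grid run."""

    config_hash: str
    seed: int
    version: str
    scenarios: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "scenarios": self.scenarios,
        }


def _base_scores(
    cohort: Sequence[ParticipantRecord],
    config: ScenarioConfig,
    definition,
    mappings,
) -> tuple[list, list[int]]:
    """Translate and score each child under zero-fill (optionally after
    complementing from earlier waves). Returns (responses per child, scores)."""
    responses_list = []
    scores = []
    for rec in cohort:
        wave = rec.wave(config.scoring_age)
        raw = {"sex": rec.sex or "", "age": str(config.scoring_age)}
        if wave is not None:
            raw.update(wave.answers)
        responses = translate_responses(raw, mappings, definition)
        if config.scoring == "complement_earlier":
            responses = complement_from_earlier(rec, responses, scoring_age=config.scoring_age)
        responses_list.append(responses)
        scores.append(compute_score(responses, definition, missing_policy="zero_fill"))
    return responses_list, scores


def _single_metrics(scores: np.ndarray, outcomes: np.ndarray, report: MetricsReport) -> None:
    fit = fit_logistic(scores, outcomes)
    a, ci = auc(scores, outcomes)
    report.auc, report.auc_ci = a, ci
    report.r2 = nagelkerke_r2(fit)
    report.brier = scaled_brier(fit.predict(scores), outcomes)
    if fit.separated:
        report.flags += ("separated",)
    else:
        report.odds_ratio, report.or_ci = odds_ratio_per_point(fit)
    lo, hi = int(scores.min()), int(scores.max())
    report.threshold_table = [
        threshold_metrics(scores, outcomes, fit, cutoff=c).as_dict() for c in range(lo, hi + 1)
    ]
    if scores.size >= 8:
        report.calibration = [
            {
                "group": g.group, "n": g.n, "events": g.events,
                "mean_predicted": g.mean_predicted,
                "observed_frequency": g.observed_frequency,
                "ci_low": g.ci_low, "ci_high": g.ci_high,
            }
            for g in calibration_table(fit.predict(scores), outcomes)
        ]


def _replicate_metrics(
    score_reps: Iterable[np.ndarray], outcomes: np.ndarray, report: MetricsReport
) -> None:
    """Per-replicate metrics pooled with Rubin's rules (log-OR pooled on the
    log scale; AUC with its DeLong variance)."""
    auc_reps, logor_reps, r2_reps, brier_reps = [], [], [], []
    for s in score_reps:
        s = np.asarray(s, dtype=float)
        a, v = auc_variance_delong(s, outcomes)
        auc_reps.append((a, v))
        fit = fit_logistic(s, outcomes)
        if not fit.separated:
            logor_reps.append((fit.slope, fit.cov[1, 1]))
        r2_reps.append(nagelkerke_r2(fit))
        brier_reps.append(scaled_brier(fit.predict(s), outcomes))
    pooled_auc = pool_estimates(auc_reps)
    report.auc = pooled_auc.estimate
    report.auc_ci = (max(0.0, pooled_auc.ci_low), min(1.0, pooled_auc.ci_high))
    if len(logor_reps) >= 2:
        pooled_or = pool_estimates(logor_reps)
        report.odds_ratio = float(np.exp(pooled_or.estimate))
        report.or_ci = (float(np.exp(pooled_or.ci_low)), float(np.exp(pooled_or.ci_high)))
    else:
        report.flags += ("separated",)
    report.r2 = float(np.mean(r2_reps))
    report.brier = float(np.mean(brier_reps))


def run_scenario(
    cohort: Sequence[ParticipantRecord],
    config: ScenarioConfig,
    definition=None,
    mappings=None,
    freqs=None,
) -> MetricsReport:
    """Run one scenario end to end; pure function of (cohort, config)."""
    definition = definition or default_score_definition()
    mappings = mappings or default_mas_mapping()

    analysed, excl_log = exclude_missing(cohort, scoring_age=config.scoring_age)
    included, incl_log = apply_inclusion(analysed, config.inclusion, scoring_age=config.scoring_age)
    logger.info(
        "scenario %s: %d records, %d after exclusion, %d included",
        config.name, len(cohort), len(analysed), len(included),
    )

    outcome_pairs = [
        (rec, evaluate_outcome(rec, config.outcome)) for rec in included
    ]
    denominated = [(rec, y) for rec, y in outcome_pairs if y is not None]
    report = MetricsReport(
        scenario=config.name,
        inclusion=config.inclusion.name,
        scoring=config.scoring,
        outcome=config.outcome.name,
        n=len(denominated),
        cases=sum(1 for _, y in denominated if y),
        exclusions={**excl_log, **incl_log,
                    "outcome_unobserved": len(outcome_pairs) - len(denominated)},
    )
    if not denominated:
        report.flags += ("empty_analysis_set",)
        logger.warning("scenario %s skipped: empty analysis set", config.name)
        return report
    if report.cases in (0, report.n):
        report.flags += ("single_class_outcome",)
        logger.warning("scenario %s: single-class outcome, metrics suppressed", config.name)
        return report

    denominated_records = [rec for rec, _ in denominated]
    outcomes = np.array([1 if y else 0 for _, y in denominated])
    responses_list, base_scores = _base_scores(denominated_records, config, definition, mappings)
    base_scores = np.asarray(base_scores, dtype=float)

    if config.scoring in ("primary_zero_fill", "complement_earlier"):
        report.n_reps = 1
        _single_metrics(base_scores, outcomes, report)
    elif config.scoring == "impute_random":
        freqs = freqs or default_reference_frequencies()
        reps = impute_random(
            responses_list, freqs, default_impute_targets(),
            n_reps=config.n_reps, seed=config.seed,
        )
        score_reps = [
            np.array([compute_score(r, definition, "zero_fill") for r in rep], dtype=float)
            for rep in reps.replicates
        ]
        report.n_reps = config.n_reps
        _replicate_metrics(score_reps, outcomes, report)
    else:  # shuffle_null
        reps = shuffle_scores(base_scores, n_reps=config.n_reps, seed=config.seed)
        report.n_reps = config.n_reps
        _replicate_metrics(reps.replicates, outcomes, report)
    return report


def load_grid_config(path=None, seed: int = 0) -> list[ScenarioConfig]:
    """Load a scenario grid from JSON/YAML; default is the packaged 16-row grid."""
    if path is None:
        from importlib import resources

        with resources.files("asthmapred.data").joinpath("default_grid.json").open() as fh:
            raw = json.load(fh)
    else:
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
    try:
        return [ScenarioConfig.from_dict(d, seed=seed) for d in raw["scenarios"]]
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"invalid grid config {path or '<packaged default>'}: {exc}") from exc


def run_grid(
    cohort: Sequence[ParticipantRecord],
    configs: Sequence[ScenarioConfig],
    out_dir=None,
    seed: int = 0,
) -> tuple[pd.DataFrame, RunManifest]:
    """Run every scenario, isolating per-scenario failures.

    Returns the grid table (one row per scenario) and a manifest; when
    ``out_dir`` is given, writes ``grid.csv``, per-scenario ROC and
    calibration CSVs, and ``manifest.json``.
    """
    config_json = json.dumps([c.to_dict() for c in configs], sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(config_json.encode()).hexdigest(),
        seed=seed,
        version=__version__,
    )
    rows = []
    reports = []
    for config in configs:
        try:
            report = run_scenario(cohort, config)
        except Exception as exc:  # noqa: BLE001 - per-scenario isolation is the contract
            logger.error("scenario %s failed: %s", config.name, exc)
            manifest.scenarios.append({"name": config.name, "error": str(exc)})
            continue
        reports.append(report)
        rows.append(report.to_row())
        manifest.scenarios.append(
            {
                "name": config.name,
                "n": report.n,
                "cases": report.cases,
                "n_reps": report.n_reps,
                "exclusions": report.exclusions,
                "flags": list(report.flags),
            }
        )
    grid = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        grid.to_csv(out_dir / "grid.csv", index=False, lineterminator="\n")
        for report in reports:
            if report.threshold_table:
                roc = pd.DataFrame(report.threshold_table)
                roc["fpr"] = 1 - roc["specificity"]
                roc.to_csv(out_dir / f"roc_{report.scenario}.csv", index=False,
                           float_format="%.6g", lineterminator="\n")
            if report.calibration:
                pd.DataFrame(report.calibration).to_csv(
                    out_dir / f"calibration_{report.scenario}.csv", index=False,
                    float_format="%.6g", lineterminator="\n")
        (out_dir / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=2) + "\n")
    return grid, manifest
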
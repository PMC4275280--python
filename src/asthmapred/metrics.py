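"""Discrimination, performance and calibration metrics for score validation.

The statistical core: a univariate logistic model of outcome on score,
threshold diagnostics (sensitivity, specificity, predictive values,
likelihood ratios), the c statistic with a DeLong (or bootstrap) confidence
interval, Nagelkerke's maximum-rescaled R², the maximum-rescaled Brier
score, grouped calibration with exact binomial intervals, and recovery of a
score distribution from tabulated sensitivity/specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import expit, logit

__all__ = [
    "LogisticFit",
    "ThresholdMetrics",
    "CalibrationGroup",
    "fit_logistic",
    "odds_ratio_per_point",
    "threshold_metrics",
    "auc",
    "auc_variance_delong",
    "nagelkerke_r2",
    "scaled_brier",
    "calibration_table",
    "recover_distribution_from_sens_spec",
    "bootstrap_proportion_ci",
]

_Z95 = 1.959963984540054  # Phi^{-1}(0.975)
SEPARATION_SLOPE = 15.0


class SingleClassError(ValueError):
    """Outcome vector contains only one class."""


class SeparationError(ValueError):
    """Fit is (quasi-)separated; the requested quantity is unreliable."""


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood fit of logit P(Y=1) = intercept + slope * score."""

    intercept: float
    slope: float
    log_likelihood: float
    null_log_likelihood: float
    n: int
    cov: np.ndarray  # 2x2 covariance of (intercept, slope)
    converged: bool
    separated: bool

    @property
    def slope_se(self) -> float:
        return float(np.sqrt(self.cov[1, 1]))

    def predict(self, scores) -> np.ndarray:
        return expit(self.intercept + self.slope * np.asarray(scores, dtype=float))


def _neg_ll(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ beta
    # numerically stable log-likelihood
    return float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)


def fit_logistic(scores: Sequence[float], outcomes: Sequence[int]) -> LogisticFit:
    """Newton (iteratively reweighted least squares) logistic fit.

    Converges when the largest coefficient change drops below 1e-8 or after
    50 iterations; fits with |slope| above 15 are flagged as separated and
    their confidence intervals suppressed downstream. Degenerate designs
    with constant score collapse to the intercept-only model.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and outcomes must be 1-d vectors of equal length")
    n = s.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcomes must be binary 0/1")
    k = y.sum()
    if k == 0 or k == n:
        raise SingleClassError("outcome has a single class; logistic fit undefined")

    p0 = k / n
    null_ll = float(k * np.log(p0) + (n - k) * np.log(1 - p0))

    if np.ptp(s) == 0:
        cov = np.full((2, 2), np.nan)
        cov[0, 0] = 1.0 / (n * p0 * (1 - p0))
        return LogisticFit(
            intercept=float(logit(p0)), slope=0.0,
            log_likelihood=null_ll, null_log_likelihood=null_ll,
            n=n, cov=cov, converged=True, separated=False,
        )

    X = np.column_stack([np.ones(n), s])
    beta = np.array([logit(p0), 0.0])
    converged = False
    for _ in range(50):
        p = expit(X @ beta)
        W = p * (1 - p)
        info = X.T @ (X * W[:, None])
        grad = X.T @ (y - p)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            # weights collapse under (quasi-)separation; keep the last iterate
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            converged = True
            break
        if abs(beta[1]) > 2 * SEPARATION_SLOPE:
            break  # diverging toward separation
    p = expit(X @ beta)
    W = p * (1 - p)
    info = X.T @ (X * W[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    ll = -_neg_ll(beta, X, y)
    # non-convergence at the iteration cap is itself a separation symptom
    # (the slope drifts without bound while the information matrix collapses)
    separated = abs(beta[1]) > SEPARATION_SLOPE or not converged
    return LogisticFit(
        intercept=float(beta[0]), slope=float(beta[1]),
        log_likelihood=ll, null_log_likelihood=null_ll,
        n=n, cov=cov, converged=converged, separated=separated,
    )


def odds_ratio_per_point(fit: LogisticFit) -> tuple[float, tuple[float, float]]:
    """Odds ratio per one-point score increase with its 95% Wald interval."""
    if fit.separated:
        raise SeparationError("separated fit: suppress the odds ratio instead of reporting it")
    se = fit.slope_se
    return float(np.exp(fit.slope)), (
        float(np.exp(fit.slope - _Z95 * se)),
        float(np.exp(fit.slope + _Z95 * se)),
    )


@dataclass(frozen=True)
class ThresholdMetrics:
    """Diagnostic performance of the rule 'test positive iff score >= cutoff'."""

    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    lr_plus: float
    lr_minus: float
    predicted_probability: float
    tp: int
    fp: int
    tn: int
    fn: int

    def as_dict(self) -> dict:
        return {
            "cutoff": self.cutoff, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "ppv": self.ppv, "npv": self.npv,
            "lr_plus": self.lr_plus, "lr_minus": self.lr_minus,
            "predicted_probability": self.predicted_probability,
        }


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def threshold_metrics(
    scores: Sequence[float],
    outcomes: Sequence[int],
    fit: LogisticFit | None = None,
    cutoff: float = 5,
    mode: str = "raw_counts",
) -> ThresholdMetrics:
    """Sensitivity/specificity/PPV/NPV/likelihood ratios at one cutoff.

    ``raw_counts`` cross-tabulates the observed scores; ``model_based``
    replaces each child's positivity by the fitted probability of scoring at
    or above the cutoff given the model (expected counts). Undefined
    measures (empty margins) come back as NaN, never as exceptions.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if mode not in ("raw_counts", "model_based"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "model_based":
        if fit is None:
            raise ValueError("model_based mode requires a fit")
        p = fit.predict(s)
        pos = s >= cutoff
        tp = float(p[pos].sum()); fp = float((1 - p[pos]).sum())
        fn = float(p[~pos].sum()); tn = float((1 - p[~pos]).sum())
    else:
        pos = s >= cutoff
        tp = int(np.sum(pos & (y == 1))); fp = int(np.sum(pos & (y == 0)))
        fn = int(np.sum(~pos & (y == 1))); tn = int(np.sum(~pos & (y == 0)))
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    lr_plus = _ratio(sens, 1 - spec) if spec < 1 else float("nan")
    lr_minus = _ratio(1 - sens, spec) if spec > 0 else float("nan")
    pred = float(fit.predict(cutoff)) if fit is not None else float("nan")
    return ThresholdMetrics(
        cutoff=cutoff, sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        lr_plus=lr_plus, lr_minus=lr_minus, predicted_probability=pred,
        tp=int(round(tp)), fp=int(round(fp)), tn=int(round(tn)), fn=int(round(fn)),
    )


def _placements(cases: np.ndarray, controls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-rank placement values used by the DeLong construction."""
    m, n = cases.size, controls.size
    both = np.concatenate([cases, controls])
    ranks = stats.rankdata(both)  # mid-ranks handle ties as 1/2
    r_cases = ranks[:m]
    r_controls = ranks[m:]
    v10 = (r_cases - stats.rankdata(cases)) / n
    v01 = 1.0 - (r_controls - stats.rankdata(controls)) / m
    return v10, v01


def auc_variance_delong(scores: Sequence[float], outcomes: Sequence[int]) -> tuple[float, float]:
    """(AUC, DeLong variance) for one score vector."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    cases, controls = s[y == 1], s[y == 0]
    if cases.size == 0 or controls.size == 0:
        raise SingleClassError("AUC requires both outcome classes")
    v10, v01 = _placements(cases, controls)
    a = float(v10.mean())
    s10 = v10.var(ddof=1) if cases.size > 1 else 0.0
    s01 = v01.var(ddof=1) if controls.size > 1 else 0.0
    return a, float(s10 / cases.size + s01 / controls.size)


def auc(
    scores: Sequence[float],
    outcomes: Sequence[int],
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Mann–Whitney concordance (ties count 1/2) with a 95% CI.

    ``ci_method='delong'`` uses the asymptotic placement-value variance;
    ``'bootstrap'`` uses stratified percentile resampling.
    """
    a, var = auc_variance_delong(scores, outcomes)
    if ci_method == "delong":
        half = _Z95 * np.sqrt(var)
        return a, (max(0.0, a - half), min(1.0, a + half))
    if ci_method != "bootstrap":
        raise ValueError(f"unknown ci_method {ci_method!r}")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    cases, controls = s[y == 1], s[y == 0]
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        cs = rng.choice(cases, cases.size, replace=True)
        ct = rng.choice(controls, controls.size, replace=True)
        boots[b], _ = auc_variance_delong(
            np.concatenate([cs, ct]),
            np.concatenate([np.ones(cs.size, int), np.zeros(ct.size, int)]),
        )
    lo, hi = np.quantile(boots, [0.025, 0.975])
    return a, (float(lo), float(hi))


def nagelkerke_r2(fit: LogisticFit) -> float:
    """Cox–Snell R² rescaled by its maximum attainable value (0..1)."""
    if fit.log_likelihood < fit.null_log_likelihood - 1e-6:
        raise ValueError("fitted log-likelihood below the null; inconsistent fit")
    n = fit.n
    cs = 1.0 - np.exp((2.0 / n) * (fit.null_log_likelihood - fit.log_likelihood))
    cs_max = 1.0 - np.exp((2.0 / n) * fit.null_log_likelihood)
    return float(min(1.0, max(0.0, cs / cs_max)))


def scaled_brier(probs: Sequence[float], outcomes: Sequence[int]) -> float:
    """Brier score rescaled against the prevalence-only prediction.

    0 means the predictions add nothing to the a-priori prevalence; 1 means
    perfect prediction. NaN when the prevalence is degenerate (0 or 1)."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0,1]")
    prev = y.mean()
    if prev in (0.0, 1.0):
        return float("nan")
    brier = float(np.mean((p - y) ** 2))
    return 1.0 - brier / (prev * (1 - prev))


@dataclass(frozen=True)
class CalibrationGroup:
    group: int
    n: int
    events: int
    mean_predicted: float
    observed_frequency: float
    ci_low: float
    ci_high: float


def _clopper_pearson(k: int, n: int) -> tuple[float, float]:
    lo = 0.0 if k == 0 else float(stats.beta.ppf(0.025, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(0.975, k + 1, n - k))
    return lo, hi


def calibration_table(
    probs: Sequence[float],
    outcomes: Sequence[int],
    n_groups: int = 8,
) -> list[CalibrationGroup]:
    """Grouped calibration: sort by predicted probability (stable), split
    into ``n_groups`` nearly equal groups (remainder to the lowest-index
    groups), and report observed event frequency with exact 95%
    Clopper–Pearson intervals from beta quantiles."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    n = p.size
    if n < n_groups:
        raise ValueError(f"need at least {n_groups} observations")
    order = np.argsort(p, kind="stable")
    base, rem = divmod(n, n_groups)
    sizes = [base + 1 if g < rem else base for g in range(n_groups)]
    groups = []
    start = 0
    for g, size in enumerate(sizes):
        idx = order[start:start + size]
        start += size
        events = int(y[idx].sum())
        lo, hi = _clopper_pearson(events, size)
        groups.append(
            CalibrationGroup(
                group=g + 1, n=size, events=events,
                mean_predicted=float(p[idx].mean()),
                observed_frequency=events / size,
                ci_low=lo, ci_high=hi,
            )
        )
    return groups


def recover_distribution_from_sens_spec(
    sens_by_cutoff: Sequence[float],
    spec_by_cutoff: Sequence[float],
    prevalence: float,
    cutoffs: Sequence[int] | None = None,
) -> dict[int, float]:
    """Recover the marginal score distribution implied by a published
    sensitivity/specificity table.

    With test-positivity defined as score >= c, P(S >= c) equals
    ``prev * sens(c) + (1 - prev) * (1 - spec(c))``; differencing the tail
    over consecutive integer cutoffs yields the per-score masses (the mass
    below the lowest cutoff absorbs the remainder). Masses within -1e-9 of
    zero are clipped to 0."""
    sens = np.asarray(sens_by_cutoff, dtype=float)
    spec = np.asarray(spec_by_cutoff, dtype=float)
    if sens.shape != spec.shape or sens.ndim != 1 or sens.size == 0:
        raise ValueError("sens and spec must be equal-length non-empty vectors")
    if not 0 <= prevalence <= 1:
        raise ValueError("prevalence must lie in [0,1]")
    if np.any(np.diff(sens) > 1e-12):
        raise ValueError("sensitivity must be non-increasing in the cutoff")
    if np.any(np.diff(spec) < -1e-12):
        raise ValueError("specificity must be non-decreasing in the cutoff")
    if cutoffs is None:
        cutoffs = list(range(1, sens.size + 1))
    cutoffs = [int(c) for c in cutoffs]
    if any(b - a != 1 for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be consecutive integers")

    tail = prevalence * sens + (1 - prevalence) * (1 - spec)
    masses: dict[int, float] = {}
    lowest = cutoffs[0] - 1
    masses[lowest] = 1.0 - tail[0]
    for i, c in enumerate(cutoffs):
        nxt = tail[i + 1] if i + 1 < len(cutoffs) else 0.0
        masses[c] = tail[i] - nxt
    for k, v in masses.items():
        if v < -1e-9:
            raise ValueError(f"negative mass {v} at score {k}; inputs inconsistent")
        masses[k] = max(0.0, v)
    total = sum(masses.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"recovered masses sum to {total}, not 1")
    return masses


def bootstrap_proportion_ci(
    successes: int,
    n: int,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap 95% CI of a binomial proportion."""
    if n == 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in 0..n")
    rng = np.random.default_rng(seed)
    draws = rng.binomial(n, successes / n, size=n_boot) / n
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return float(lo), float(hi)
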
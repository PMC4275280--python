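"""Scoring-data strategies for incompletely observed questionnaires.

Three strategies are supported besides the baseline zero-fill: complementing
eczema and parental history from earlier follow-ups and baseline, random
imputation of structurally missing answers from development-cohort answer
frequencies, and a permutation null that reshuffles observed total scores
between children. Replicated strategies pool estimates with Rubin's rules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort import ParticipantRecord
from .score import ItemResponseSet, normalize_code

__all__ = [
    "ReferenceFrequencies",
    "ImputeTarget",
    "ReplicateSet",
    "PooledEstimate",
    "default_reference_frequencies",
    "default_impute_targets",
    "complement_from_earlier",
    "impute_random",
    "shuffle_scores",
    "pool_estimates",
]


@dataclass(frozen=True)
class ReferenceFrequencies:
    """Answer-category probabilities per item, used as the imputation source.

    Keys are item ids as strings; the additive parental item is stored as
    two independent sub-flag margins (``10.mother``, ``10.father``) so each
    entry is a proper probability distribution.
    """

    frequencies: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        for key, dist in self.frequencies.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequencies for {key!r} sum to {total}, not 1")
            if any(p < 0 for p in dist.values()):
                raise ValueError(f"negative probability under {key!r}")

    def distribution(self, key: str) -> dict[str, float]:
        if key not in self.frequencies:
            raise KeyError(f"no reference frequencies for {key!r}")
        return dict(self.frequencies[key])


def default_reference_frequencies() -> ReferenceFrequencies:
    """Development-cohort answer frequencies of the ten scoring questions."""
    with resources.files("asthmapred.data").joinpath("leicester_frequencies.json").open() as fh:
        raw = json.load(fh)["frequencies"]
    freqs = {
        key: {normalize_code(c): float(p) for c, p in dist.items()}
        for key, dist in raw.items()
    }
    return ReferenceFrequencies(freqs)


@dataclass(frozen=True)
class ImputeTarget:
    """One imputation instruction.

    ``fill_missing`` draws an answer for children lacking the item entirely
    (the validation cohort never asked item 8). ``reallocate`` redistributes
    children currently at ``from_code`` among ``categories`` with
    probabilities proportional to the reference frequencies — used for
    item 6, whose most severe answer category was never offered in the
    validation interview.
    """

    item_id: int
    mode: str = "fill_missing"  # or "reallocate"
    categories: tuple[str, ...] | None = None
    from_code: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("fill_missing", "reallocate"):
            raise ValueError(f"unknown impute mode {self.mode!r}")
        if self.mode == "reallocate" and (self.from_code is None or not self.categories):
            raise ValueError("reallocate target needs from_code and categories")


def default_impute_targets() -> list[ImputeTarget]:
    return [
        ImputeTarget(item_id=8, mode="fill_missing"),
        ImputeTarget(item_id=6, mode="reallocate", from_code="sometimes",
                     categories=("sometimes", "always")),
    ]


@dataclass
class ReplicateSet:
    """Reproducible bundle of replicated datasets or score vectors.

    Replicate ``r`` is regenerated from the derived stream ``(seed, r)``, so
    individual replicates are independently reproducible.
    """

    n_reps: int
    seed: int
    replicates: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2 for variance pooling")


def _restricted(dist: Mapping[str, float], categories: Sequence[str] | None) -> tuple[list[str], np.ndarray]:
    if categories is None:
        codes = list(dist)
    else:
        codes = [c for c in categories if c in dist]
        if not codes:
            raise KeyError(f"none of {categories} present in reference frequencies")
    probs = np.array([dist[c] for c in codes], dtype=float)
    total = probs.sum()
    if total <= 0:
        raise ValueError("restricted categories carry zero total probability")
    return codes, probs / total


def complement_from_earlier(
    record: ParticipantRecord,
    responses: Mapping[int, str],
    scoring_age: int = 3,
    item_ids: Iterable[int] = (9, 10),
) -> ItemResponseSet:
    """Upgrade eczema and parental-history answers using earlier waves.

    The scoring interview asks about the last 12 months only; item 9 is
    meant as "eczema ever" and item 10 as parental asthma "ever", so a yes
    at any earlier follow-up (or the baseline parental history) upgrades the
    answer. A later "no" never overwrites an earlier "yes"."""
    out = ItemResponseSet(responses)
    item_ids = set(item_ids)
    if 9 in item_ids:
        ever = any(
            record.answer_at(a, "eczema_12m") == "yes"
            for a in record.waves
            if a <= scoring_age
        )
        if ever:
            out[9] = "yes"
    if 10 in item_ids:
        flags = set()
        current = out.get(10)
        if current and current != "none":
            flags.update(current.split("+"))
        if record.baseline_flag("mother_asthma_ever"):
            flags.add("mother")
        if record.baseline_flag("father_asthma_ever"):
            flags.add("father")
        for a in record.waves:
            if a <= scoring_age:
                if record.answer_at(a, "mother_asthma_12m") == "yes":
                    flags.add("mother")
                if record.answer_at(a, "father_asthma_12m") == "yes":
                    flags.add("father")
        if flags or current is not None:
            out[10] = "+".join(c for c in ("mother", "father") if c in flags) or "none"
    return out


def _freq_key(item_id: int, subflag: str | None = None) -> str:
    return f"{item_id}.{subflag}" if subflag else str(item_id)


def impute_random(
    responses_list: Sequence[Mapping[int, str]],
    freqs: ReferenceFrequencies | None = None,
    targets: Sequence[ImputeTarget] | None = None,
    n_reps: int = 100,
    seed: int = 0,
) -> ReplicateSet:
    """Draw ``n_reps`` completed response sets per child.

    Each replicate draws independently per child from the reference
    frequencies restricted to the target categories; answers outside the
    target list are never touched. Raises ``KeyError`` when a target item
    has no frequency entry.
    """
    freqs = freqs or default_reference_frequencies()
    targets = default_impute_targets() if targets is None else list(targets)
    # validate configuration up front
    prepared = []
    for t in targets:
        if t.item_id == 10 and t.mode == "fill_missing":
            prepared.append((t, [( "mother", *_restricted(freqs.distribution(_freq_key(10, "mother")), None)),
                                 ("father", *_restricted(freqs.distribution(_freq_key(10, "father")), None))]))
        else:
            dist = freqs.distribution(_freq_key(t.item_id))
            prepared.append((t, _restricted(dist, t.categories)))

    replicates = []
    for r in range(n_reps):
        rng = np.random.default_rng([seed, r])
        rep = []
        for responses in responses_list:
            completed = ItemResponseSet(responses)
            for t, spec in prepared:
                if t.item_id == 10 and t.mode == "fill_missing":
                    if 10 in completed:
                        continue
                    flags = []
                    for subflag, codes, probs in spec:
                        draw = codes[rng.choice(len(codes), p=probs)]
                        if draw == "yes":
                            flags.append(subflag)
                    completed[10] = "+".join(flags) or "none"
                    continue
                codes, probs = spec
                if t.mode == "fill_missing":
                    if t.item_id not in completed:
                        completed[t.item_id] = codes[rng.choice(len(codes), p=probs)]
                elif completed.get(t.item_id) == t.from_code:
                    completed[t.item_id] = codes[rng.choice(len(codes), p=probs)]
            rep.append(completed)
        replicates.append(rep)
    return ReplicateSet(n_reps=n_reps, seed=seed, replicates=replicates)


def shuffle_scores(scores: Sequence[int], n_reps: int = 100, seed: int = 0) -> ReplicateSet:
    """Permutation null: each replicate is a uniformly random rearrangement
    of the observed total scores between children (multiset invariant)."""
    scores = np.asarray(scores)
    if scores.size < 2:
        raise ValueError("need at least 2 scores to shuffle")
    replicates = [
        np.random.default_rng([seed, r]).permutation(scores) for r in range(n_reps)
    ]
    return ReplicateSet(n_reps=n_reps, seed=seed, replicates=replicates)


@dataclass(frozen=True)
class PooledEstimate:
    estimate: float
    variance: float
    ci_low: float
    ci_high: float
    within_variance: float
    between_variance: float
    n_reps: int


def pool_estimates(per_rep: Sequence[tuple[float, float]]) -> PooledEstimate:
    """Rubin's rules: pooled estimate is the replicate mean; total variance
    is the mean within-replicate variance plus ``(1 + 1/m)`` times the
    between-replicate variance; the 95% CI is normal-based."""
    if len(per_rep) < 2:
        raise ValueError("need >= 2 replicates to pool")
    est = np.array([e for e, _ in per_rep], dtype=float)
    var = np.array([v for _, v in per_rep], dtype=float)
    bad = np.flatnonzero(~(np.isfinite(est) & np.isfinite(var)))
    if bad.size:
        raise ValueError(f"non-finite estimate/variance in replicate(s) {bad.tolist()}")
    m = len(per_rep)
    qbar = est.mean()
    within = var.mean()
    between = est.var(ddof=1)
    total = within + (1 + 1 / m) * between
    half = 1.96 * np.sqrt(total)
    return PooledEstimate(
        estimate=float(qbar),
        variance=float(total),
        ci_low=float(qbar - half),
        ci_high=float(qbar + half),
        within_variance=float(within),
        between_variance=float(between),
        n_reps=m,
    )
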
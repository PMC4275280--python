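"""The 10-item asthma prediction score: items, weights, dialect mapping, risk groups.

The score assigns integer points to ten questionnaire items asked around age
2-3 years (sex, age, four wheeze-severity items, two trigger items, eczema,
parental asthma history) and sums them to 0-15. High scores indicate high
risk of school-age asthma. Validation cohorts answer the questions in their
own "dialect"; an :class:`ItemMapping` translates cohort answers into the
score's canonical answer codes, possibly negating a question or declaring an
item unavailable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "ScoreItem",
    "ScoreDefinition",
    "ItemMapping",
    "ItemResponseSet",
    "normalize_code",
    "default_score_definition",
    "default_mas_mapping",
    "load_score_definition",
    "load_mappings",
    "translate_responses",
    "compute_score",
    "risk_group",
]

COMPARABILITY_LEVELS = ("perfect", "very_good", "good", "moderate", "absent")


def normalize_code(value: str) -> str:
    """Canonical answer-code form: trimmed, lower-case, apostrophes dropped,
    internal whitespace collapsed to underscores."""
    return "_".join(str(value).replace("'", "").strip().lower().split())


@dataclass(frozen=True)
class ScoreItem:
    """One scored question: ordered answer categories with point values.

    ``additive`` items (parental history) are answered by a set of sub-flags
    whose points add up, e.g. ``mother+father`` scores 2.
    """

    item_id: int
    label: str
    categories: tuple[tuple[str, int], ...]
    additive: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.item_id <= 10:
            raise ValueError(f"item_id must be 1..10, got {self.item_id}")
        pts = dict(self.categories)
        if any(p < 0 or int(p) != p for p in pts.values()):
            raise ValueError(f"item {self.item_id}: points must be non-negative integers")
        if min(pts.values()) != 0:
            raise ValueError(f"item {self.item_id}: at least one category must score 0")

    @property
    def points(self) -> dict[str, int]:
        return dict(self.categories)

    @property
    def max_points(self) -> int:
        if self.additive:
            return sum(p for _, p in self.categories)
        return max(p for _, p in self.categories)

    def score_answer(self, code: str) -> int:
        """Points for one answer code; additive items accept '+'-joined sub-flags."""
        pts = self.points
        if self.additive:
            total = 0
            for part in code.split("+"):
                if part not in pts:
                    raise KeyError(f"item {self.item_id}: unknown sub-flag {part!r}")
                total += pts[part]
            return total
        if code not in pts:
            raise KeyError(f"item {self.item_id}: unknown answer code {code!r}")
        return pts[code]


@dataclass(frozen=True)
class ScoreDefinition:
    """The full instrument: ten items plus the risk-band cut points."""

    items: tuple[ScoreItem, ...]
    low_cut: int = 5
    high_cut: int = 10

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if sorted(ids) != list(range(1, 11)):
            raise ValueError(f"expected items 1..10 exactly once, got {sorted(ids)}")
        if not 0 < self.low_cut < self.high_cut <= self.max_score:
            raise ValueError("risk cuts must satisfy 0 < low < high <= max score")

    @property
    def max_score(self) -> int:
        return sum(it.max_points for it in self.items)

    def item(self, item_id: int) -> ScoreItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(f"no item {item_id}")

    def to_dict(self) -> dict:
        return {
            "items": [
                {
                    "id": it.item_id,
                    "label": it.label,
                    **({"additive": True} if it.additive else {}),
                    "categories": [{"code": c, "points": p} for c, p in it.categories],
                }
                for it in self.items
            ],
            "cuts": {"low": self.low_cut, "high": self.high_cut},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoreDefinition":
        items = tuple(
            ScoreItem(
                item_id=int(spec["id"]),
                label=str(spec.get("label", f"item {spec['id']}")),
                categories=tuple(
                    (normalize_code(c["code"]), int(c["points"])) for c in spec["categories"]
                ),
                additive=bool(spec.get("additive", False)),
            )
            for spec in d["items"]
        )
        cuts = d.get("cuts", {})
        return cls(items=items, low_cut=int(cuts.get("low", 5)), high_cut=int(cuts.get("high", 10)))


@dataclass(frozen=True)
class ItemMapping:
    """Translation of one cohort question into a score item.

    ``source_variable`` is the cohort variable name (two comma-separated
    variables for the additive parental item); ``translation`` maps
    normalized cohort answers to score answer codes. ``comparability``
    records how faithful the translation is; ``absent`` means the cohort has
    no usable question and the item never receives a response.
    """

    item_id: int
    source_variable: str | None
    translation: Mapping[str, str]
    comparability: str = "good"

    def __post_init__(self) -> None:
        if self.comparability not in COMPARABILITY_LEVELS:
            raise ValueError(f"comparability must be one of {COMPARABILITY_LEVELS}")
        if self.comparability == "absent" and self.source_variable:
            raise ValueError("absent mapping must not name a source variable")

    @property
    def source_variables(self) -> tuple[str, ...]:
        if not self.source_variable:
            return ()
        return tuple(v.strip() for v in self.source_variable.split(","))


class ItemResponseSet(dict):
    """Per-child answers keyed by item id; items may be absent.

    A thin dict subclass (item_id -> answer_code) so responses behave like a
    mapping while carrying validation against a :class:`ScoreDefinition`.
    """

    def validate(self, definition: ScoreDefinition) -> None:
        for item_id, code in self.items():
            definition.item(item_id).score_answer(code)


def default_score_definition() -> ScoreDefinition:
    """The canonical 10-item instrument (weights as published; max score 15)."""
    with resources.files("asthmapred.data").joinpath("score_definition.json").open() as fh:
        return ScoreDefinition.from_dict(json.load(fh))


def load_score_definition(path) -> ScoreDefinition:
    with open(path) as fh:
        return ScoreDefinition.from_dict(json.load(fh))


def _mappings_from_dict(d: Mapping) -> list[ItemMapping]:
    out = []
    for m in d["mappings"]:
        out.append(
            ItemMapping(
                item_id=int(m["item_id"]),
                source_variable=m.get("source_variable"),
                translation={normalize_code(k) if ":" not in k else k.strip().lower(): normalize_code(v)
                             for k, v in m.get("translation", {}).items()},
                comparability=m.get("comparability", "good"),
            )
        )
    return out


def default_mas_mapping() -> list[ItemMapping]:
    """Mapping from the German birth-cohort 3-year interview dialect onto the
    score items (item 8 has no counterpart and is declared absent; item 3 is
    a negated question)."""
    with resources.files("asthmapred.data").joinpath("mas_mapping.json").open() as fh:
        return _mappings_from_dict(json.load(fh))


def load_mappings(path) -> list[ItemMapping]:
    with open(path) as fh:
        return _mappings_from_dict(json.load(fh))


class TranslationError(ValueError):
    """Raised when a cohort answer cannot be mapped onto a score category."""


def translate_responses(
    raw_record: Mapping[str, str],
    mappings: Iterable[ItemMapping],
    definition: ScoreDefinition | None = None,
) -> ItemResponseSet:
    """Translate one child's cohort answers into score answer codes.

    ``raw_record`` maps cohort variable names to raw answers (missing answers
    simply absent or empty). Items whose mapping is ``absent`` or whose
    source answer is missing carry no response. Unknown answers for a mapped
    item raise :class:`TranslationError` naming item and value.
    """
    definition = definition or default_score_definition()
    responses = ItemResponseSet()
    for mapping in mappings:
        if mapping.comparability == "absent":
            continue
        item = definition.item(mapping.item_id)
        if item.additive:
            flags: list[str] = []
            answered = False
            for var in mapping.source_variables:
                raw = raw_record.get(var)
                if raw is None or str(raw).strip() == "":
                    continue
                key = f"{var}:{normalize_code(raw)}"
                if key not in mapping.translation:
                    raise TranslationError(
                        f"item {mapping.item_id}: unmappable answer {raw!r} for {var!r}"
                    )
                answered = True
                code = mapping.translation[key]
                if code:
                    flags.append(code)
            if answered:
                # canonical sub-flag order follows the item definition
                order = [c for c, _ in item.categories]
                flags.sort(key=order.index)
                responses[mapping.item_id] = "+".join(flags) if flags else "none"
            continue
        (var,) = mapping.source_variables
        raw = raw_record.get(var)
        if raw is None or str(raw).strip() == "":
            continue
        norm = normalize_code(raw)
        if norm not in mapping.translation:
            raise TranslationError(
                f"item {mapping.item_id}: unmappable answer {raw!r} for {var!r}"
            )
        responses[mapping.item_id] = mapping.translation[norm]
    responses.validate(definition)
    return responses


class MissingItemError(ValueError):
    def __init__(self, item_ids):
        self.item_ids = sorted(item_ids)
        super().__init__(f"missing responses for items {self.item_ids}")


def compute_score(
    responses: Mapping[int, str],
    definition: ScoreDefinition | None = None,
    missing_policy: str = "zero_fill",
) -> int:
    """Total score of one response set.

    ``zero_fill`` lets absent items contribute their baseline of zero (the
    primary scoring rule); ``fail`` raises :class:`MissingItemError` listing
    the absent items.
    """
    definition = definition or default_score_definition()
    if missing_policy not in ("zero_fill", "fail"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    missing = [it.item_id for it in definition.items if it.item_id not in responses]
    if missing and missing_policy == "fail":
        raise MissingItemError(missing)
    total = 0
    for it in definition.items:
        code = responses.get(it.item_id)
        if code is not None:
            total += it.score_answer(code)
    return total


def risk_group(score: int, definition: ScoreDefinition | None = None) -> str:
    """Risk band for a score: 'low' (<= low cut), 'medium', or 'high' (>= high cut)."""
    definition = definition or default_score_definition()
    if not 0 <= score <= definition.max_score:
        raise ValueError(f"score {score} outside 0..{definition.max_score}")
    if score <= definition.low_cut:
        return "low"
    if score >= definition.high_cut:
        return "high"
    return "medium"
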
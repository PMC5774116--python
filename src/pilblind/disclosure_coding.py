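"""Rule-based coding of how a trial's information leaflet describes its placebo control.

Each placebo control group of a trial is one coding unit.  Free text
describing the control condition is classified into one of three
categories:

``FD``
    full disclosure — the text names the control with an explicit
    placebo/sham vocabulary, or a neutrally labelled control arm is
    *escalated* to FD because the text additionally describes a sham
    procedure (e.g. needling away from true points).
``DD``
    deceptive disclosure — the control arm is given only a neutral or
    deceitful label ("control group", "group one", ...).
``MI``
    missing information — nothing about a placebo control is described.

The matching engine, not the shipped lexicon, is the contract: rule sets
are plain token lists loadable from JSON/YAML and a default set is
packaged under ``pilblind/data/default_rules.json``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CATEGORIES",
    "REGIONS",
    "RuleConfigError",
    "RuleSet",
    "PilSnippet",
    "DisclosureRecord",
    "CategorySummary",
    "Chi2Result",
    "classify_disclosure",
    "summarize_categories",
    "chi_square_2x2",
    "round_half_up",
]

CATEGORIES = ("FD", "DD", "MI")
REGIONS = ("Asia", "non-Asia")

_RULE_TIERS = ("fd", "dd", "fd_escalation")

_NORM_RE = re.compile(r"[^a-z0-9]+")


class RuleConfigError(ValueError):
    """Raised for malformed rule-set configuration (e.g. unknown tier name)."""


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as tables conventionally print."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _normalize(text: str) -> str:
    """Lowercase and collapse all punctuation/whitespace runs to single spaces."""
    return _NORM_RE.sub(" ", text.lower()).strip()


@dataclass(frozen=True)
class RuleSet:
    """Three ordered tiers of whole-word, case-insensitive match tokens."""

    fd_tokens: tuple[str, ...]
    dd_tokens: tuple[str, ...]
    escalation_tokens: tuple[str, ...]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Sequence[str]]) -> "RuleSet":
        unknown = set(mapping) - set(_RULE_TIERS)
        if unknown:
            raise RuleConfigError(
                f"unknown rule tier(s) {sorted(unknown)}; expected {list(_RULE_TIERS)}"
            )
        missing = set(_RULE_TIERS) - set(mapping)
        if missing:
            raise RuleConfigError(f"missing rule tier(s) {sorted(missing)}")
        return cls(
            fd_tokens=tuple(mapping["fd"]),
            dd_tokens=tuple(mapping["dd"]),
            escalation_tokens=tuple(mapping["fd_escalation"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "RuleSet":
        """Load a rule set from a JSON or YAML file."""
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            mapping = yaml.safe_load(text)
        else:
            mapping = json.loads(text)
        if not isinstance(mapping, Mapping):
            raise RuleConfigError(f"rule file {path} must contain a mapping of tiers")
        return cls.from_mapping(mapping)

    @classmethod
    def default(cls) -> "RuleSet":
        with resources.files("pilblind.data").joinpath("default_rules.json").open(
            encoding="utf-8"
        ) as fh:
            return cls.from_mapping(json.load(fh))

    def _match(self, tokens: Iterable[str], norm_text: str) -> list[str]:
        padded = f" {norm_text} "
        return [tok for tok in tokens if f" {_normalize(tok)} " in padded]


@dataclass(frozen=True)
class PilSnippet:
    """Free text describing the control condition for one placebo group."""

    pil_id: str
    placebo_group_id: str
    text: str
    region: str = "non-Asia"

    def __post_init__(self) -> None:
        if not self.pil_id:
            raise ValueError("pil_id must be non-empty")
        if not self.placebo_group_id:
            raise ValueError("placebo_group_id must be non-empty")
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}, got {self.region!r}")


@dataclass(frozen=True)
class DisclosureRecord:
    placebo_group_id: str
    category: str
    matched_keywords: tuple[str, ...] = ()
    escalated: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}")
        if self.category == "MI" and self.matched_keywords:
            raise ValueError("MI records cannot carry matched keywords")
        if self.escalated and self.category != "FD":
            raise ValueError("escalated=True only valid for FD records")


def classify_disclosure(snippet: PilSnippet, rules: RuleSet | None = None) -> DisclosureRecord:
    """Classify one snippet into FD/DD/MI.

    Decision order: any FD token -> FD; else a DD token together with a
    sham-procedure escalation token -> FD (escalated); else DD token only
    -> DD; else MI.  A bare escalation token (sham procedure described
    without any labelled control arm) also yields escalated FD, since the
    text does disclose a sham procedure.
    """
    if rules is None:
        rules = RuleSet.default()
    norm = _normalize(snippet.text)
    if not norm:
        return DisclosureRecord(snippet.placebo_group_id, "MI")

    fd_hits = rules._match(rules.fd_tokens, norm)
    dd_hits = rules._match(rules.dd_tokens, norm)
    esc_hits = rules._match(rules.escalation_tokens, norm)

    if fd_hits:
        return DisclosureRecord(
            snippet.placebo_group_id, "FD", tuple(fd_hits + esc_hits), escalated=False
        )
    if esc_hits:
        return DisclosureRecord(
            snippet.placebo_group_id, "FD", tuple(dd_hits + esc_hits), escalated=True
        )
    if dd_hits:
        return DisclosureRecord(snippet.placebo_group_id, "DD", tuple(dd_hits))
    return DisclosureRecord(snippet.placebo_group_id, "MI")


@dataclass(frozen=True)
class CategorySummary:
    """Counts and one-decimal percentages per category over placebo groups."""

    total: int
    counts: Mapping[str, int]
    percentages: Mapping[str, float]

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "counts": dict(self.counts),
            "percentages": dict(self.percentages),
        }


def summarize_categories(records: Sequence[DisclosureRecord]) -> CategorySummary:
    if not records:
        raise ValueError("summarize_categories requires at least one record")
    counts = {c: 0 for c in CATEGORIES}
    for rec in records:
        counts[rec.category] += 1
    total = len(records)
    pct = {c: round_half_up(100.0 * n / total) for c, n in counts.items()}
    return CategorySummary(total=total, counts=counts, percentages=pct)


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p: float


def chi_square_2x2(table, correction: bool = False) -> Chi2Result:
    """Pearson chi-square on a 2x2 count table (optionally Yates-corrected)."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("all cells must be non-negative")
    for axis, name in ((1, "row"), (0, "column")):
        margins = arr.sum(axis=axis)
        for i, m in enumerate(margins):
            if m == 0:
                raise ValueError(f"degenerate table: {name} {i} has zero margin")
    stat, p, df, _ = stats.chi2_contingency(arr, correction=correction)
    return Chi2Result(statistic=float(stat), df=int(df), p=float(p))
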
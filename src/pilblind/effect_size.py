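"""Per-comparison standardized mean differences from continuous or dichotomous summaries.

Sign convention throughout: negative SMD favors the real intervention.
Continuous outcomes use Hedges' g (small-sample corrected) by default;
dichotomous outcomes are converted through the logistic route
SMD = (sqrt(3)/pi) * ln OR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "ContinuousSummary",
    "DichotomousSummary",
    "StudyEffect",
    "OutcomeCandidate",
    "DegenerateOutcomeError",
    "OutcomeSelectionError",
    "smd_continuous",
    "smd_from_dichotomous",
    "split_shared_arm",
    "select_outcome",
]

SQRT3_OVER_PI = math.sqrt(3.0) / math.pi


class DegenerateOutcomeError(ValueError):
    """Outcome summary carries no usable effect information."""


class OutcomeSelectionError(ValueError):
    """No candidate outcome has extractable data; study must be excluded."""


@dataclass(frozen=True)
class ContinuousSummary:
    mean_real: float
    sd_real: float
    n_real: int
    mean_placebo: float
    sd_placebo: float
    n_placebo: int

    def __post_init__(self) -> None:
        if self.sd_real < 0 or self.sd_placebo < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_real < 2 or self.n_placebo < 2:
            raise ValueError("each arm needs n >= 2")


@dataclass(frozen=True)
class DichotomousSummary:
    events_real: int
    total_real: int
    events_placebo: int
    total_placebo: int

    def __post_init__(self) -> None:
        if self.total_real < 1 or self.total_placebo < 1:
            raise ValueError("arm totals must be >= 1")
        if not 0 <= self.events_real <= self.total_real:
            raise ValueError("events_real must lie in [0, total_real]")
        if not 0 <= self.events_placebo <= self.total_placebo:
            raise ValueError("events_placebo must lie in [0, total_placebo]")


@dataclass(frozen=True)
class StudyEffect:
    study_id: str
    smd: float
    var_smd: float
    source: str  # "continuous" | "dichotomous"
    category: str | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        if self.var_smd <= 0:
            raise ValueError("var_smd must be positive")
        if self.source not in ("continuous", "dichotomous"):
            raise ValueError(f"source must be continuous|dichotomous, got {self.source!r}")

    @property
    def se_smd(self) -> float:
        return math.sqrt(self.var_smd)


def smd_continuous(
    cs: ContinuousSummary,
    *,
    hedges: bool = True,
    study_id: str = "",
    category: str | None = None,
    region: str | None = None,
) -> StudyEffect:
    """Hedges' g (or Cohen's d with ``hedges=False``) and its variance.

    d = (mean_real - mean_placebo) / s_pooled with the df-weighted pooled
    SD; J = 1 - 3/(4*(n1+n2-2) - 1); g = J*d;
    var = (n1+n2)/(n1*n2) + g**2 / (2*(n1+n2)).
    """
    n1, n2 = cs.n_real, cs.n_placebo
    df = n1 + n2 - 2
    s_pooled = math.sqrt(
        ((n1 - 1) * cs.sd_real**2 + (n2 - 1) * cs.sd_placebo**2) / df
    )
    if s_pooled == 0:
        raise DegenerateOutcomeError("pooled SD is zero; outcome carries no variation")
    d = (cs.mean_real - cs.mean_placebo) / s_pooled
    g = d * (1.0 - 3.0 / (4.0 * df - 1.0)) if hedges else d
    var = (n1 + n2) / (n1 * n2) + g**2 / (2.0 * (n1 + n2))
    return StudyEffect(
        study_id=study_id, smd=g, var_smd=var, source="continuous",
        category=category, region=region,
    )


def smd_from_dichotomous(
    ds: DichotomousSummary,
    *,
    event_is_harm: bool = True,
    study_id: str = "",
    category: str | None = None,
    region: str | None = None,
) -> StudyEffect:
    """SMD via the odds ratio: smd = (sqrt(3)/pi) ln OR, var = (3/pi^2) var(ln OR).

    A 0.5 continuity correction is added to every cell when any cell is
    zero.  ``event_is_harm`` fixes the sign so a negative SMD favors the
    real intervention: when the counted event is beneficial the converted
    effect is negated.
    """
    a = float(ds.events_real)
    b = float(ds.total_real - ds.events_real)
    c = float(ds.events_placebo)
    d = float(ds.total_placebo - ds.events_placebo)
    if (a == 0 and c == 0) or (b == 0 and d == 0):
        raise DegenerateOutcomeError(
            "both arms are all-events or all-non-events; odds ratio undefined"
        )
    if 0.0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ln_or = math.log((a * d) / (b * c))
    var_ln_or = 1 / a + 1 / b + 1 / c + 1 / d
    smd = SQRT3_OVER_PI * ln_or
    if not event_is_harm:
        smd = -smd
    var = (3.0 / math.pi**2) * var_ln_or
    return StudyEffect(
        study_id=study_id, smd=smd, var_smd=var, source="dichotomous",
        category=category, region=region,
    )


def split_shared_arm(n_shared: int, k: int) -> list[int]:
    """Split a shared arm's n as evenly as possible across k comparisons.

    Deterministic: when n is not divisible by k the earlier comparisons
    receive the extra participants.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_shared < k:
        raise ValueError(f"cannot split {n_shared} participants across {k} comparisons")
    base, rem = divmod(n_shared, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


@dataclass(frozen=True)
class OutcomeCandidate:
    label: str
    is_primary_endpoint: bool = False
    timepoint_offset_from_last_treatment: float = 0.0
    is_common_scale: bool = False
    has_clear_data: bool = True


def select_outcome(candidates: Sequence[OutcomeCandidate]) -> OutcomeCandidate:
    """Pick one outcome per study by a deterministic priority.

    (a) a designated primary endpoint with extractable data; else
    (b) among clear-data candidates, one on the condition's common scale;
    else (c) any clear-data candidate.  Within a rule the timepoint
    closest to the last treatment session wins; ties keep input order.
    """
    if not candidates:
        raise ValueError("candidate list must be non-empty")

    def closest(pool: list[tuple[int, OutcomeCandidate]]) -> OutcomeCandidate:
        return min(
            pool,
            key=lambda ic: (abs(ic[1].timepoint_offset_from_last_treatment), ic[0]),
        )[1]

    indexed = list(enumerate(candidates))
    clear = [(i, c) for i, c in indexed if c.has_clear_data]
    primaries = [(i, c) for i, c in clear if c.is_primary_endpoint]
    if primaries:
        return closest(primaries)
    common = [(i, c) for i, c in clear if c.is_common_scale]
    if common:
        return closest(common)
    if clear:
        return closest(clear)
    raise OutcomeSelectionError("no candidate outcome reports extractable data")
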
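"""Bang's blinding index per trial arm, nine-scenario classification, and group comparison.

The index for an arm is the difference between the proportion guessing
their own intervention and the proportion guessing the other one, with
"don't know" answers kept in the denominator.  It lies in [-1, 1]: 1
means every participant guessed correctly, 0 means guessing looked
random, -1 means everyone guessed the opposite arm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .disclosure_coding import round_half_up

__all__ = [
    "ARMS",
    "STATUSES",
    "GuessTable",
    "BlindingAssessment",
    "BlindingScenario",
    "ComparisonResult",
    "bang_bi",
    "bi_confidence_interval",
    "classify_bi",
    "assess_blinding",
    "assign_scenario",
    "scenario_for_statuses",
    "scenario_frequency_grid",
    "compare_bi_groups",
]

ARMS = ("real", "placebo")

RANDOM_GUESS = "random_guess"
UNBLINDED = "unblinded"
OPPOSITE_GUESS = "opposite_guess"
STATUSES = (RANDOM_GUESS, UNBLINDED, OPPOSITE_GUESS)

Status = Literal["random_guess", "unblinded", "opposite_guess"]


@dataclass(frozen=True)
class GuessTable:
    """End-of-trial allocation-guess counts for one arm."""

    arm: str
    n_guess_real: int
    n_guess_placebo: int
    n_dont_know: int = 0

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        for name in ("n_guess_real", "n_guess_placebo", "n_dont_know"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("guess table must have at least one respondent")

    @property
    def total(self) -> int:
        return self.n_guess_real + self.n_guess_placebo + self.n_dont_know


def bang_bi(gt: GuessTable) -> float:
    """Blinding index: (correct - incorrect guesses) / all respondents."""
    diff = gt.n_guess_real - gt.n_guess_placebo
    if gt.arm == "placebo":
        diff = -diff
    return diff / gt.total


def bi_confidence_interval(
    gt: GuessTable, level: float = 0.95, truncate: bool = False
) -> tuple[float, float, float]:
    """Standard error and Wald CI for the index.

    The variance is that of a difference of two multinomial proportions:
    [p1(1-p1) + p2(1-p2) + 2 p1 p2] / n, where p1 is the proportion
    guessing their own arm and p2 the proportion guessing the other.
    By default the CI is not clipped to [-1, 1]; set ``truncate`` to clip.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    n = gt.total
    correct = gt.n_guess_real if gt.arm == "real" else gt.n_guess_placebo
    incorrect = gt.n_guess_placebo if gt.arm == "real" else gt.n_guess_real
    p1, p2 = correct / n, incorrect / n
    var = (p1 * (1 - p1) + p2 * (1 - p2) + 2 * p1 * p2) / n
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.5 + level / 2)
    bi = bang_bi(gt)
    lo, hi = bi - z * se, bi + z * se
    if truncate:
        lo, hi = max(lo, -1.0), min(hi, 1.0)
    return se, lo, hi


def classify_bi(bi: float) -> Status:
    """Threshold status: random guess strictly inside (-0.2, 0.2); the
    boundaries belong to unblinded (>= 0.2) / opposite guess (<= -0.2)."""
    if not -1.0 - 1e-12 <= bi <= 1.0 + 1e-12:
        raise ValueError(f"blinding index must lie in [-1, 1], got {bi}")
    if bi >= 0.2:
        return UNBLINDED
    if bi <= -0.2:
        return OPPOSITE_GUESS
    return RANDOM_GUESS


@dataclass(frozen=True)
class BlindingAssessment:
    bi: float
    se: float
    ci_low: float
    ci_high: float
    status: Status


def assess_blinding(
    gt: GuessTable, level: float = 0.95, truncate: bool = False
) -> BlindingAssessment:
    bi = bang_bi(gt)
    se, lo, hi = bi_confidence_interval(gt, level=level, truncate=truncate)
    return BlindingAssessment(bi=bi, se=se, ci_low=lo, ci_high=hi, status=classify_bi(bi))


@dataclass(frozen=True)
class BlindingScenario:
    id: str
    exp_status: Status
    ctrl_status: Status
    interpretation: str


# (experimental-arm status, control-arm status) -> scenario id, stock reading.
_SCENARIOS: dict[tuple[str, str], tuple[str, str]] = {
    (RANDOM_GUESS, RANDOM_GUESS): ("S1", "ideal: random guessing in both arms"),
    (RANDOM_GUESS, OPPOSITE_GUESS): ("S2", "rare"),
    (RANDOM_GUESS, UNBLINDED): ("S3", "little apparent effect in either arm"),
    (UNBLINDED, UNBLINDED): ("S4", "possibly problematic: correct guessing in both arms"),
    (UNBLINDED, OPPOSITE_GUESS): ("S5", "ideal: wishful thinking in both arms"),
    (UNBLINDED, RANDOM_GUESS): ("S6", "possibly problematic: control arm uncertain"),
    (OPPOSITE_GUESS, OPPOSITE_GUESS): ("S7", "rare"),
    (OPPOSITE_GUESS, RANDOM_GUESS): ("S8", "rare"),
    (OPPOSITE_GUESS, UNBLINDED): ("S9", "no apparent effect or low expectations"),
}

_SCENARIO_BY_ID = {sid: key for key, (sid, _) in _SCENARIOS.items()}
SCENARIO_IDS = tuple(sorted(_SCENARIO_BY_ID))


def assign_scenario(exp_status: Status, ctrl_status: Status) -> BlindingScenario:
    """Map the (experimental, control) status pair onto scenarios S1-S9."""
    for name, status in (("exp_status", exp_status), ("ctrl_status", ctrl_status)):
        if status not in STATUSES:
            raise ValueError(f"{name} must be one of {STATUSES}, got {status!r}")
    sid, interp = _SCENARIOS[(exp_status, ctrl_status)]
    return BlindingScenario(sid, exp_status, ctrl_status, interp)


def scenario_for_statuses(scenario_id: str) -> tuple[Status, Status]:
    """Inverse mapping: scenario id -> (experimental, control) statuses."""
    try:
        return _SCENARIO_BY_ID[scenario_id]
    except KeyError:
        raise ValueError(f"unknown scenario id {scenario_id!r}") from None


def scenario_frequency_grid(assignments: Iterable[tuple[str, str]]) -> pd.DataFrame:
    """Scenario-frequency grid split by group label.

    ``assignments`` yields (scenario_id, group_label) pairs, one per study.
    Returns a frame indexed S1..S9 with an interpretation column plus, per
    group, a count column and a one-decimal percentage column.
    """
    pairs = list(assignments)
    groups = sorted({g for _, g in pairs})
    grid = pd.DataFrame(
        {"interpretation": [_SCENARIOS[_SCENARIO_BY_ID[s]][1] for s in SCENARIO_IDS]},
        index=pd.Index(SCENARIO_IDS, name="scenario"),
    )
    for g in groups:
        sids = [s for s, gg in pairs if gg == g]
        counts = pd.Series(sids).value_counts().reindex(SCENARIO_IDS, fill_value=0)
        grid[f"{g}_n"] = counts.to_numpy()
        denom = max(len(sids), 1)
        grid[f"{g}_pct"] = [round_half_up(100.0 * c / denom) for c in counts]
    return grid


@dataclass(frozen=True)
class ComparisonResult:
    test: str  # "independent_t" or "mann_whitney_u"
    statistic: float
    p: float
    shapiro_p_a: float
    shapiro_p_b: float


def compare_bi_groups(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alpha: float = 0.05,
    force: str | None = None,
    welch: bool = False,
) -> ComparisonResult:
    """Two-sided location comparison of two sets of blinding indices.

    A Shapiro-Wilk check runs on each group; if both pass at ``alpha`` an
    independent t-test is used, otherwise a Mann-Whitney U test (exact for
    small tie-free samples, normal approximation with tie correction
    otherwise, per scipy's method selection).  ``force`` overrides the
    gate with "t" or "mannwhitney".
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs >= 3 values for the normality check")
    if force not in (None, "t", "mannwhitney"):
        raise ValueError(f"force must be None, 't' or 'mannwhitney', got {force!r}")

    sw_a = stats.shapiro(a).pvalue if np.ptp(a) > 0 else 0.0
    sw_b = stats.shapiro(b).pvalue if np.ptp(b) > 0 else 0.0

    use_t = force == "t" or (force is None and sw_a > alpha and sw_b > alpha)
    if use_t:
        res = stats.ttest_ind(a, b, equal_var=not welch)
        name = "independent_t"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        name = "mann_whitney_u"
    return ComparisonResult(
        test=name,
        statistic=float(res.statistic),
        p=float(res.pvalue),
        shapiro_p_a=float(sw_a),
        shapiro_p_b=float(sw_b),
    )
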
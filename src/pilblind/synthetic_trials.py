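"""Seeded synthetic trial corpora: leaflet snippets, guess tables, outcome summaries.

The guess model is a minimal three-parameter mixture able to realize all
nine blinding scenarios: each participant independently either perceives
their true assignment (probability ``p_perceive``, guesses it correctly),
answers don't-know (``p_dontknow``), or otherwise guesses "real" with
probability ``w_wishful``.  Under this model the expected blinding index
is analytic:

    E[BI_real]    = p + r*(2w - 1)
    E[BI_placebo] = p + r*(1 - 2w),  r = 1 - p - p_dontknow

so a model can be calibrated exactly to any target pair of arm-level
mean indices (see :func:`calibrate_guess_model`).

Outcome summaries are drawn from their exact sampling distributions
(normal sample mean, chi-distributed sample SD) around a per-study true
effect with configurable between-study heterogeneity.  Each study owns
its own random substream derived from the master seed, so corpora are
stable when study counts change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import meta_analysis
from .blinding_index import GuessTable
from .disclosure_coding import PilSnippet, RuleSet, classify_disclosure
from .effect_size import ContinuousSummary, smd_continuous

__all__ = [
    "GuessModel",
    "SimulationConfig",
    "Corpus",
    "calibrate_guess_model",
    "default_guess_models",
    "generate_corpus",
    "recover_parameters",
    "simulate_null_subgroup_rejection",
    "RecoveryReport",
]

_CAT_CODE = {"FD": 0, "DD": 1, "MI": 2}

# Snippet templates per category; built from the default rule lexicon so
# the disclosure coder recovers the intended category exactly.
_FD_TEMPLATES = (
    "You will be randomly assigned to receive either real acupuncture or sham acupuncture.",
    "Half of the participants will receive placebo acupuncture with a device that looks identical.",
    "The comparison arm will receive fake acupuncture needles.",
    "The control group will receive needling at non-acupoint locations.",
)
_DD_TEMPLATES = (
    "You will be allocated to group one or group two.",
    "Participants will be assigned to the treatment group or the control group.",
    "You may receive a different style of acupuncture from the usual one.",
)
_MI_TEMPLATES = (
    "",
    "This study investigates whether acupuncture relieves your symptoms over eight weeks.",
    "You will attend weekly acupuncture sessions and complete questionnaires.",
)
_TEMPLATES = {"FD": _FD_TEMPLATES, "DD": _DD_TEMPLATES, "MI": _MI_TEMPLATES}

# Probability a study originates in Asia, by category (full disclosure is
# more common outside Asia in the emulated corpus).
_P_ASIA = {"FD": 0.35, "DD": 0.75, "MI": 0.75}


@dataclass(frozen=True)
class GuessModel:
    """Per-category parameters of the participant guess mixture."""

    p_perceive: float
    w_wishful: float
    p_dontknow: float

    def __post_init__(self) -> None:
        for name in ("p_perceive", "w_wishful", "p_dontknow"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.p_perceive + self.p_dontknow > 1.0 + 1e-12:
            raise ValueError("p_perceive + p_dontknow must not exceed 1")

    def arm_probabilities(self, arm: str) -> tuple[float, float, float]:
        """(P[guess real], P[guess placebo], P[don't know]) for one arm."""
        r = 1.0 - self.p_perceive - self.p_dontknow
        guess_real_unperceived = r * self.w_wishful
        guess_placebo_unperceived = r * (1.0 - self.w_wishful)
        if arm == "real":
            p_real = self.p_perceive + guess_real_unperceived
            p_placebo = guess_placebo_unperceived
        elif arm == "placebo":
            p_real = guess_real_unperceived
            p_placebo = self.p_perceive + guess_placebo_unperceived
        else:
            raise ValueError(f"arm must be 'real' or 'placebo', got {arm!r}")
        return p_real, p_placebo, self.p_dontknow

    def expected_bi(self, arm: str) -> float:
        p_real, p_placebo, _ = self.arm_probabilities(arm)
        return p_real - p_placebo if arm == "real" else p_placebo - p_real


def calibrate_guess_model(
    target_real_bi: float, target_placebo_bi: float, p_dontknow: float = 0.15
) -> GuessModel:
    """Invert the mixture so expected arm-level indices hit the targets exactly.

    Solving the two expectation equations gives
    p_perceive = (bi_real + bi_placebo)/2 and
    w_wishful = ((bi_real - bi_placebo)/(2r) + 1)/2 with
    r = 1 - p_perceive - p_dontknow.
    """
    p_perceive = (target_real_bi + target_placebo_bi) / 2.0
    r = 1.0 - p_perceive - p_dontknow
    if r <= 0:
        raise ValueError("infeasible targets: p_perceive + p_dontknow >= 1")
    w = ((target_real_bi - target_placebo_bi) / (2.0 * r) + 1.0) / 2.0
    return GuessModel(p_perceive=p_perceive, w_wishful=w, p_dontknow=p_dontknow)


def default_guess_models() -> dict[str, GuessModel]:
    """Models calibrated to mean arm indices of (0.42, -0.16) for FD and
    (0.41, -0.21) for DD/MI."""
    fd = calibrate_guess_model(0.42, -0.16)
    dd = calibrate_guess_model(0.41, -0.21)
    return {"FD": fd, "DD": dd, "MI": dd}


@dataclass(frozen=True)
class SimulationConfig:
    k_fd: int = 14
    k_dd: int = 10
    k_mi: int = 1
    n_per_arm_range: tuple[int, int] = (16, 90)
    true_smd_fd: float = -0.12
    true_smd_dd: float = -0.43
    tau: float = 0.1  # between-study SD of the true effect
    guess_models: Mapping[str, GuessModel] = field(default_factory=default_guess_models)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k_fd", "k_dd", "k_mi"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.n_per_arm_range
        if lo < 2 or hi < lo:
            raise ValueError("n_per_arm_range must satisfy 2 <= lo <= hi")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        missing = {"FD", "DD", "MI"} - set(self.guess_models)
        if missing:
            raise ValueError(f"guess_models missing categories {sorted(missing)}")


@dataclass(frozen=True)
class Corpus:
    snippets: tuple[PilSnippet, ...]
    guess_tables: pd.DataFrame  # schema of the blinding-input CSV
    outcomes: pd.DataFrame  # schema of the effects-input CSV
    true_categories: Mapping[str, str]  # study_id -> intended category
    true_smds: Mapping[str, float]  # study_id -> per-study true effect


def _study_rng(seed: int, category: str, index: int) -> np.random.Generator:
    return np.random.default_rng([seed, _CAT_CODE[category], index])


def _simulate_arm_summary(
    rng: np.random.Generator, n: int, mean: float, sd: float
) -> tuple[float, float]:
    """Sample mean and SD drawn from their exact sampling distributions."""
    m = rng.normal(mean, sd / np.sqrt(n))
    s = sd * np.sqrt(rng.chisquare(n - 1) / (n - 1))
    return float(m), float(s)


def generate_corpus(config: SimulationConfig) -> Corpus:
    """Deterministically generate one synthetic corpus from a seeded config.

    Per study: a leaflet snippet from category-appropriate templates, one
    guess table per arm drawn from the category's guess mixture, and (for
    FD/DD studies) a continuous outcome summary whose between-arm gap
    realizes the category's true SMD plus N(0, tau^2) heterogeneity.
    MI studies contribute no outcome rows.
    """
    snippets: list[PilSnippet] = []
    guess_rows: list[dict] = []
    outcome_rows: list[dict] = []
    true_cat: dict[str, str] = {}
    true_smd: dict[str, float] = {}

    plan = [("FD", config.k_fd), ("DD", config.k_dd), ("MI", config.k_mi)]
    lo, hi = config.n_per_arm_range
    for category, k in plan:
        model = config.guess_models[category]
        templates = _TEMPLATES[category]
        for i in range(k):
            rng = _study_rng(config.seed, category, i)
            study_id = f"{category}-{i + 1:02d}"
            true_cat[study_id] = category

            region = "Asia" if rng.random() < _P_ASIA[category] else "non-Asia"
            text = templates[int(rng.integers(len(templates)))]
            snippets.append(
                PilSnippet(
                    pil_id=study_id,
                    placebo_group_id=study_id,
                    text=text,
                    region=region,
                )
            )

            n_real = int(rng.integers(lo, hi + 1))
            n_placebo = int(rng.integers(lo, hi + 1))
            for arm, n in (("real", n_real), ("placebo", n_placebo)):
                counts = rng.multinomial(n, model.arm_probabilities(arm))
                guess_rows.append(
                    {
                        "study_id": study_id,
                        "arm": arm,
                        "n_guess_real": int(counts[0]),
                        "n_guess_placebo": int(counts[1]),
                        "n_dont_know": int(counts[2]),
                        "category": category,
                        "region": region,
                    }
                )

            if category == "MI":
                continue  # no MI study provides poolable outcome data
            base = config.true_smd_fd if category == "FD" else config.true_smd_dd
            theta_i = base + config.tau * rng.normal()
            true_smd[study_id] = float(theta_i)
            mean_r, sd_r = _simulate_arm_summary(rng, n_real, theta_i, 1.0)
            mean_p, sd_p = _simulate_arm_summary(rng, n_placebo, 0.0, 1.0)
            outcome_rows.append(
                {
                    "study_id": study_id,
                    "category": category,
                    "region": region,
                    "outcome_type": "continuous",
                    "mean_real": mean_r,
                    "sd_real": sd_r,
                    "n_real": n_real,
                    "mean_placebo": mean_p,
                    "sd_placebo": sd_p,
                    "n_placebo": n_placebo,
                    "events_real": "",
                    "total_real": "",
                    "events_placebo": "",
                    "total_placebo": "",
                    "event_is_harm": "",
                    "shared_arm_k": 1,
                }
            )

    return Corpus(
        snippets=tuple(snippets),
        guess_tables=pd.DataFrame(guess_rows),
        outcomes=pd.DataFrame(outcome_rows),
        true_categories=true_cat,
        true_smds=true_smd,
    )


@dataclass(frozen=True)
class RecoveryReport:
    n_replicates: int
    mean_pooled: Mapping[str, float]
    bias: Mapping[str, float]
    ci_coverage: Mapping[str, float]
    coding_agreement: float
    subgroup_rejection_rate: float


def recover_parameters(
    config: SimulationConfig,
    n_replicates: int = 100,
    alpha: float = 0.05,
    rules: RuleSet | None = None,
) -> RecoveryReport:
    """Run the full downstream pipeline over replicated corpora.

    Per replicate: code the snippets, derive study effects from the
    outcome summaries grouped by *coded* category, pool each subgroup,
    and test the subgroup difference.  Reports bias of the subgroup
    pooled estimates against the configured true effects, CI coverage of
    the truths, coding agreement against the generating categories, and
    the subgroup-test rejection rate.
    """
    if rules is None:
        rules = RuleSet.default()
    truths = {"FD": config.true_smd_fd, "DD": config.true_smd_dd}
    pooled: dict[str, list[float]] = {"FD": [], "DD": []}
    covered: dict[str, list[bool]] = {"FD": [], "DD": []}
    agree = 0
    total_snippets = 0
    rejections = 0

    for rep in range(n_replicates):
        corpus = generate_corpus(replace(config, seed=config.seed + rep))
        coded = {}
        for snippet in corpus.snippets:
            rec = classify_disclosure(snippet, rules)
            coded[snippet.placebo_group_id] = rec.category
            agree += rec.category == corpus.true_categories[snippet.placebo_group_id]
            total_snippets += 1

        by_cat: dict[str, list] = {"FD": [], "DD": []}
        for row in corpus.outcomes.itertuples(index=False):
            cat = coded.get(row.study_id, row.category)
            if cat not in by_cat:
                continue
            cs = ContinuousSummary(
                mean_real=row.mean_real,
                sd_real=row.sd_real,
                n_real=int(row.n_real),
                mean_placebo=row.mean_placebo,
                sd_placebo=row.sd_placebo,
                n_placebo=int(row.n_placebo),
            )
            by_cat[cat].append(
                smd_continuous(cs, study_id=row.study_id, category=cat, region=row.region)
            )

        results = {}
        for cat, effects in by_cat.items():
            if not effects:
                continue
            res = meta_analysis.pool_random_effects(effects)
            results[cat] = res
            pooled[cat].append(res.pooled_smd)
            covered[cat].append(res.ci_low <= truths[cat] <= res.ci_high)
        if len(results) >= 2:
            comp = meta_analysis.subgroup_difference(results)
            rejections += comp.p_between < alpha

    mean_pooled = {c: float(np.mean(v)) for c, v in pooled.items() if v}
    return RecoveryReport(
        n_replicates=n_replicates,
        mean_pooled=mean_pooled,
        bias={c: mean_pooled[c] - truths[c] for c in mean_pooled},
        ci_coverage={c: float(np.mean(v)) for c, v in covered.items() if v},
        coding_agreement=agree / total_snippets if total_snippets else float("nan"),
        subgroup_rejection_rate=rejections / n_replicates,
    )


def simulate_null_subgroup_rejection(
    k_per_group: tuple[int, int] = (14, 10),
    true_smd: float = -0.2,
    tau: float = 0.2,
    se_range: tuple[float, float] = (0.15, 0.35),
    n_replicates: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I-error check of the subgroup test at the effect level.

    Both subgroups share one true effect; per-study observed effects are
    the truth plus a N(0, tau^2) study deviation plus N(0, se_i^2) noise.
    Returns the fraction of replicates where the subgroup test rejects.
    """
    rng = np.random.default_rng(seed)
    from .effect_size import StudyEffect

    rejections = 0
    for _ in range(n_replicates):
        results = {}
        for g, k in enumerate(k_per_group):
            ses = rng.uniform(*se_range, size=k)
            thetas = true_smd + rng.normal(0.0, tau, size=k) + rng.normal(0.0, ses)
            effects = [
                StudyEffect(study_id=f"g{g}-{i}", smd=float(t), var_smd=float(s**2),
                            source="continuous")
                for i, (t, s) in enumerate(zip(thetas, ses))
            ]
            results[f"g{g}"] = meta_analysis.pool_random_effects(effects)
        comp = meta_analysis.subgroup_difference(results)
        rejections += comp.p_between < alpha
    return rejections / n_replicates
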
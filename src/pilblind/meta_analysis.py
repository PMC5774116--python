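"""DerSimonian-Laird random-effects pooling under generic inverse variance,
plus a subgroup-difference test that treats each subgroup subtotal as one study.

Conventions match RevMan 5.x output: DL tau-squared truncated at zero,
normal-quantile confidence intervals, no Knapp-Hartung adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effect_size import StudyEffect

__all__ = [
    "MetaResult",
    "SubgroupComparison",
    "pool_random_effects",
    "subgroup_difference",
    "forest_table",
]


@dataclass(frozen=True)
class MetaResult:
    pooled_smd: float
    se_pooled: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    q: float
    df_q: int
    tau2: float
    i2: float
    weights: tuple[float, ...]  # normalized random-effects weights, sum to 1
    study_ids: tuple[str, ...]
    k: int

    def to_dict(self) -> dict:
        return {
            "pooled_smd": self.pooled_smd,
            "se_pooled": self.se_pooled,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "z": self.z,
            "p": self.p,
            "q": self.q,
            "df_q": self.df_q,
            "tau2": self.tau2,
            "i2": self.i2,
            "k": self.k,
            "weights": dict(zip(self.study_ids, self.weights)),
        }


def _pool_arrays(
    smds: np.ndarray, variances: np.ndarray, level: float
) -> tuple[float, float, float, int, float, float, np.ndarray]:
    w = 1.0 / variances
    theta_fe = float(np.sum(w * smds) / np.sum(w))
    q = float(np.sum(w * (smds - theta_fe) ** 2))
    df = len(smds) - 1
    if df > 0:
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    else:
        tau2 = 0.0
    w_star = 1.0 / (variances + tau2)
    pooled = float(np.sum(w_star * smds) / np.sum(w_star))
    se = float(1.0 / math.sqrt(np.sum(w_star)))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return pooled, se, q, df, tau2, i2, w_star / np.sum(w_star)


def pool_random_effects(
    effects: Sequence[StudyEffect], level: float = 0.95
) -> MetaResult:
    """Pool study effects with DerSimonian-Laird random-effects weights.

    Fixed-effect weights 1/var feed Cochran's Q; tau2 = max(0, (Q-df)/C)
    with C = sum(w) - sum(w^2)/sum(w); random weights 1/(var+tau2) give
    the pooled estimate, its SE, and a two-sided z-test.  A single effect
    passes through unchanged with Q = tau2 = 0.
    """
    if not effects:
        raise ValueError("cannot pool an empty list of effects")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    smds = np.array([e.smd for e in effects], dtype=float)
    variances = np.array([e.var_smd for e in effects], dtype=float)
    if (variances <= 0).any():
        raise ValueError("all effect variances must be positive")
    pooled, se, q, df, tau2, i2, weights = _pool_arrays(smds, variances, level)
    zq = stats.norm.ppf(0.5 + level / 2)
    z = pooled / se
    return MetaResult(
        pooled_smd=pooled,
        se_pooled=se,
        ci_low=pooled - zq * se,
        ci_high=pooled + zq * se,
        z=z,
        p=float(2 * stats.norm.sf(abs(z))),
        q=q,
        df_q=df,
        tau2=tau2,
        i2=i2,
        weights=tuple(weights),
        study_ids=tuple(e.study_id for e in effects),
        k=len(effects),
    )


@dataclass(frozen=True)
class SubgroupComparison:
    subgroup_results: Mapping[str, MetaResult]
    q_between: float
    df_between: int
    p_between: float
    i2_between: float

    def to_dict(self) -> dict:
        return {
            "q_between": self.q_between,
            "df_between": self.df_between,
            "p_between": self.p_between,
            "i2_between": self.i2_between,
            "subgroups": {k: v.to_dict() for k, v in self.subgroup_results.items()},
        }


def subgroup_difference(results: Mapping[str, MetaResult]) -> SubgroupComparison:
    """Cochran's Q across subgroup subtotals, each weighted by 1/se^2."""
    if len(results) < 2:
        raise ValueError("need at least two subgroups to compare")
    ses = np.array([r.se_pooled for r in results.values()], dtype=float)
    if (ses == 0).any():
        raise ValueError("subgroup with zero standard error cannot be compared")
    thetas = np.array([r.pooled_smd for r in results.values()], dtype=float)
    w = 1.0 / ses**2
    theta_bar = float(np.sum(w * thetas) / np.sum(w))
    q = float(np.sum(w * (thetas - theta_bar) ** 2))
    df = len(results) - 1
    p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return SubgroupComparison(
        subgroup_results=dict(results),
        q_between=q,
        df_between=df,
        p_between=p,
        i2_between=i2,
    )


def forest_table(
    effects: Sequence[StudyEffect], result: MetaResult, level: float = 0.95
) -> pd.DataFrame:
    """Plain forest table: per-study SMD, CI and weight %, plus a total row."""
    z = stats.norm.ppf(0.5 + level / 2)
    rows = [
        {
            "study": e.study_id,
            "smd": e.smd,
            "ci_low": e.smd - z * e.se_smd,
            "ci_high": e.smd + z * e.se_smd,
            "weight_pct": 100.0 * w,
        }
        for e, w in zip(effects, result.weights)
    ]
    rows.append(
        {
            "study": "Total",
            "smd": result.pooled_smd,
            "ci_low": result.ci_low,
            "ci_high": result.ci_high,
            "weight_pct": 100.0,
        }
    )
    return pd.DataFrame(rows, columns=["study", "smd", "ci_low", "ci_high", "weight_pct"])
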
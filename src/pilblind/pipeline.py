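"""End-to-end orchestration: coding -> blinding -> effects -> meta, with logging.

Stages are independent: a missing input file skips only its own stage
(and downstream dependents) with a logged reason.  Every dropped record
is accounted for in the run log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import io as pio
from .blinding_index import GuessTable, assess_blinding, assign_scenario, scenario_frequency_grid
from .disclosure_coding import (
    CategorySummary,
    DisclosureRecord,
    RuleSet,
    classify_disclosure,
    summarize_categories,
)
from .effect_size import StudyEffect
from .meta_analysis import MetaResult, SubgroupComparison, forest_table, pool_random_effects, subgroup_difference

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "EXIT_OK", "EXIT_WARNINGS", "EXIT_VALIDATION", "EXIT_STAGE"]

logger = logging.getLogger("pilblind")

EXIT_OK = 0
EXIT_WARNINGS = 1
EXIT_VALIDATION = 2
EXIT_STAGE = 3


@dataclass
class PipelineConfig:
    snippets_path: str | None = None
    guesses_path: str | None = None
    outcomes_path: str | None = None
    rules_path: str | None = None
    out_dir: str = "pilblind_out"
    alpha: float = 0.05
    ci_level: float = 0.95
    grouping: str = "disclosure"  # "disclosure" merges DD+MI for blinding grids
    yates: bool = False
    welch: bool = False
    hedges: bool = True
    truncate_ci: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.grouping not in ("disclosure", "category"):
            raise ValueError("grouping must be 'disclosure' or 'category'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)


@dataclass
class ReportBundle:
    records: list[DisclosureRecord] = field(default_factory=list)
    category_summary: CategorySummary | None = None
    blinding_table: pd.DataFrame | None = None
    scenario_grid: pd.DataFrame | None = None
    meta_results: Mapping[str, MetaResult] = field(default_factory=dict)
    subgroup_comparison: SubgroupComparison | None = None
    dropped: list[str] = field(default_factory=list)
    log_lines: list[str] = field(default_factory=list)


def _merge_group(category: str, mode: str) -> str:
    if mode == "disclosure" and category in ("DD", "MI"):
        return "DD/MI"
    return category


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle()

    def log(msg: str) -> None:
        logger.info(msg)
        bundle.log_lines.append(msg)

    log(f"config: {config}")
    rules = RuleSet.load(config.rules_path) if config.rules_path else RuleSet.default()

    coded: dict[str, str] = {}
    if config.snippets_path and Path(config.snippets_path).exists():
        snippets = pio.read_snippets_jsonl(config.snippets_path)
        bundle.records = [classify_disclosure(s, rules) for s in snippets]
        bundle.category_summary = summarize_categories(bundle.records)
        coded = {r.placebo_group_id: r.category for r in bundle.records}
        pio.records_to_tsv(bundle.records, out_dir / "disclosure_records.tsv")
        (out_dir / "category_summary.json").write_text(
            json.dumps(bundle.category_summary.to_dict(), indent=2) + "\n"
        )
        log(f"coding: classified {len(bundle.records)} placebo groups")
    else:
        log("coding: no snippet file; stage skipped")

    if config.guesses_path and Path(config.guesses_path).exists():
        gdf = pio.read_guess_tables(config.guesses_path)
        rows = []
        for idx, row in gdf.iterrows():
            gt = GuessTable(
                arm=row["arm"],
                n_guess_real=int(row["n_guess_real"]),
                n_guess_placebo=int(row["n_guess_placebo"]),
                n_dont_know=int(row["n_dont_know"]),
            )
            a = assess_blinding(gt, level=config.ci_level, truncate=config.truncate_ci)
            rows.append(
                {
                    "study_id": row["study_id"],
                    "arm": row["arm"],
                    "category": coded.get(row["study_id"], row["category"]),
                    "region": row["region"],
                    "bi": a.bi,
                    "se": a.se,
                    "ci_low": a.ci_low,
                    "ci_high": a.ci_high,
                    "status": a.status,
                }
            )
        bt = pd.DataFrame(rows)
        bundle.blinding_table = bt
        bt.to_csv(out_dir / "blinding_assessments.tsv", sep="\t", index=False)

        assignments = []
        for study_id, sub in bt.groupby("study_id", sort=True):
            by_arm = {r["arm"]: r for _, r in sub.iterrows()}
            if "real" not in by_arm or "placebo" not in by_arm:
                msg = f"blinding: study {study_id} lacks a complete arm pair; no scenario"
                bundle.dropped.append(msg)
                log(msg)
                continue
            scen = assign_scenario(by_arm["real"]["status"], by_arm["placebo"]["status"])
            group = _merge_group(by_arm["real"]["category"], config.grouping)
            assignments.append((scen.id, group))
        bundle.scenario_grid = scenario_frequency_grid(assignments)
        bundle.scenario_grid.to_csv(out_dir / "scenario_grid.tsv", sep="\t")
        log(f"blinding: assessed {len(rows)} arms, {len(assignments)} study scenarios")
    else:
        log("blinding: no guess file; stage skipped")

    if config.outcomes_path and Path(config.outcomes_path).exists():
        odf = pio.read_outcomes(config.outcomes_path)
        effects, dropped = pio.effects_from_outcomes(odf, hedges=config.hedges)
        for rowno, study_id, reason in dropped:
            msg = f"effects: row {rowno} ({study_id}) dropped: {reason}"
            bundle.dropped.append(msg)
            log(msg)
        # Coded category (when the leaflet was seen) overrides the file's column.
        effects = [
            StudyEffect(
                study_id=e.study_id, smd=e.smd, var_smd=e.var_smd, source=e.source,
                category=coded.get(e.study_id, e.category), region=e.region,
            )
            for e in effects
        ]
        pio.effects_to_tsv(effects, out_dir / "study_effects.tsv")

        by_group: dict[str, list[StudyEffect]] = {}
        for e in effects:
            by_group.setdefault(e.category or "unknown", []).append(e)
        results = {}
        forest_frames = []
        for group in sorted(by_group):
            group_effects = by_group[group]
            if not group_effects:
                continue
            res = pool_random_effects(group_effects, level=config.ci_level)
            results[group] = res
            ft = forest_table(group_effects, res, level=config.ci_level)
            ft.insert(0, "subgroup", group)
            forest_frames.append(ft)
        for cat in ("FD", "DD", "MI"):
            if cat not in results:
                log(f"meta: subgroup {cat} contributed no poolable effects; excluded")
        bundle.meta_results = results
        if forest_frames:
            pd.concat(forest_frames, ignore_index=True).to_csv(
                out_dir / "forest_table.tsv", sep="\t", index=False
            )
        if len(results) >= 2:
            bundle.subgroup_comparison = subgroup_difference(results)
            payload = bundle.subgroup_comparison.to_dict()
        else:
            payload = {"subgroups": {k: v.to_dict() for k, v in results.items()}}
            log("meta: fewer than two subgroups; no between-subgroup test")
        (out_dir / "meta_results.json").write_text(json.dumps(payload, indent=2) + "\n")
        log(f"meta: pooled {sum(len(v) for v in by_group.values())} effects "
            f"across {len(results)} subgroup(s)")
    else:
        log("meta: no outcomes file; stage skipped")

    (out_dir / "run_log.txt").write_text("\n".join(bundle.log_lines) + "\n")
    return bundle
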
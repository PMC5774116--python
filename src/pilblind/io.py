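"""Readers and writers for the pipeline's plain-text interchange formats.

Inputs: JSONL leaflet snippets, CSV guess tables, CSV outcome summaries.
Outputs: TSV tables and JSON summaries.  Validation errors always carry
the offending row number.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import pandas as pd

from .blinding_index import GuessTable
from .disclosure_coding import DisclosureRecord, PilSnippet
from .effect_size import (
    ContinuousSummary,
    DichotomousSummary,
    StudyEffect,
    smd_continuous,
    smd_from_dichotomous,
)

__all__ = [
    "SchemaError",
    "read_snippets_jsonl",
    "write_snippets_jsonl",
    "read_guess_tables",
    "read_outcomes",
    "effects_from_outcomes",
    "records_to_tsv",
    "effects_to_tsv",
    "read_effects_tsv",
]

GUESS_COLUMNS = [
    "study_id", "arm", "n_guess_real", "n_guess_placebo", "n_dont_know",
    "category", "region",
]
OUTCOME_COLUMNS = [
    "study_id", "category", "region", "outcome_type",
    "mean_real", "sd_real", "n_real", "mean_placebo", "sd_placebo", "n_placebo",
    "events_real", "total_real", "events_placebo", "total_placebo",
    "event_is_harm", "shared_arm_k",
]


class SchemaError(ValueError):
    """Input file violates the expected schema; message names the row."""


def read_snippets_jsonl(path: str | Path) -> list[PilSnippet]:
    snippets = []
    seen = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                snippet = PilSnippet(
                    pil_id=str(obj["pil_id"]),
                    placebo_group_id=str(obj["placebo_group_id"]),
                    text=str(obj.get("text", "")),
                    region=str(obj.get("region", "non-Asia")),
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise SchemaError(f"{path}: line {lineno}: {exc}") from exc
            key = (snippet.pil_id, snippet.placebo_group_id)
            if key in seen:
                raise SchemaError(f"{path}: line {lineno}: duplicate id pair {key}")
            seen.add(key)
            snippets.append(snippet)
    return snippets


def write_snippets_jsonl(snippets: Sequence[PilSnippet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in snippets:
            fh.write(
                json.dumps(
                    {
                        "pil_id": s.pil_id,
                        "placebo_group_id": s.placebo_group_id,
                        "text": s.text,
                        "region": s.region,
                    }
                )
                + "\n"
            )


def read_guess_tables(path: str | Path) -> pd.DataFrame:
    """Read and validate the per-arm guess-count CSV."""
    df = pd.read_csv(path, dtype={"study_id": str})
    missing = [c for c in GUESS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    for idx, row in df.iterrows():
        try:
            GuessTable(
                arm=row["arm"],
                n_guess_real=int(row["n_guess_real"]),
                n_guess_placebo=int(row["n_guess_placebo"]),
                n_dont_know=int(row["n_dont_know"]),
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: row {idx + 2}: {exc}") from exc
    return df


def read_outcomes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"study_id": str})
    required = ["study_id", "category", "region", "outcome_type"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return df


def _is_blank(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return str(value).strip() == ""


def effects_from_outcomes(
    df: pd.DataFrame, hedges: bool = True
) -> tuple[list[StudyEffect], list[tuple[int, str, str]]]:
    """Derive one StudyEffect per outcome row.

    Returns (effects, dropped) where each dropped entry is
    (row_number, study_id, reason).  Rows are dropped — never fatal —
    so partial corpora still pool.
    """
    effects: list[StudyEffect] = []
    dropped: list[tuple[int, str, str]] = []
    for idx, row in df.iterrows():
        rowno = idx + 2  # header is row 1
        study_id = str(row["study_id"])
        try:
            if row["outcome_type"] == "continuous":
                cs = ContinuousSummary(
                    mean_real=float(row["mean_real"]),
                    sd_real=float(row["sd_real"]),
                    n_real=int(float(row["n_real"])),
                    mean_placebo=float(row["mean_placebo"]),
                    sd_placebo=float(row["sd_placebo"]),
                    n_placebo=int(float(row["n_placebo"])),
                )
                effect = smd_continuous(
                    cs, hedges=hedges, study_id=study_id,
                    category=row["category"], region=row["region"],
                )
            elif row["outcome_type"] == "dichotomous":
                ds = DichotomousSummary(
                    events_real=int(float(row["events_real"])),
                    total_real=int(float(row["total_real"])),
                    events_placebo=int(float(row["events_placebo"])),
                    total_placebo=int(float(row["total_placebo"])),
                )
                harm = True if _is_blank(row.get("event_is_harm")) else \
                    str(row["event_is_harm"]).strip().lower() in ("1", "true", "yes")
                effect = smd_from_dichotomous(
                    ds, event_is_harm=harm, study_id=study_id,
                    category=row["category"], region=row["region"],
                )
            else:
                raise ValueError(f"unknown outcome_type {row['outcome_type']!r}")
        except (ValueError, TypeError) as exc:
            dropped.append((rowno, study_id, str(exc)))
            continue
        effects.append(effect)
    return effects, dropped


def records_to_tsv(records: Sequence[DisclosureRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "placebo_group_id": [r.placebo_group_id for r in records],
            "category": [r.category for r in records],
            "matched_keywords": [";".join(r.matched_keywords) for r in records],
            "escalated": [r.escalated for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def effects_to_tsv(effects: Sequence[StudyEffect], path: str | Path) -> None:
    pd.DataFrame(
        {
            "study_id": [e.study_id for e in effects],
            "smd": [e.smd for e in effects],
            "var_smd": [e.var_smd for e in effects],
            "se_smd": [e.se_smd for e in effects],
            "source": [e.source for e in effects],
            "category": [e.category for e in effects],
            "region": [e.region for e in effects],
        }
    ).to_csv(path, sep="\t", index=False)


def read_effects_tsv(path: str | Path) -> list[StudyEffect]:
    df = pd.read_csv(path, sep="\t", dtype={"study_id": str})
    effects = []
    for idx, row in df.iterrows():
        try:
            effects.append(
                StudyEffect(
                    study_id=str(row["study_id"]),
                    smd=float(row["smd"]),
                    var_smd=float(row["var_smd"]),
                    source=str(row["source"]),
                    category=None if _is_blank(row.get("category")) else str(row["category"]),
                    region=None if _is_blank(row.get("region")) else str(row["region"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: row {idx + 2}: {exc}") from exc
    return effects
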
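# pilblind

Tools for analysing how placebo-information disclosure in participant
information leaflets (PILs) relates to blinding success and trial outcomes
in placebo-controlled trials:

- **disclosure_coding** — rule-based coding of leaflet text describing the
  control intervention into three categories (FD: full disclosure, DD:
  deceptive/neutral-label disclosure, MI: missing information), category
  summaries, and a 2×2 chi-square comparison.
- **blinding_index** — Bang's blinding index per arm with multinomial-
  difference standard errors and Wald CIs, threshold classification
  (random guess / unblinded / opposite guess), the nine-scenario
  classification of (experimental, control) status pairs, and a
  Shapiro-Wilk-gated t-test / Mann-Whitney comparison of index
  distributions between groups.
- **effect_size** — Hedges' g from continuous summaries, SMD from
  dichotomous summaries via SMD = (√3/π)·ln OR, shared-arm splitting for
  multi-arm trials, and deterministic outcome selection.
- **meta_analysis** — DerSimonian-Laird random-effects pooling under
  generic inverse variance, subgroup-difference testing (subtotals as
  studies), and plain-text forest tables.
- **synthetic_trials** — seeded synthetic corpora (leaflet snippets, guess
  tables, outcome summaries) with an analytically calibratable
  participant-guess model, plus parameter-recovery checks over the full
  pipeline.
- **cli / pipeline** — input validation, orchestration, and JSON/TSV
  reporting.

## CLI

```bash
# generate a seeded synthetic corpus
pilblind simulate --seed 1 --out corpus/

# run every stage end to end
pilblind run-all --snippets corpus/snippets.jsonl \
                 --guesses corpus/guesses.csv \
                 --outcomes corpus/outcomes.csv \
                 --out out/
```

Individual stages are available as `pilblind code | blinding | effects |
meta`. Outputs land in the `--out` directory: disclosure records and
category summary, per-arm blinding assessments and the scenario grid,
per-study effects, subgroup meta-analysis JSON, a forest table, and a run
log accounting for every dropped record. Exit codes: 0 success, 1 success
with warnings, 2 validation failure, 3 stage failure.

Input schemas: snippets as JSONL with `pil_id`, `placebo_group_id`,
`text`, `region`; guesses as CSV with one row per arm (`study_id, arm,
n_guess_real, n_guess_placebo, n_dont_know, category, region`); outcomes
as CSV with one row per comparison (continuous mean/SD/n or dichotomous
events/total per arm). The keyword rule set for disclosure coding can be
overridden with `--rules rules.json` (tiers `fd`, `dd`, `fd_escalation`).

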
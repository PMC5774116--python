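import pytest

from pilblind.disclosure_coding import RuleSet
from pilblind.synthetic_trials import SimulationConfig, generate_corpus


@pytest.fixture(scope="session")
def rules() -> RuleSet:
    return RuleSet.default()


@pytest.fixture(scope="session")
def default_corpus():
    return generate_corpus(SimulationConfig(seed=12345))


@pytest.fixture
def corpus_files(tmp_path, default_corpus):
    """Write the default corpus to disk in the pipeline's input formats."""
    from pilblind import io as pio

    snippets = tmp_path / "snippets.jsonl"
    guesses = tmp_path / "guesses.csv"
    outcomes = tmp_path / "outcomes.csv"
    pio.write_snippets_jsonl(default_corpus.snippets, snippets)
    default_corpus.guess_tables.to_csv(guesses, index=False)
    default_corpus.outcomes.to_csv(outcomes, index=False)
    return {"snippets": snippets, "guesses": guesses, "outcomes": outcomes}
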
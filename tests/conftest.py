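import hypothesis
import pytest

from inka import synthetic

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_experiment():
    """A small generated experiment shared by read-only tests."""
    return synthetic.generate(
        seed=42, n_kinases=12, n_substrates=15, kb_coverage=0.75, n_samples=2
    )


@pytest.fixture(scope="session")
def toy_bundle(toy_experiment):
    """(experiment, knowledgebase, merged table) for the toy experiment."""
    return toy_experiment, toy_experiment.knowledgebase(), toy_experiment.merged_table()


def write_tsv(path, text):
    """Write a literal tab-separated fixture; '|' separates columns."""
    lines = [line.strip().replace("|", "\t") for line in text.strip().splitlines()]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
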
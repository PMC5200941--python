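import pytest
from hypothesis import settings

from trialaudit.dates import PartialDate
from trialaudit.export import run_pipeline
from trialaudit.synthetic import demo_spec, generate_corpus

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")

AS_OF = PartialDate(2016, 10)


@pytest.fixture(scope="session")
def demo_corpus():
    """The built-in demo corpus: (trials, citations, ground_truth)."""
    return generate_corpus(demo_spec())


@pytest.fixture(scope="session")
def demo_audit(demo_corpus):
    """A full pipeline run over the demo corpus."""
    trials, citations, _ = demo_corpus
    return run_pipeline(trials, citations, as_of=AS_OF)
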
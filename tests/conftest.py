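import pytest

from abspec.synthetic import CorpusSpec, corpus_to_datasets, generate_corpus


@pytest.fixture(scope="session")
def corpus20():
    return generate_corpus(CorpusSpec(n_articles=20, seed=11))


@pytest.fixture(scope="session")
def datasets20(corpus20):
    return corpus_to_datasets(corpus20)
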
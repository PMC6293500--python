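import numpy as np
import pytest

from rlda.preprocess import TokenizedCorpus
from rlda.synthetic import GeneratorConfig, generate


@pytest.fixture(scope="session")
def tiny_corpus() -> TokenizedCorpus:
    """Six tiny documents over a handful of words."""
    docs = [
        ["cell", "tumor", "cell", "growth"],
        ["tumor", "cell", "tumor"],
        ["insulin", "glucose", "insulin"],
        ["glucose", "insulin", "glucose", "insulin"],
        ["cell", "growth", "tumor"],
        ["insulin", "glucose"],
    ]
    return TokenizedCorpus.from_token_lists(docs)


@pytest.fixture(scope="session")
def separated_corpus():
    """A 5-topic corpus sampled from the generative process, with ground truth.

    Near-single-topic documents (small alpha_true) over sparse topics give a
    clearly separated regime in which the sampler should recover the topics.
    """
    config = GeneratorConfig(K_true=5, vocab_size=100, M=300,
                             doc_length_mean=120.0, alpha_true=0.05,
                             beta_true=0.01, seed=101)
    collection, truth = generate(config)
    return collection, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
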
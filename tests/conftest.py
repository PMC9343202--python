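import numpy as np
import pytest

from mirsite.embedding import EmbeddingTable, SkipGramConfig, build_corpus, train_skipgram
from mirsite.sequence_io import Alphabet
from mirsite.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture
def alphabet() -> Alphabet:
    return Alphabet(unknown_policy="reject")


@pytest.fixture(scope="session")
def fixture_corpus() -> list[str]:
    """100 random 22-nt sequences (session-wide embedding fixture)."""
    rng = np.random.default_rng(12345)
    return ["".join(rng.choice(list("ACGU"), size=22)) for _ in range(100)]


@pytest.fixture(scope="session")
def small_table(fixture_corpus) -> EmbeddingTable:
    """A d=8 skip-gram table trained briefly on the fixture corpus."""
    cfg = SkipGramConfig(dim=8, epochs=2, seed=11)
    return train_skipgram(build_corpus(fixture_corpus), cfg)


@pytest.fixture(scope="session")
def tiny_dataset():
    """200 balanced noise-free synthetic pairs."""
    cfg = SyntheticConfig(n_positive=100, n_negative=100, rng_seed=42)
    dataset, mirna_corpus, cts_corpus = generate_dataset(cfg)
    return dataset, mirna_corpus, cts_corpus


def random_table(rng, dim=6) -> EmbeddingTable:
    return EmbeddingTable(
        molecule="miRNA",
        input_vectors=rng.normal(size=(4, dim)),
        output_vectors=rng.normal(size=(4, dim)),
    )
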
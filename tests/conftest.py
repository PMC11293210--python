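import numpy as np
import pytest

from gptriple.synthetic_data import GenConfig, generate_corpus, relation_schema


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_corpus():
    """Tiny mixed corpus shared across tests (deterministic)."""
    cfg = GenConfig(
        n_sentences=60,
        seed=99,
        pattern_mix={"Normal": 0.5, "SEO": 0.3, "EPO": 0.2},
    )
    examples, manifest = generate_corpus(cfg)
    return cfg, examples, manifest


@pytest.fixture(scope="session")
def small_schema(small_corpus):
    cfg, _, _ = small_corpus
    return relation_schema(cfg)
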
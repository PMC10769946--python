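import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import topicplant as tp

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tiny_corpus() -> list[tp.Document]:
    """Six labeled documents over a small vocabulary, by hand."""
    return [
        tp.Document("d1", ("apple", "apple", "insulin", "retina"), "positive"),
        tp.Document("d2", ("insulin", "kidney", "kidney", "kidney"), "positive"),
        tp.Document("d3", ("apple", "banana", "banana"), "negative"),
        tp.Document("d4", ("banana", "liver", "liver", "apple"), "negative"),
        tp.Document("d5", ("retina", "insulin", "apple"), "positive"),
        tp.Document("d6", ("liver", "banana", "kidney"), "negative"),
    ]


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated corpus shared by fit-quality tests."""
    cfg = tp.SimConfig(M_train=150, M_test=40, V=200, K_true=3, alpha_true=0.1,
                       beta_concentration=0.05, doc_len_mean=60, seed=11)
    train, test, truth = tp.generate_corpus(cfg)
    return cfg, train, test, truth


def random_corpus(rng: np.random.Generator, m: int, v: int,
                  mean_len: int = 30) -> list[tp.Document]:
    """Random multinomial documents over a skewed word distribution."""
    word_p = rng.dirichlet(np.full(v, 0.3))
    docs = []
    for i in range(m):
        n = rng.poisson(mean_len) + 1
        counts = rng.multinomial(n, word_p)
        toks = [f"w{t}" for t in np.flatnonzero(counts) for _ in range(counts[t])]
        label = "positive" if i % 2 == 0 else "negative"
        docs.append(tp.Document(f"doc{i}", tuple(toks), label))
    return docs
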
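"""Synthetic labeled corpora from the LDA generative process.

No real clinical corpus ships with this package, so every downstream module
is exercised on corpora sampled from the very model the fit assumes: per
document, topic proportions theta ~ Dirichlet(alpha_true), a Poisson token
count, and per token a topic z ~ Categorical(theta) and a word
w ~ Categorical(beta_true[z]).  On top of the generative process the module
adds the three features of the study data that matter downstream:

* outcome labels statistically dependent on a subset of "signal" topics
  through a logistic link, with a label-noise floor, targeting a roughly
  balanced positive/negative split;
* controlled out-of-vocabulary injection into the held-out documents, so
  the transplantation smoothing path is exercised at realistic unseen-word
  rates (roughly 12-16% of held-out vocabulary);
* optional product-name/ingredient-name alias pairs with a matching
  synonym map, as a round-trip fixture for token normalization.

Defaults give ~1,000 training documents over a 2,000-word vocabulary with
>=95% matrix sparsity — a scaled-down analogue of merged outpatient-note
corpora (hundreds to thousands of documents, 8k-14k words, ~99% sparsity).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.optimize

from .corpus import Document, SynonymMap, write_corpus

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimConfig:
    M_train: int = 1000
    M_test: int = 200
    V: int = 2000
    K_true: int = 5
    alpha_true: float = 0.1
    doc_len_mean: float = 80.0
    beta_concentration: float = 0.05
    signal_topics: tuple[int, ...] = (0, 1)
    signal_strength: float = 8.0
    label_noise: float = 0.05
    unseen_fraction: float = 0.12
    synonym_pairs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M_train < 1 or self.M_test < 0 or self.V < 1 or self.K_true < 1:
            raise ValueError("corpus sizes must be positive")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        if not 0.0 <= self.unseen_fraction < 1.0:
            raise ValueError("unseen_fraction must be in [0, 1)")
        if self.alpha_true <= 0 or self.beta_concentration <= 0 or self.doc_len_mean <= 0:
            raise ValueError("alpha_true, beta_concentration, doc_len_mean must be positive")
        if any(k < 0 or k >= self.K_true for k in self.signal_topics):
            raise ValueError("signal_topics must be a subset of 0..K_true-1")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class GroundTruth:
    """The latent quantities the generator sampled (train rows, then test)."""

    beta_true: np.ndarray      # K_true x V topic-word probabilities
    theta_true: np.ndarray     # (M_train + M_test) x K_true topic proportions
    z_counts: np.ndarray       # per-document topic assignment counts
    labels_true: list[str]
    M_train: int
    synonym_map: SynonymMap | None = None


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def label_documents(
    theta_true: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> list[str]:
    """Draw outcome labels dependent on the signal topics' total proportion.

    p(positive) = logistic(signal_strength * (s - c)) clamped to
    [label_noise, 1 - label_noise], where s is the per-document sum of the
    signal topics' proportions.  The centering offset c is calibrated on
    the sample so the expected positive rate is exactly 1/2 (the median of
    s is the natural first guess, but the clamped logistic is asymmetric
    around it when s is skewed); the clamp keeps a noise floor on both
    classes.
    """
    if not cfg.signal_topics:
        raise ValueError("signal_topics must be nonempty")
    s = theta_true[:, list(cfg.signal_topics)].sum(axis=1)

    def positive_rate(c: float) -> float:
        p = np.clip(_logistic(cfg.signal_strength * (s - c)),
                    cfg.label_noise, 1.0 - cfg.label_noise)
        return float(p.mean())

    center = float(np.median(s))
    if cfg.signal_strength > 0 and len(s) > 1:
        lo, hi = float(s.min()) - 1.0, float(s.max()) + 1.0
        if positive_rate(lo) > 0.5 > positive_rate(hi):  # rate decreases in c
            center = scipy.optimize.brentq(
                lambda c: positive_rate(c) - 0.5, lo, hi, xtol=1e-12)
    p = np.clip(_logistic(cfg.signal_strength * (s - center)),
                cfg.label_noise, 1.0 - cfg.label_noise)
    draws = rng.random(len(p))
    return ["positive" if d < pi else "negative" for d, pi in zip(draws, p)]


def inject_unseen(
    test_docs: list[Document],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> list[Document]:
    """Replace a random fraction of held-out tokens with novel word symbols.

    Replacement (not appending) keeps document lengths fixed, isolating the
    smoothing effect.  Novel symbols are drawn from a pool sized so the
    TYPE-level out-of-vocabulary percentage of the held-out corpus lands
    near the token-level replacement fraction.
    """
    f = cfg.unseen_fraction
    if f == 0.0 or not test_docs:
        return list(test_docs)
    n_types = len({t for d in test_docs for t in d.tokens})
    pool_size = max(1, round(n_types * f / (1.0 - f)))
    pool = [f"unseen{j:05d}" for j in range(pool_size)]
    out = []
    for d in test_docs:
        toks = list(d.tokens)
        replace = rng.random(len(toks)) < f
        for i in np.flatnonzero(replace):
            toks[i] = pool[rng.integers(pool_size)]
        out.append(Document(doc_id=d.doc_id, tokens=tuple(toks), label=d.label))
    return out


def _apply_synonyms(
    docs: list[Document],
    vocab_words: list[str],
    n_pairs: int,
    rng: np.random.Generator,
) -> tuple[list[Document], SynonymMap]:
    """Alias some vocabulary words ('product names') in ~half their occurrences."""
    chosen = rng.choice(len(vocab_words), size=n_pairs, replace=False)
    alias_of = {vocab_words[i]: f"brand{j:03d}" for j, i in enumerate(chosen)}
    out = []
    for d in docs:
        toks = [
            alias_of[t] if t in alias_of and rng.random() < 0.5 else t
            for t in d.tokens
        ]
        out.append(Document(doc_id=d.doc_id, tokens=tuple(toks), label=d.label))
    synmap = SynonymMap({alias: word for word, alias in alias_of.items()})
    return out, synmap


def generate_corpus(cfg: SimConfig) -> tuple[list[Document], list[Document], GroundTruth]:
    """Sample a labeled train corpus and a held-out test corpus.

    Fully deterministic given cfg.seed.  Test documents additionally
    receive unseen-word injection (after ground truth is recorded) so
    their vocabulary is only partially covered by any model trained on
    the training half.
    """
    rng = np.random.default_rng(cfg.seed)
    K, V = cfg.K_true, cfg.V
    M = cfg.M_train + cfg.M_test
    words = [f"w{t:05d}" for t in range(V)]

    beta_true = rng.dirichlet(np.full(V, cfg.beta_concentration), size=K)
    theta_true = rng.dirichlet(np.full(K, cfg.alpha_true), size=M)
    lengths = rng.poisson(cfg.doc_len_mean, size=M)

    docs: list[Document] = []
    z_counts = np.zeros((M, K), dtype=np.int64)
    labels = label_documents(theta_true, cfg, rng)
    for m in range(M):
        zc = rng.multinomial(lengths[m], theta_true[m])
        z_counts[m] = zc
        toks: list[str] = []
        for k in np.flatnonzero(zc):
            wc = rng.multinomial(zc[k], beta_true[k])
            for t in np.flatnonzero(wc):
                toks.extend([words[t]] * wc[t])
        rng.shuffle(toks)
        prefix = "tr" if m < cfg.M_train else "te"
        docs.append(Document(doc_id=f"{prefix}{m:05d}", tokens=tuple(toks),
                             label=labels[m]))

    train = docs[:cfg.M_train]
    test = docs[cfg.M_train:]
    synmap = None
    if cfg.synonym_pairs > 0:
        train, synmap = _apply_synonyms(train, words, cfg.synonym_pairs, rng)
    test = inject_unseen(test, cfg, rng)

    truth = GroundTruth(beta_true=beta_true, theta_true=theta_true,
                        z_counts=z_counts, labels_true=labels,
                        M_train=cfg.M_train, synonym_map=synmap)
    n_pos = sum(1 for l in labels if l == "positive")
    logger.info("simulated corpus: %d train + %d test docs, V=%d, K_true=%d, "
                "%.1f%% positive", cfg.M_train, cfg.M_test, V, K, 100.0 * n_pos / M)
    return train, test, truth


def write_ground_truth(truth: GroundTruth, cfg: SimConfig, out_dir: str | Path) -> None:
    """Write the generator bundle: corpora-adjacent TSVs plus a config echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "beta_true.tsv", truth.beta_true, delimiter="\t")
    np.savetxt(out / "theta_true.tsv", truth.theta_true, delimiter="\t")
    with open(out / "labels_true.tsv", "w") as fh:
        for m, label in enumerate(truth.labels_true):
            split = "train" if m < truth.M_train else "test"
            fh.write(f"{m}\t{split}\t{label}\n")
    cfg.to_json(out / "sim_config.json")
    if truth.synonym_map is not None:
        truth.synonym_map.write_tsv(out / "synonyms.tsv")


def write_simulation(
    cfg: SimConfig, out_dir: str | Path
) -> tuple[list[Document], list[Document], GroundTruth]:
    """Generate and persist a full simulation bundle under out_dir."""
    train, test, truth = generate_corpus(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_corpus(train, out / "train.corpus.tsv")
    write_corpus(test, out / "test.corpus.tsv")
    write_ground_truth(truth, cfg, out)
    return train, test, truth
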
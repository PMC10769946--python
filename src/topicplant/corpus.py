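"""Bag-of-words corpus handling: documents, vocabulary, document-term matrix.

A corpus here is a set of per-patient documents — each patient's clinical
notes merged into a single bag of tokens, optionally tagged with a binary
outcome label.  This module turns such documents into the sparse M x V
term-frequency matrix that topic modeling consumes, applies drug-name
normalization (product name -> ingredient name), and computes the corpus
descriptive statistics used for data-quality assessment (sparsity, IDF
distribution summaries).
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp
import scipy.stats

logger = logging.getLogger(__name__)

LABELS = ("positive", "negative", "unknown")
_LABEL_ALIASES = {
    "pos": "positive", "positive": "positive", "1": "positive",
    "neg": "negative", "negative": "negative", "0": "negative",
    "unknown": "unknown", "na": "unknown", "": "unknown",
}


def canonical_label(label: str) -> str:
    """Map a label spelling ('pos', '1', ...) to one of positive/negative/unknown."""
    try:
        return _LABEL_ALIASES[str(label).strip().lower()]
    except KeyError:
        raise ValueError(f"unrecognized label {label!r}; expected one of {LABELS}") from None


@dataclass(frozen=True)
class Document:
    """One patient's merged notes as a token multiset with an outcome label."""

    doc_id: str
    tokens: tuple[str, ...]
    label: str = "unknown"

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be nonempty")
        if self.label not in LABELS:
            object.__setattr__(self, "label", canonical_label(self.label))

    @property
    def n_tokens(self) -> int:
        """N: total token count of the document."""
        return len(self.tokens)

    def term_frequencies(self) -> Counter:
        return Counter(self.tokens)


class SynonymMap:
    """Surface-form -> canonical-form token map (drug product -> ingredient).

    The map must be acyclic after one application: no canonical token may
    itself be a key (a key mapping to itself is allowed and is a no-op), so
    applying the map is idempotent.
    """

    def __init__(self, entries: Mapping[str, str]):
        entries = dict(entries)
        for surface, canon in entries.items():
            if canon in entries and canon != surface:
                raise ValueError(
                    f"synonym map is not idempotent: canonical form {canon!r} is itself a key"
                )
        self.entries = entries

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, token: str) -> str:
        return self.entries.get(token, token)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SynonymMap":
        """Read a two-column tab-separated surface<TAB>canonical file."""
        entries = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            surface, canon = line.split("\t")[:2]
            entries[surface] = canon
        return cls(entries)

    def write_tsv(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{s}\t{c}\n" for s, c in sorted(self.entries.items()))
        )


def normalize_tokens(tokens: Sequence[str], synonym_map: SynonymMap | Mapping[str, str]) -> list[str]:
    """Replace every token that is a known surface form by its canonical form.

    Unknown tokens pass through unchanged; output length equals input length.
    Idempotent by the SynonymMap invariant.
    """
    if not isinstance(synonym_map, SynonymMap):
        synonym_map = SynonymMap(synonym_map)
    return [synonym_map.get(t) for t in tokens]


def merge_documents(
    notes: Sequence[tuple[str, Sequence[str]]],
    doc_id: str | None = None,
    label: str = "unknown",
) -> Document:
    """Merge one patient's clinical notes into a single Document.

    ``notes`` is a list of (note_id, tokens).  Note ids of the form
    ``patient/visit`` share the patient identifier before the slash; all
    notes must belong to the same patient.  Token counts add (multiset
    union), so N of the result is the sum of the note lengths.
    """
    if not notes:
        raise ValueError("cannot merge an empty note list: patient has no notes")
    patients = {nid.split("/", 1)[0] for nid, _ in notes}
    if len(patients) != 1:
        raise ValueError(f"notes belong to multiple patients: {sorted(patients)}")
    if doc_id is None:
        doc_id = patients.pop()
    merged: list[str] = []
    for _, toks in notes:
        merged.extend(toks)
    return Document(doc_id=doc_id, tokens=tuple(merged), label=label)


@dataclass
class Vocabulary:
    """Ordered distinct word list with per-word document frequencies."""

    words: list[str]
    doc_freq: np.ndarray

    def __post_init__(self) -> None:
        self._index = {w: t for t, w in enumerate(self.words)}
        if len(self._index) != len(self.words):
            raise ValueError("vocabulary words must be unique")
        self.doc_freq = np.asarray(self.doc_freq, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def index(self, word: str) -> int:
        return self._index[word]

    def get_index(self, word: str, default: int = -1) -> int:
        return self._index.get(word, default)

    @property
    def size(self) -> int:
        return len(self.words)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for t, w in enumerate(self.words):
                fh.write(f"{t}\t{w}\t{self.doc_freq[t]}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Vocabulary":
        words, dfs = [], []
        for line in Path(path).read_text().splitlines():
            _, w, df = line.rstrip("\n").split("\t")
            words.append(w)
            dfs.append(int(df))
        return cls(words=words, doc_freq=np.array(dfs, dtype=np.int64))


@dataclass
class DocTermMatrix:
    """Sparse M x V nonnegative integer count matrix with row/column metadata."""

    counts: sp.csr_matrix
    row_ids: list[str]
    vocab: Vocabulary
    labels: list[str]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.row_ids), len(self.vocab)):
            raise ValueError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.row_ids)} documents x {len(self.vocab)} words"
            )
        if len(self.labels) != len(self.row_ids):
            raise ValueError("labels and row_ids length mismatch")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_docs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_words(self) -> int:
        return self.counts.shape[1]

    def row_totals(self) -> np.ndarray:
        """In-vocabulary token count per document."""
        return np.asarray(self.counts.sum(axis=1)).ravel()


def build_matrix(docs: Sequence[Document], min_df: int = 2) -> DocTermMatrix:
    """Index documents into an M x V term-frequency matrix.

    The vocabulary holds exactly the distinct tokens appearing in at least
    ``min_df`` documents, in lexicographic order (deterministic matrices).
    Tokens below the document-frequency cutoff are dropped from the counts.
    """
    if min_df < 1:
        raise ValueError("min_df must be >= 1")
    if not docs:
        raise ValueError("cannot build a matrix from zero documents")
    ids = [d.doc_id for d in docs]
    if len(set(ids)) != len(ids):
        raise ValueError("doc_ids must be unique within a corpus")

    df_counter: Counter = Counter()
    tfs = []
    for d in docs:
        tf = d.term_frequencies()
        tfs.append(tf)
        df_counter.update(tf.keys())

    words = sorted(w for w, df in df_counter.items() if df >= min_df)
    if not words:
        raise ValueError(f"vocabulary empty after min_df={min_df} filtering")
    vocab = Vocabulary(words=words, doc_freq=np.array([df_counter[w] for w in words]))

    rows, cols, data = [], [], []
    for m, tf in enumerate(tfs):
        for w, c in tf.items():
            t = vocab.get_index(w)
            if t >= 0:
                rows.append(m)
                cols.append(t)
                data.append(c)
    counts = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(docs), len(vocab)), dtype=np.int64
    )
    logger.info("indexed corpus: M=%d documents, V=%d words, nnz=%d",
                counts.shape[0], counts.shape[1], counts.nnz)
    return DocTermMatrix(counts=counts, row_ids=ids, vocab=vocab,
                         labels=[d.label for d in docs])


def sparsity(dtm: DocTermMatrix) -> float:
    """Percentage of blank (zero) cells in the M x V matrix."""
    m, v = dtm.counts.shape
    if m * v == 0:
        raise ValueError("matrix has zero cells")
    n_nonzero = int((dtm.counts.data != 0).sum())
    return 100.0 * (m * v - n_nonzero) / (m * v)


@dataclass(frozen=True)
class IdfSummary:
    """Summary statistics of the per-word IDF distribution of a training matrix.

    Skewness is the sample moment coefficient g1 and kurtosis the Fisher
    excess g2; quartiles use linear interpolation between order statistics
    (the common "type 7" rule); sd is the unbiased (n-1) standard deviation.
    """

    skewness: float
    kurtosis: float
    min: float
    q1: float
    median: float
    mean: float
    q3: float
    max: float
    sd: float
    log_base: str = "e"

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {k: getattr(self, k) for k in
                   ("skewness", "kurtosis", "min", "q1", "median", "mean", "q3", "max", "sd")}
        payload["log_base"] = self.log_base
        payload["conventions"] = "skewness=g1, kurtosis=Fisher excess g2, quartiles=linear (type 7)"
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def idf_values(dtm: DocTermMatrix, log_base: str = "e") -> np.ndarray:
    """IDF[t] = log(M / DF[t]) per vocabulary word (natural log by default)."""
    m = dtm.n_docs
    if m == 0:
        raise ValueError("IDF undefined for an empty corpus")
    df = np.asarray(dtm.vocab.doc_freq, dtype=float)
    if (df < 1).any():
        raise ValueError("every vocabulary word must appear in at least one document")
    idf = np.log(m / df)
    if log_base == "10":
        idf = idf / math.log(10)
    elif log_base != "e":
        raise ValueError("log_base must be 'e' or '10'")
    return idf


def idf_summary(dtm: DocTermMatrix, log_base: str = "e") -> IdfSummary:
    """Distribution summary of the IDF values over the vocabulary."""
    idf = idf_values(dtm, log_base=log_base)
    q1, med, q3 = np.quantile(idf, [0.25, 0.5, 0.75])
    return IdfSummary(
        skewness=float(scipy.stats.skew(idf, bias=True)),
        kurtosis=float(scipy.stats.kurtosis(idf, fisher=True, bias=True)),
        min=float(idf.min()),
        q1=float(q1),
        median=float(med),
        mean=float(idf.mean()),
        q3=float(q3),
        max=float(idf.max()),
        sd=float(idf.std(ddof=1)) if idf.size > 1 else 0.0,
        log_base=log_base,
    )


def split_holdout(
    docs: Sequence[Document],
    test_fraction: float,
    seed: int,
    stratify: bool = True,
) -> tuple[list[Document], list[Document]]:
    """Partition labeled documents into train and test sets.

    Stratified by label by default so both sides keep the class ratio
    (per-class test counts are rounded to the nearest document).  The
    partition is disjoint, exhaustive, and deterministic given ``seed``.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if not stratify:
        order = rng.permutation(len(docs))
        n_test = max(1, round(len(docs) * test_fraction))
        test_idx = set(order[:n_test].tolist())
        train = [d for i, d in enumerate(docs) if i not in test_idx]
        test = [d for i, d in enumerate(docs) if i in test_idx]
        return train, test

    by_label: dict[str, list[int]] = {}
    for i, d in enumerate(docs):
        by_label.setdefault(d.label, []).append(i)
    test_idx = set()
    for label in sorted(by_label):
        idx = by_label[label]
        if len(idx) < 2:
            raise ValueError(f"label class {label!r} has fewer than 2 documents")
        n_test = max(1, round(len(idx) * test_fraction))
        chosen = rng.permutation(len(idx))[:n_test]
        test_idx.update(idx[i] for i in chosen)
    train = [d for i, d in enumerate(docs) if i not in test_idx]
    test = [d for i, d in enumerate(docs) if i in test_idx]
    logger.info("holdout split: %d train / %d test (fraction %.3f, stratified=%s)",
                len(train), len(test), test_fraction, stratify)
    return train, test


# ---------------------------------------------------------------------------
# I/O: line-delimited corpora, Matrix Market matrices


def read_corpus(path: str | Path) -> list[Document]:
    """Read a line-delimited corpus.

    Two dialects are accepted, detected per line:
      * plain:  ``doc_id<TAB>label<TAB>tok tok tok ...``
      * JSON lines: ``{"id": ..., "label": ..., "tokens": [...]}``
    """
    docs = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("{"):
            rec = json.loads(line)
            docs.append(Document(doc_id=str(rec["id"]),
                                 tokens=tuple(rec["tokens"]),
                                 label=canonical_label(rec.get("label", "unknown"))))
        else:
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed corpus line: {line[:80]!r}")
            doc_id, label = parts[0], canonical_label(parts[1])
            tokens = tuple(parts[2].split()) if len(parts) > 2 and parts[2] else ()
            docs.append(Document(doc_id=doc_id, tokens=tokens, label=label))
    return docs


def write_corpus(docs: Iterable[Document], path: str | Path) -> None:
    with open(path, "w") as fh:
        for d in docs:
            fh.write(f"{d.doc_id}\t{d.label}\t{' '.join(d.tokens)}\n")


def write_matrix(dtm: DocTermMatrix, prefix: str | Path) -> None:
    """Write counts (Matrix Market), vocabulary TSV, and row manifest TSV."""
    prefix = Path(prefix)
    scipy.io.mmwrite(str(prefix) + ".mtx", dtm.counts.tocoo(), field="integer")
    dtm.vocab.write_tsv(str(prefix) + ".vocab.tsv")
    with open(str(prefix) + ".rows.tsv", "w") as fh:
        for m, (doc_id, label) in enumerate(zip(dtm.row_ids, dtm.labels)):
            fh.write(f"{m}\t{doc_id}\t{label}\n")


def read_matrix(prefix: str | Path) -> DocTermMatrix:
    prefix = Path(prefix)
    counts = sp.csr_matrix(scipy.io.mmread(str(prefix) + ".mtx"), dtype=np.int64)
    vocab = Vocabulary.read_tsv(str(prefix) + ".vocab.tsv")
    row_ids, labels = [], []
    for line in Path(str(prefix) + ".rows.tsv").read_text().splitlines():
        _, doc_id, label = line.rstrip("\n").split("\t")
        row_ids.append(doc_id)
        labels.append(label)
    return DocTermMatrix(counts=counts, row_ids=row_ids, vocab=vocab, labels=labels)
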
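"""Transplantation: topic weights for held-out documents.

A classifier trained on the M x K document-topic matrix of the training
corpus can only score a held-out document if that document is expressed in
the same K topic dimensions.  Transplantation computes, for each held-out
document m and topic k,

    gamma_tilde[m, k] = sum over the document's words of TF * exp(log_beta[k, t])

where t indexes the word in the TRAINING vocabulary.  Words absent from the
training vocabulary ("unseen data" — including words dropped from training
by the document-frequency cutoff) have no topic-word row; their log weight
is fixed at a large negative smoothing constant (-100.0 by default) so each
unseen token contributes exactly exp(smoothing_log) per count unit, a
numerically negligible amount.

Note the scale caveat: transplanted weights are plain TF-weighted sums of
word probabilities, NOT variational Dirichlet parameters — there is no
alpha offset and no digamma weighting — so they are not interchangeable
with training gamma values column-for-column outside a pipeline that keeps
the two roles separate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus import Document, DocTermMatrix, Vocabulary
from .lda import LOG_FLOOR_DEFAULT, DocTopicMatrix, TopicModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoverageReport:
    """How much of the held-out data the training topic model covers.

    in_tr_pct : percentage of test words found in the training vocabulary.
    out_tr_pct : complementary percentage (the "unseen data").
    basis : 'types' counts distinct words, 'tokens' counts occurrences.
    """

    in_tr_pct: float
    out_tr_pct: float
    basis: str

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({"inTR%": self.in_tr_pct, "outTR%": self.out_tr_pct,
                           "basis": self.basis}, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class TransplantedFeatures:
    """Transplanted M_test x K topic weights plus the coverage report."""

    gamma_tilde: np.ndarray
    row_ids: list[str]
    labels: list[str]
    coverage: CoverageReport

    def as_doc_topic(self) -> DocTopicMatrix:
        """View as a DocTopicMatrix so the feature TSV layout is shared."""
        return DocTopicMatrix(gamma=self.gamma_tilde, row_ids=self.row_ids,
                              labels=self.labels)


def coverage(
    test_docs: Iterable[Document],
    training_vocab: Vocabulary,
    basis: str = "types",
) -> CoverageReport:
    """Percentage of held-out words present in the training vocabulary."""
    if basis not in ("types", "tokens"):
        raise ValueError("basis must be 'types' or 'tokens'")
    docs = list(test_docs)
    if not docs:
        raise ValueError("coverage undefined for an empty test corpus")
    if basis == "types":
        types = {t for d in docs for t in d.tokens}
        if not types:
            raise ValueError("coverage undefined: test corpus has no tokens")
        n_in = sum(1 for t in types if t in training_vocab)
        total = len(types)
    else:
        total = sum(d.n_tokens for d in docs)
        if total == 0:
            raise ValueError("coverage undefined: test corpus has no tokens")
        n_in = sum(1 for d in docs for t in d.tokens if t in training_vocab)
    in_pct = 100.0 * n_in / total
    return CoverageReport(in_tr_pct=in_pct, out_tr_pct=100.0 - in_pct, basis=basis)


def transplant_gamma(
    test_dtm: DocTermMatrix,
    model: TopicModel,
    smoothing_log: float = LOG_FLOOR_DEFAULT,
    row_normalize: bool = False,
) -> TransplantedFeatures:
    """Compute transplanted document-topic weights for held-out documents.

    ``test_dtm`` holds counts over the TEST vocabulary; words are matched to
    the training vocabulary by string, and unmatched words fall back to the
    exp(smoothing_log) weight for every topic.  The output always has K
    columns — the dimension contract that makes the features consumable by
    a classifier trained on the training document-topic matrix.

    With ``row_normalize`` each nonzero row is scaled to sum to 1 (off by
    default: the raw formula output is the headline feature).
    """
    if smoothing_log > 0:
        raise ValueError("smoothing_log must be <= 0")
    K = model.K
    counts = test_dtm.counts.tocsr()
    M_test = counts.shape[0]

    # map test vocabulary columns onto training vocabulary columns (-1 = unseen)
    col_map = np.array(
        [model.vocab.get_index(w, -1) for w in test_dtm.vocab.words], dtype=np.int64
    )
    exp_beta = np.exp(model.log_beta)  # (K, V_train)
    unseen_weight = np.exp(smoothing_log)

    gamma_tilde = np.zeros((M_test, K))
    test_word = counts.indices
    tf = counts.data.astype(float)
    doc_idx = np.repeat(np.arange(M_test), np.diff(counts.indptr))
    train_word = col_map[test_word]
    seen = train_word >= 0

    if seen.any():
        contrib = tf[seen, None] * exp_beta[:, train_word[seen]].T  # (nnz_seen, K)
        for k in range(K):
            gamma_tilde[:, k] += np.bincount(doc_idx[seen], weights=contrib[:, k],
                                             minlength=M_test)
    if (~seen).any():
        unseen_tokens = np.bincount(doc_idx[~seen], weights=tf[~seen], minlength=M_test)
        gamma_tilde += unseen_tokens[:, None] * unseen_weight

    if row_normalize:
        totals = gamma_tilde.sum(axis=1, keepdims=True)
        nonzero = totals.ravel() > 0
        gamma_tilde[nonzero] /= totals[nonzero]

    n_types = len(test_dtm.vocab)
    n_seen_types = int((col_map >= 0).sum())
    in_pct = 100.0 * n_seen_types / n_types if n_types else 0.0
    cov = CoverageReport(in_tr_pct=in_pct, out_tr_pct=100.0 - in_pct, basis="types")
    logger.info("transplanted %d documents onto K=%d topics; vocabulary coverage "
                "inTR=%.2f%% outTR=%.2f%% (types)", M_test, K, cov.in_tr_pct,
                cov.out_tr_pct)
    return TransplantedFeatures(
        gamma_tilde=gamma_tilde,
        row_ids=list(test_dtm.row_ids),
        labels=list(test_dtm.labels),
        coverage=cov,
    )
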
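"""Latent Dirichlet allocation fitted by variational EM.

The model: each document draws topic proportions theta ~ Dirichlet(alpha)
(symmetric), each token draws a topic z ~ Categorical(theta) and a word
w ~ Categorical(beta_z), where beta is the K x V topic-word matrix.  The
fit maximizes a variational lower bound on the corpus log likelihood by
coordinate ascent: the E-step optimizes, per document, a Dirichlet
posterior gamma over theta and multinomial responsibilities over token
topic assignments; the M-step re-estimates beta by maximum likelihood
from the expected topic-word counts (zero cells clamped to a log floor
rather than smoothed with a prior, in the style of Blei's original LDA-C).

The document-topic matrix gamma is the feature set handed to downstream
classifiers; the log topic-word matrix is what held-out documents are
"transplanted" onto (see the transplant module).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.special import digamma, gammaln, logsumexp, polygamma, xlogy

from .corpus import DocTermMatrix, Vocabulary

logger = logging.getLogger(__name__)

LOG_FLOOR_DEFAULT = -100.0  # one consistent floor for log 0 across the package


@dataclass(frozen=True)
class LdaConfig:
    """Knobs of the variational EM fit.

    K : number of topics (the document-topic feature dimension).
    alpha : symmetric Dirichlet hyperparameter on topic proportions;
        small values favor sparse per-document topic mixtures.
    estimate_alpha : if True, update alpha by Newton-Raphson each M-step.
    em_rel_tol : relative change of the bound that stops the outer EM loop.
    var_rel_tol : relative change of gamma that stops a document's E-step.
    log_floor : clamp for log-probabilities of zero expected counts.
    """

    K: int = 100
    alpha: float = 0.1
    estimate_alpha: bool = False
    em_max_iter: int = 100
    em_rel_tol: float = 1e-4
    var_max_iter: int = 20
    var_rel_tol: float = 1e-6
    seed: int = 0
    log_floor: float = LOG_FLOOR_DEFAULT

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.em_rel_tol <= 0 or self.var_rel_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.log_floor > 0:
            raise ValueError("log_floor must be <= 0")


@dataclass
class TopicModel:
    """Fitted topic-word structure: K x V log word probabilities per topic."""

    K: int
    alpha: float
    log_beta: np.ndarray
    vocab: Vocabulary

    def __post_init__(self) -> None:
        self.log_beta = np.asarray(self.log_beta, dtype=float)
        if self.log_beta.shape != (self.K, len(self.vocab)):
            raise ValueError("log_beta shape does not match K x V")

    def write_tsv(self, path: str | Path) -> None:
        """Serialize as TSV: a header line (K, alpha, V) then log_beta row-major."""
        with open(path, "w") as fh:
            fh.write(f"#K\t{self.K}\talpha\t{self.alpha!r}\tV\t{len(self.vocab)}\n")
            for k in range(self.K):
                fh.write("\t".join(repr(float(x)) for x in self.log_beta[k]) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path, vocab: Vocabulary) -> "TopicModel":
        lines = Path(path).read_text().splitlines()
        header = lines[0].lstrip("#").split("\t")
        K, alpha, V = int(header[1]), float(header[3]), int(header[5])
        if V != len(vocab):
            raise ValueError(f"model was fitted on V={V} but vocabulary has {len(vocab)} words")
        log_beta = np.array([[float(x) for x in line.split("\t")] for line in lines[1:K + 1]])
        return cls(K=K, alpha=alpha, log_beta=log_beta, vocab=vocab)


@dataclass
class DocTopicMatrix:
    """M x K nonnegative document-topic weights with row metadata.

    For training documents these are variational gamma values (each entry
    >= alpha); for held-out documents, transplanted weights on a different
    scale — the two must not be mixed within one feature column outside a
    pipeline that is explicit about it.
    """

    gamma: np.ndarray
    row_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.gamma.shape[0] != len(self.row_ids) or len(self.labels) != len(self.row_ids):
            raise ValueError("gamma rows, row_ids and labels must align")

    @property
    def K(self) -> int:
        return self.gamma.shape[1]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("doc_id\tlabel\t" + "\t".join(f"topic_{k}" for k in range(self.K)) + "\n")
            for doc_id, label, row in zip(self.row_ids, self.labels, self.gamma):
                fh.write(f"{doc_id}\t{label}\t"
                         + "\t".join(repr(float(x)) for x in row) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DocTopicMatrix":
        lines = Path(path).read_text().splitlines()
        row_ids, labels, rows = [], [], []
        for line in lines[1:]:
            parts = line.split("\t")
            row_ids.append(parts[0])
            labels.append(parts[1])
            rows.append([float(x) for x in parts[2:]])
        return cls(gamma=np.array(rows), row_ids=row_ids, labels=labels)


@dataclass
class VariationalState:
    """Per-document variational posterior.

    gamma_d is the Dirichlet parameter over topic proportions; resp holds,
    for each distinct word of the document (indexed by word_idx into the
    vocabulary), the posterior probability of each topic for that word's
    tokens.  Satisfies gamma_d = alpha + sum_t TF_t * resp[t].
    """

    gamma_d: np.ndarray
    resp: np.ndarray
    word_idx: np.ndarray


@dataclass
class FitDiagnostics:
    bound_per_iter: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False


# ---------------------------------------------------------------------------
# E-step

def _doc_arrays(counts_row: sp.spmatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distinct-word indices and their term frequencies for one document."""
    row = sp.csr_matrix(counts_row)
    return row.indices.astype(np.int64), row.data.astype(float)


def variational_inference(
    doc_counts: sp.spmatrix | np.ndarray,
    model: TopicModel,
    cfg: LdaConfig,
) -> VariationalState:
    """Coordinate-ascent posterior inference for one document.

    Iterates resp[t,k] proportional to exp(digamma(gamma_d[k]) + log_beta[k,t])
    and gamma_d[k] = alpha + sum_t TF_t * resp[t,k] until the relative change
    in gamma_d drops below var_rel_tol.
    """
    word_idx, tf = _doc_arrays(doc_counts)
    K = model.K
    if len(word_idx) == 0:
        return VariationalState(
            gamma_d=np.full(K, model.alpha),
            resp=np.zeros((0, K)),
            word_idx=word_idx,
        )
    n_d = tf.sum()
    gamma_d = np.full(K, model.alpha + n_d / K)
    log_beta_doc = model.log_beta[:, word_idx].T  # (W, K)
    resp = np.full((len(word_idx), K), 1.0 / K)
    for _ in range(cfg.var_max_iter):
        log_resp = digamma(gamma_d)[None, :] + log_beta_doc
        log_resp -= logsumexp(log_resp, axis=1, keepdims=True)
        resp = np.exp(log_resp)
        gamma_new = model.alpha + tf @ resp
        delta = np.abs(gamma_new - gamma_d).sum() / gamma_d.sum()
        gamma_d = gamma_new
        if delta < cfg.var_rel_tol:
            break
    return VariationalState(gamma_d=gamma_d, resp=resp, word_idx=word_idx)


def _e_step_batch(
    counts: sp.csr_matrix,
    log_beta: np.ndarray,
    alpha: float,
    cfg: LdaConfig,
    gamma_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized E-step over all documents at once.

    Works on the flattened nonzero entries of the count matrix; returns the
    M x K gamma matrix and the (nnz, K) responsibilities aligned with
    counts.indices/counts.data.  Equivalent to running variational_inference
    per document to the same tolerance.  ``gamma_init`` warm-starts the
    coordinate ascent (the outer EM loop passes the previous gamma so every
    inner step ascends from the current state and the bound stays monotone
    even when var_max_iter truncates the loop).
    """
    M = counts.shape[0]
    K = log_beta.shape[0]
    doc_idx = np.repeat(np.arange(M), np.diff(counts.indptr))
    word_idx = counts.indices
    tf = counts.data.astype(float)
    n_d = np.asarray(counts.sum(axis=1)).ravel().astype(float)

    if gamma_init is not None:
        gamma = np.array(gamma_init, dtype=float)
    else:
        gamma = np.full((M, K), alpha) + (n_d / K)[:, None]
    log_beta_flat = log_beta.T[word_idx]  # (nnz, K)
    resp = np.zeros((len(tf), K))
    for _ in range(cfg.var_max_iter):
        log_resp = digamma(gamma)[doc_idx] + log_beta_flat
        log_resp -= logsumexp(log_resp, axis=1, keepdims=True)
        resp = np.exp(log_resp)
        gamma_new = np.full((M, K), alpha)
        wr = tf[:, None] * resp
        for k in range(K):
            gamma_new[:, k] += np.bincount(doc_idx, weights=wr[:, k], minlength=M)
        delta = np.abs(gamma_new - gamma).sum(axis=1) / gamma.sum(axis=1)
        gamma = gamma_new
        if delta.max() < cfg.var_rel_tol:
            break
    return gamma, resp


# ---------------------------------------------------------------------------
# M-step and alpha update

def m_step(expected_counts: np.ndarray, cfg: LdaConfig) -> np.ndarray:
    """Maximum-likelihood topic-word re-estimation.

    log_beta[k,t] = log(expected_counts[k,t] / row total), with zero cells
    clamped to cfg.log_floor (the clamp stands in for log 0; rows are not
    renormalized after clamping).  A topic with an all-zero row falls back
    to the uniform distribution with a warning.
    """
    ec = np.asarray(expected_counts, dtype=float)
    totals = ec.sum(axis=1)
    V = ec.shape[1]
    log_beta = np.full_like(ec, cfg.log_floor)
    for k in range(ec.shape[0]):
        if totals[k] <= 0:
            warnings.warn(f"topic {k} has zero expected counts; set to uniform")
            log_beta[k] = -np.log(V)
            continue
        nz = ec[k] > 0
        log_beta[k, nz] = np.log(ec[k, nz]) - np.log(totals[k])
    np.maximum(log_beta, cfg.log_floor, out=log_beta)
    return log_beta


def update_alpha(gammas: np.ndarray, current_alpha: float, max_iter: int = 50,
                 tol: float = 1e-8) -> float:
    """Newton-Raphson update of the symmetric Dirichlet hyperparameter.

    Maximizes the alpha-dependent terms of the variational bound,
    M*(lgamma(K a) - K lgamma(a)) + (a-1)*ss with
    ss = sum_d sum_k E[log theta_dk], via Newton steps in log(alpha) so the
    iterate stays positive (floored at 1e-8).
    """
    gammas = np.asarray(gammas, dtype=float)
    M, K = gammas.shape
    ss = float((digamma(gammas) - digamma(gammas.sum(axis=1))[:, None]).sum())
    log_a = np.log(max(current_alpha, 1e-8))
    for _ in range(max_iter):
        a = np.exp(log_a)
        df = M * K * (digamma(K * a) - digamma(a)) + ss
        d2f = M * K * (K * polygamma(1, K * a) - polygamma(1, a))
        # Newton in log-space: d/dlog_a = a*df, d2/dlog_a2 = a*df + a^2*d2f
        step = (a * df) / (a * df + a * a * d2f)
        if not np.isfinite(step):
            warnings.warn("alpha update hit a non-finite Newton step; keeping last iterate")
            break
        log_a -= step
        if abs(step) < tol:
            return float(max(np.exp(log_a), 1e-8))
    else:
        warnings.warn("alpha update did not converge; returning last iterate")
    return float(max(np.exp(log_a), 1e-8))


# ---------------------------------------------------------------------------
# Variational lower bound

def _bound_from_flat(
    counts: sp.csr_matrix,
    log_beta: np.ndarray,
    alpha: float,
    gamma: np.ndarray,
    resp: np.ndarray,
) -> float:
    """Evidence lower bound from the flattened E-step output."""
    M = counts.shape[0]
    K = log_beta.shape[0]
    doc_idx = np.repeat(np.arange(M), np.diff(counts.indptr))
    word_idx = counts.indices
    tf = counts.data.astype(float)

    elog_theta = digamma(gamma) - digamma(gamma.sum(axis=1))[:, None]  # (M, K)

    # E[log p(theta | alpha)] - E[log q(theta | gamma)]
    lp_theta = M * (gammaln(K * alpha) - K * gammaln(alpha)) \
        + (alpha - 1.0) * elog_theta.sum()
    lq_theta = (gammaln(gamma.sum(axis=1)).sum() - gammaln(gamma).sum()
                + ((gamma - 1.0) * elog_theta).sum())

    # token terms: E[log p(z|theta)] + E[log p(w|z,beta)] - E[log q(z)]
    per_entry = resp * (elog_theta[doc_idx] + log_beta.T[word_idx]) - xlogy(resp, resp)
    lp_tokens = float(tf @ per_entry.sum(axis=1))

    bound = lp_theta - lq_theta + lp_tokens
    if not np.isfinite(bound):
        raise FloatingPointError("variational bound is not finite")
    return float(bound)


def bound(
    dtm: DocTermMatrix,
    model: TopicModel,
    states: list[VariationalState],
) -> float:
    """Variational lower bound on the corpus log likelihood for given states."""
    if len(states) != dtm.n_docs:
        raise ValueError("one VariationalState per document is required")
    total = 0.0
    K, alpha = model.K, model.alpha
    for m, st in enumerate(states):
        gamma_d = st.gamma_d
        elog = digamma(gamma_d) - digamma(gamma_d.sum())
        lp_theta = gammaln(K * alpha) - K * gammaln(alpha) + (alpha - 1.0) * elog.sum()
        lq_theta = (gammaln(gamma_d.sum()) - gammaln(gamma_d).sum()
                    + ((gamma_d - 1.0) * elog).sum())
        tf = np.asarray(dtm.counts[m, st.word_idx].todense()).ravel() if len(st.word_idx) \
            else np.zeros(0)
        per_word = st.resp * (elog[None, :] + model.log_beta[:, st.word_idx].T) \
            - xlogy(st.resp, st.resp)
        total += lp_theta - lq_theta + float(tf @ per_word.sum(axis=1))
    if not np.isfinite(total):
        raise FloatingPointError("variational bound is not finite")
    return float(total)


# ---------------------------------------------------------------------------
# Outer EM loop

def fit_lda(
    dtm: DocTermMatrix,
    cfg: LdaConfig,
) -> tuple[TopicModel, DocTopicMatrix, FitDiagnostics]:
    """Fit LDA to a document-term matrix by variational EM.

    Topic-word log probabilities are initialized from a seeded uniform
    perturbation of the expected counts followed by one M-step, then EM
    alternates the batch E-step with maximum-likelihood M-steps (and an
    optional alpha update) until the relative bound change falls below
    em_rel_tol.  Deterministic given cfg.seed.  Empty documents are kept;
    their gamma row is the all-alpha vector.
    """
    if dtm.n_docs == 0:
        raise ValueError("cannot fit on an empty corpus")
    V = dtm.n_words
    K = cfg.K
    if K > V:
        warnings.warn(f"K={K} exceeds vocabulary size V={V}")
    rng = np.random.default_rng(cfg.seed)
    counts = dtm.counts.tocsr().astype(np.int64)

    init_counts = rng.uniform(size=(K, V)) + 1.0 / V
    log_beta = m_step(init_counts, cfg)
    alpha = cfg.alpha

    diag = FitDiagnostics()
    gamma = None
    prev_bound = None
    for it in range(cfg.em_max_iter):
        gamma, resp = _e_step_batch(counts, log_beta, alpha, cfg, gamma_init=gamma)
        b = _bound_from_flat(counts, log_beta, alpha, gamma, resp)
        diag.bound_per_iter.append(b)
        diag.iterations = it + 1
        if prev_bound is not None:
            rel = abs(b - prev_bound) / (abs(prev_bound) + 1e-300)
            if rel < cfg.em_rel_tol:
                diag.converged = True
                break
        prev_bound = b

        # M-step: expected topic-word counts from responsibilities
        doc_word = counts.indices
        wr = counts.data.astype(float)[:, None] * resp
        expected = np.empty((K, V))
        for k in range(K):
            expected[k] = np.bincount(doc_word, weights=wr[:, k], minlength=V)
        log_beta = m_step(expected, cfg)
        if cfg.estimate_alpha:
            alpha = update_alpha(gamma, alpha)

    logger.info("LDA fit: M=%d V=%d K=%d alpha=%.4g iters=%d converged=%s bound=%.4f",
                dtm.n_docs, V, K, alpha, diag.iterations, diag.converged,
                diag.bound_per_iter[-1])
    model = TopicModel(K=K, alpha=alpha, log_beta=log_beta, vocab=dtm.vocab)
    doc_topic = DocTopicMatrix(gamma=gamma, row_ids=list(dtm.row_ids),
                               labels=list(dtm.labels))
    return model, doc_topic, diag
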
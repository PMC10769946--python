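"""Variational EM for LDA: closed forms, oracles, monotonicity, determinism."""

import numpy as np
import pytest
from scipy.special import digamma, gammaln

import topicplant as tp
from topicplant.lda import _e_step_batch

from conftest import random_corpus


def corpus_frequencies(dtm: tp.DocTermMatrix) -> np.ndarray:
    totals = np.asarray(dtm.counts.sum(axis=0)).ravel().astype(float)
    return totals / totals.sum()


class TestSingleTopicClosedForm:
    """With K=1 the model degenerates to a unigram model with known MLE."""

    def test_log_beta_equals_log_corpus_frequencies(self, tiny_corpus):
        dtm = tp.build_matrix(tiny_corpus, min_df=1)
        model, doc_topic, _ = tp.fit_lda(dtm, tp.LdaConfig(K=1, alpha=0.5, seed=0))
        np.testing.assert_allclose(
            model.log_beta[0], np.log(corpus_frequencies(dtm)), atol=1e-10)

    def test_gamma_is_alpha_plus_doc_length(self, tiny_corpus):
        dtm = tp.build_matrix(tiny_corpus, min_df=1)
        _, doc_topic, _ = tp.fit_lda(dtm, tp.LdaConfig(K=1, alpha=0.5, seed=0))
        np.testing.assert_allclose(
            doc_topic.gamma[:, 0], 0.5 + dtm.row_totals(), atol=1e-10)

    def test_bound_matches_unigram_log_likelihood(self, tiny_corpus):
        # K=1: E[log theta] = psi(gamma) - psi(gamma) = 0 and the q/p Dirichlet
        # normalizers cancel, so the bound is exactly the unigram log likelihood
        dtm = tp.build_matrix(tiny_corpus, min_df=1)
        cfg = tp.LdaConfig(K=1, alpha=0.5, seed=0)
        model, _, _ = tp.fit_lda(dtm, cfg)
        states = [tp.variational_inference(dtm.counts[m], model, cfg)
                  for m in range(dtm.n_docs)]
        b = tp.bound(dtm, model, states)
        log_freq = np.log(corpus_frequencies(dtm))
        unigram_ll = float(np.asarray(dtm.counts.sum(axis=0)).ravel() @ log_freq)
        assert b == pytest.approx(unigram_ll, rel=1e-10)


class TestVariationalInference:
    def test_empty_document_returns_prior(self, tiny_corpus):
        dtm = tp.build_matrix(tiny_corpus, min_df=1)
        cfg = tp.LdaConfig(K=3, alpha=0.2, seed=0)
        model, _, _ = tp.fit_lda(dtm, cfg)
        st = tp.variational_inference(np.zeros(dtm.n_words), model, cfg)
        np.testing.assert_allclose(st.gamma_d, np.full(3, 0.2))

    def test_single_topic_exact(self, tiny_corpus):
        dtm = tp.build_matrix(tiny_corpus, min_df=1)
        cfg = tp.LdaConfig(K=1, alpha=1.0, seed=0)
        model, _, _ = tp.fit_lda(dtm, cfg)
        st = tp.variational_inference(dtm.counts[0], model, cfg)
        assert st.gamma_d[0] == pytest.approx(1.0 + dtm.row_totals()[0], abs=1e-12)
        np.testing.assert_allclose(st.resp, 1.0)

    def test_one_word_document_against_independent_fixed_point(self):
        # brute-force fixed-point iteration written independently of the module
        vocab = tp.Vocabulary(words=["u", "v"], doc_freq=np.array([1, 1]))
        log_beta = np.log(np.array([[0.9, 0.1], [0.1, 0.9]]))
        model = tp.TopicModel(K=2, alpha=1.0, log_beta=log_beta, vocab=vocab)
        cfg = tp.LdaConfig(K=2, alpha=1.0, var_max_iter=200, var_rel_tol=1e-14, seed=0)
        st = tp.variational_inference(np.array([1, 0]), model, cfg)

        gamma = np.array([1.0 + 0.5, 1.0 + 0.5])
        for _ in range(200):
            w = np.exp(digamma(gamma)) * np.array([0.9, 0.1])
            phi = w / w.sum()
            gamma = 1.0 + phi
        np.testing.assert_allclose(st.gamma_d, gamma, atol=1e-8)
        assert st.resp[0, 0] > 0.8  # heavily favors the topic that explains the word

    def test_responsibilities_sum_to_one(self, small_sim):
        _, train, _, _ = small_sim
        dtm = tp.build_matrix(train, min_df=2)
        cfg = tp.LdaConfig(K=3, seed=4)
        model, _, _ = tp.fit_lda(dtm, cfg)
        st = tp.variational_inference(dtm.counts[0], model, cfg)
        np.testing.assert_allclose(st.resp.sum(axis=1), 1.0, atol=1e-10)

    def test_batch_e_step_matches_per_document_inference(self, tiny_corpus):
        dtm = tp.build_matrix(tiny_corpus, min_df=1)
        cfg = tp.LdaConfig(K=2, alpha=0.3, seed=1, var_max_iter=200, var_rel_tol=1e-12)
        model, _, _ = tp.fit_lda(dtm, cfg)
        gamma, _ = _e_step_batch(dtm.counts, model.log_beta, model.alpha, cfg)
        for m in range(dtm.n_docs):
            st = tp.variational_inference(dtm.counts[m], model, cfg)
            np.testing.assert_allclose(gamma[m], st.gamma_d, rtol=1e-6)


class TestMStep:
    def test_arithmetic_example(self):
        cfg = tp.LdaConfig(K=1, log_floor=-100.0)
        lb = tp.m_step(np.array([[3.0, 1.0, 0.0]]), cfg)
        np.testing.assert_allclose(lb, [[np.log(0.75), np.log(0.25), -100.0]])

    def test_uniform_counts(self):
        cfg = tp.LdaConfig(K=2)
        lb = tp.m_step(np.full((2, 4), 5.0), cfg)
        np.testing.assert_allclose(lb, -np.log(4))

    def test_single_nonzero_cell(self):
        cfg = tp.LdaConfig(K=1)
        lb = tp.m_step(np.array([[0.0, 7.0, 0.0]]), cfg)
        np.testing.assert_allclose(lb[0], [-100.0, 0.0, -100.0], atol=1e-12)

    def test_zero_row_falls_back_to_uniform_with_warning(self):
        cfg = tp.LdaConfig(K=2)
        with pytest.warns(UserWarning, match="zero expected counts"):
            lb = tp.m_step(np.array([[1.0, 1.0], [0.0, 0.0]]), cfg)
        np.testing.assert_allclose(lb[1], -np.log(2))


class TestUpdateAlpha:
    def test_against_golden_section_oracle(self):
        rng = np.random.default_rng(0)
        gammas = 0.3 + rng.gamma(2.0, 1.0, size=(40, 4))
        a_hat = tp.update_alpha(gammas, current_alpha=0.5)

        M, K = gammas.shape
        ss = float((digamma(gammas) - digamma(gammas.sum(1))[:, None]).sum())

        def objective(a):
            return M * (gammaln(K * a) - K * gammaln(a)) + (a - 1) * ss

        lo, hi = 1e-6, 50.0
        gr = (np.sqrt(5) - 1) / 2
        for _ in range(200):
            c, d = hi - gr * (hi - lo), lo + gr * (hi - lo)
            if objective(c) > objective(d):
                hi = d
            else:
                lo = c
        assert a_hat == pytest.approx((lo + hi) / 2, abs=1e-4)

    def test_disabled_alpha_stays_fixed(self, tiny_corpus):
        dtm = tp.build_matrix(tiny_corpus, min_df=1)
        model, _, _ = tp.fit_lda(dtm, tp.LdaConfig(K=2, alpha=0.37, seed=0))
        assert model.alpha == 0.37

    def test_enabled_alpha_moves_and_stays_positive(self, tiny_corpus):
        dtm = tp.build_matrix(tiny_corpus, min_df=1)
        model, _, _ = tp.fit_lda(
            dtm, tp.LdaConfig(K=2, alpha=0.37, estimate_alpha=True, seed=0))
        assert model.alpha > 0
        assert model.alpha != 0.37


class TestFitProperties:
    def test_topic_rows_normalized(self, small_sim):
        _, train, _, _ = small_sim
        dtm = tp.build_matrix(train, min_df=2)
        model, _, _ = tp.fit_lda(dtm, tp.LdaConfig(K=3, seed=2))
        np.testing.assert_allclose(np.exp(model.log_beta).sum(axis=1), 1.0, atol=1e-8)
        assert model.log_beta.min() >= -100.0

    def test_gamma_conservation(self, small_sim):
        _, train, _, _ = small_sim
        dtm = tp.build_matrix(train, min_df=2)
        cfg = tp.LdaConfig(K=3, alpha=0.1, seed=2)
        _, doc_topic, _ = tp.fit_lda(dtm, cfg)
        np.testing.assert_allclose(
            (doc_topic.gamma - cfg.alpha).sum(axis=1), dtm.row_totals(), atol=1e-8)

    def test_seeded_determinism_bit_identical(self, small_sim):
        _, train, _, _ = small_sim
        dtm = tp.build_matrix(train, min_df=2)
        cfg = tp.LdaConfig(K=3, seed=9)
        m1, g1, _ = tp.fit_lda(dtm, cfg)
        m2, g2, _ = tp.fit_lda(dtm, cfg)
        assert np.array_equal(m1.log_beta, m2.log_beta)
        assert np.array_equal(g1.gamma, g2.gamma)

    def test_disjoint_vocabulary_corpus_separates_topics(self):
        docs = [tp.Document(f"a{i}", ("a",) * 3) for i in range(5)] + \
               [tp.Document(f"b{i}", ("b",) * 3) for i in range(5)]
        dtm = tp.build_matrix(docs, min_df=1)
        model, _, _ = tp.fit_lda(
            dtm, tp.LdaConfig(K=2, alpha=0.1, seed=0, em_max_iter=200))
        top = np.exp(model.log_beta).max(axis=1)
        assert (top > 0.95).all()

    def test_empty_documents_kept_with_prior_gamma(self):
        docs = [tp.Document("d1", ("a", "b", "a")), tp.Document("d2", ())]
        dtm = tp.build_matrix(docs, min_df=1)
        cfg = tp.LdaConfig(K=2, alpha=0.4, seed=0)
        _, doc_topic, _ = tp.fit_lda(dtm, cfg)
        assert doc_topic.gamma.shape[0] == 2
        np.testing.assert_allclose(doc_topic.gamma[1], 0.4)

    def test_bound_non_decreasing_on_random_corpus(self):
        rng = np.random.default_rng(21)
        docs = random_corpus(rng, m=40, v=60)
        dtm = tp.build_matrix(docs, min_df=1)
        _, _, diag = tp.fit_lda(dtm, tp.LdaConfig(K=4, seed=21))
        b = np.array(diag.bound_per_iter)
        assert (np.diff(b) >= -1e-6 * np.abs(b[:-1])).all()

    def test_k_above_vocabulary_warns(self):
        docs = [tp.Document("d1", ("a", "b")), tp.Document("d2", ("a",))]
        dtm = tp.build_matrix(docs, min_df=1)
        with pytest.warns(UserWarning, match="exceeds vocabulary"):
            tp.fit_lda(dtm, tp.LdaConfig(K=5, seed=0))


class TestSerialization:
    def test_model_tsv_roundtrip(self, tiny_corpus, tmp_path):
        dtm = tp.build_matrix(tiny_corpus, min_df=1)
        model, doc_topic, _ = tp.fit_lda(dtm, tp.LdaConfig(K=2, seed=0))
        model.write_tsv(tmp_path / "model.tsv")
        back = tp.TopicModel.read_tsv(tmp_path / "model.tsv", dtm.vocab)
        np.testing.assert_array_equal(back.log_beta, model.log_beta)
        assert back.alpha == model.alpha

    def test_model_vocabulary_mismatch_rejected(self, tiny_corpus, tmp_path):
        dtm = tp.build_matrix(tiny_corpus, min_df=1)
        model, _, _ = tp.fit_lda(dtm, tp.LdaConfig(K=2, seed=0))
        model.write_tsv(tmp_path / "model.tsv")
        wrong = tp.Vocabulary(words=["only"], doc_freq=np.array([1]))
        with pytest.raises(ValueError, match="vocabulary"):
            tp.TopicModel.read_tsv(tmp_path / "model.tsv", wrong)

    def test_doc_topic_tsv_roundtrip(self, tiny_corpus, tmp_path):
        dtm = tp.build_matrix(tiny_corpus, min_df=1)
        _, doc_topic, _ = tp.fit_lda(dtm, tp.LdaConfig(K=2, seed=0))
        doc_topic.write_tsv(tmp_path / "f.tsv")
        back = tp.DocTopicMatrix.read_tsv(tmp_path / "f.tsv")
        np.testing.assert_array_equal(back.gamma, doc_topic.gamma)
        assert back.labels == doc_topic.labels
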
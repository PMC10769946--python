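# Methods

## The model

topicplant predicts a binary disease outcome for a patient from the free
text of their clinical notes, using latent Dirichlet allocation (LDA) as
the feature extractor. Each patient's notes over an observation window are
merged into one bag-of-words document; the corpus of M documents over a
vocabulary of V words is indexed into a sparse M x V term-frequency matrix.

LDA assumes each document draws topic proportions
`theta_d ~ Dirichlet(alpha)` (symmetric), and each token draws a topic
`z ~ Categorical(theta_d)` and a word `w ~ Categorical(beta_z)`, where
`beta` is the K x V topic-word matrix. The fit is variational EM in the
style of Blei's original LDA-C: the E-step optimizes, per document, a
Dirichlet posterior `gamma_d` over `theta_d` and multinomial
responsibilities over token-topic assignments; the M-step re-estimates
`beta` by maximum likelihood from the expected topic-word counts. The M x K
matrix of `gamma` values is the "topic structure" used as classifier
features.

## Transplantation

A classifier trained on the training corpus's M x K topic structure can
only score a held-out document if that document is expressed in the same K
dimensions, and — crucially — the held-out set must not influence the
vocabulary or the topic model. Transplantation computes, for held-out
document m and topic k,

    gamma_tilde[m, k] = sum_n TF_n * exp(phi[t, k])

where the sum runs over the document's distinct words, `TF_n` is the word's
term frequency in the document, and `t` indexes the word in the *training*
vocabulary's topic-word matrix `phi` (log probabilities). Words absent from
the training vocabulary ("unseen data", including words removed from
training by the document-frequency cutoff) have no `phi` row; their log
weight is fixed at the smoothing constant −100.0, so each unseen token
contributes exactly `e^-100 ≈ 3.7e-44` per count unit — in double
precision this is fully absorbed when any seen word contributes, which is
the intent: unseen words must not influence the inferred weights.

The sum over word occurrences weighted by TF is implemented as one term
per distinct word type multiplied by its TF; a per-token sum is the same
number, so there is no double counting.

## Feature scale and the classifier contract

Variational `gamma` (each entry `alpha` + expected topic token count) and
transplanted `gamma_tilde` (TF-weighted sums of word probabilities) are
*not* on the same scale, and tree ensembles split on absolute feature
values, so mixing the two representations between training and test rows
degrades transfer badly (we measured held-out F1 dropping from ~0.89 to
~0.27 on synthetic corpora when raw variational features train a model
evaluated on raw transplanted features). The held-out pipeline therefore

1. featurizes **both** training and held-out rows through the transplant
   formula by default (`train_feature_mode="transplant"`), so both sides
   come from the same map and share a distribution; the variational
   training features remain available (`train_feature_mode="variational"`),
   and are still what `fit_lda` itself exports; and
2. L1-normalizes every feature row to topic proportions
   (`feature_scale="l1"`), removing document length as a nuisance
   dimension; `"raw"` disables this.

`transplant_gamma` itself always returns the raw formula output (with an
optional `row_normalize` flag); scaling is the classifier layer's concern.

## Evaluation protocols

* **Held-out** (main): split 9:1 stratified by outcome *before* any topic
  modeling; vocabulary, topic model, and training features come from the
  training 90% only; the 10% enters through transplantation. A doc-id
  overlap between the two sides aborts the run, and a stage callback lets
  tests instrument that held-out tokens are untouched until the topic model
  is fixed.
* **10-fold cross-validation** (preliminary): LDA is fitted once on the
  full matrix, then stratified folds rotate over the resulting `gamma`
  rows. This protocol lets dimension reduction see the test rows and is
  retained for comparison, not as the headline evaluation.

Metrics per classifier: precision `tp/(tp+fp)`, recall (= sensitivity)
`tp/(tp+fn)`, F1 (harmonic mean), specificity `tn/(tn+fp)`. Ratios with a
zero denominator are reported as 0 with a `degenerate` flag. CV metrics
are averaged over folds (pooled-confusion optional). Class assignment
thresholds the positive-class probability at 0.5.

Classifiers: random forest (500 trees), gradient boosting, and extreme
gradient boosting, all with library defaults otherwise and fixed seeds.
Hyperparameter search is deliberately out of scope — data quality, not the
choice among tree ensembles, dominates performance in this setting.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `K` | 100 | topic count for real corpora of ~1k-3k documents and ~10k words; simulations and tests use K = 3-10, matched to the generator |
| `alpha` | 0.1 | symmetric Dirichlet prior; small values suit sparse per-patient topic mixtures; fixed by default, Newton-Raphson update available (`estimate_alpha`) |
| `min_df` | 2 | training vocabulary keeps words appearing in >= 2 documents; consistent with IDF maxima equal to ln(M/2) in clinical corpora of this kind |
| `smoothing_log` | −100.0 | log weight of unseen words at transplant time |
| `log_floor` | −100.0 | clamp for log 0 in the topic-word matrix; one consistent floor package-wide |
| `em_rel_tol`, `em_max_iter` | 1e-4, 100 | outer EM stop rule on the relative bound change |
| `var_rel_tol`, `var_max_iter` | 1e-6, 20 | per-document E-step stop rule on the relative gamma change |
| `test_fraction` | 0.1 | 9:1 train:test split, stratified by outcome |

IDF is `ln(M/DF)` (natural log; base-10 via a flag), computed on the
training matrix; summaries report sample skewness g1, Fisher excess
kurtosis g2, and type-7 (linear interpolation) quartiles, with the
conventions echoed in the JSON output.

## Numerical choices

* **Initialization**: expected counts start from seeded `Uniform(0,1) + 1/V`
  noise followed by one M-step — reproducible, and breaks the symmetric
  saddle point. Identical seed, config and input give bit-identical fits.
* **E-step warm start**: each EM iteration's E-step ascends from the
  previous iteration's `gamma` (not a fresh initialization). This keeps the
  variational bound monotone even when `var_max_iter` truncates the inner
  loop; a fresh-start truncated E-step can otherwise land below the
  previous bound.
* **Zero cells**: M-step log probabilities are clamped at `log_floor`
  instead of −inf; an all-zero topic row falls back to uniform with a
  warning. Rows are not renormalized after clamping (the clamp stands in
  for log 0).
* **Empty documents** are retained with `gamma = (alpha, ..., alpha)` so
  row alignment with labels is preserved; their transplanted row is all
  zeros.
* **Degenerate folds** (single-class test part) are skipped with a warning
  in CV; single-class training labels are an error.
* **Vocabulary order** is lexicographic, making matrices bit-reproducible
  across runs and platforms.

## The synthetic-data generator

No real clinical corpus ships with the package; the generator samples from
the LDA generative process itself and adds the downstream-relevant
features of merged outpatient-note corpora:

* **Scale** (defaults): M_train = 1000, M_test = 200, V = 2000, K_true = 5,
  Poisson document lengths with mean 80, topic rows from
  Dirichlet(0.05) — giving >= 95% matrix sparsity, a scaled-down analogue
  of EMR corpora with hundreds-to-thousands of patients, 8k-14k word
  vocabularies and ~99% sparsity. Fit-quality studies in the tests and the
  acceptance script use M_train = 500, V = 300, doc_len_mean = 100 to keep
  runs at desk scale.
* **Labels**: p(positive) = logistic(signal_strength · (s − c)) clamped to
  [label_noise, 1 − label_noise], where s is the per-document sum of the
  designated signal topics' true proportions and c is calibrated on the
  sample so the expected positive rate is 1/2 (a median centering is
  biased under the clamp when s is skewed). Defaults: signal topics
  {0, 1}, strength 8, noise 0.05 — a strong but noisy topic-outcome link
  with balanced classes. Note the link leaves documents with s near c at
  p ≈ 0.5, so even the Bayes rule does not approach F1 = 1 at strength 8;
  measured Bayes-rule F1 at the study scale is ≈ 0.81-0.90 across seeds.
* **Unseen words**: a seeded 12% (default) of held-out tokens are replaced
  (not appended, keeping lengths fixed) by novel symbols drawn from a pool
  sized so the type-level out-of-vocabulary share of the held-out corpus
  lands near the token-level fraction — matching the 12-16% unseen-word
  regime typical of held-out clinical vocabulary.
* **Synonyms**: optionally, some vocabulary words receive "product-name"
  aliases in ~half their occurrences, with the matching alias-to-ingredient
  map emitted, as a round-trip fixture for token normalization.

What the generator does **not** emulate: real clinical language (burstiness,
templated note structure, misspellings), Korean morphology, visit-level
temporal structure, correlated comorbidity vocabulary, or label links
other than through topic proportions. Passing tests therefore demonstrate
the pipeline's correctness and its statistical behavior *under the LDA
model's own assumptions*, not clinical-grade predictive validity.

## Known limitations

* Variational EM finds local optima; recovery tests use well-separated
  topics (Dirichlet 0.05 rows). Highly overlapping topics may need
  restarts, which the seeded API supports but does not automate.
* Transplanted weights are a linear image of the document's TF vector
  through `exp(phi)`; they are not a posterior and have no uncertainty.
  A variational fold-in alternative is deliberately not implemented.
* Classifier determinism is guaranteed per library version and platform;
  across library versions, tree ensembles may differ.
* The CV protocol intentionally reproduces a leaky design (dimension
  reduction before segmentation) for comparison; its scores should not be
  quoted as generalization estimates.
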
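"""Ensemble-tree classification of document-topic features, two protocols.

The outcome classifiers are the three tree ensembles commonly used for
tabular clinical features: random forest, gradient boosting, and extreme
gradient boosting.  Two evaluation protocols are provided:

* run_cv — the preliminary protocol: topic modeling on the FULL corpus
  first, then 10-fold cross-validation over the resulting document-topic
  rows (dimension reduction before segmentation).
* run_holdout — the main protocol: the test set is held out BEFORE any
  topic modeling; the vocabulary, the topic model and the training
  features come from training documents only, and the held-out documents
  enter the classifier through transplanted topic weights.  This is the
  leakage-free setting a deployed model faces with genuinely new patients.

Metrics are precision, recall (= sensitivity), F1 and specificity.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .corpus import Document, DocTermMatrix, build_matrix
from .lda import LOG_FLOOR_DEFAULT, DocTopicMatrix, LdaConfig, fit_lda
from .transplant import transplant_gamma

logger = logging.getLogger(__name__)

METHODS = ("random_forest", "gradient_boosting", "extreme_gradient_boosting")
POSITIVE, NEGATIVE = "positive", "negative"


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the three ensemble-tree methods with its hyperparameters."""

    method: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")


def default_specs(seed: int = 0) -> list[ClassifierSpec]:
    return [ClassifierSpec(method=m, seed=seed) for m in METHODS]


def _make_estimator(spec: ClassifierSpec):
    hp = dict(spec.hyperparams)
    if spec.method == "random_forest":
        hp.setdefault("n_estimators", 500)
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **hp)
    if spec.method == "gradient_boosting":
        return GradientBoostingClassifier(random_state=spec.seed, **hp)
    hp.setdefault("n_estimators", 200)
    return XGBClassifier(random_state=spec.seed, n_jobs=1, verbosity=0,
                         eval_metric="logloss", **hp)


def scale_features(X: np.ndarray, feature_scale: str = "l1") -> np.ndarray:
    """Row-wise feature scaling applied before classification.

    'l1' divides each row by its sum, turning document-topic weights into
    topic proportions (removes document-length nuisance and puts
    variational and transplanted features on comparable scales); 'raw'
    passes the weights through unchanged.  All-zero rows are left as is.
    """
    X = np.asarray(X, dtype=float)
    if feature_scale == "raw":
        return X
    if feature_scale != "l1":
        raise ValueError("feature_scale must be 'l1' or 'raw'")
    totals = X.sum(axis=1, keepdims=True)
    safe = np.where(totals == 0, 1.0, totals)
    return X / safe


def _binary(labels: Sequence[str]) -> np.ndarray:
    y = np.array([1 if l == POSITIVE else 0 for l in labels])
    bad = [l for l in labels if l not in (POSITIVE, NEGATIVE)]
    if bad:
        raise ValueError(f"labels must be positive/negative for classification; got {bad[:3]}")
    return y


def train_classifier(features: np.ndarray, labels: Sequence[str], spec: ClassifierSpec):
    """Fit one ensemble-tree classifier; deterministic given spec.seed."""
    X = np.asarray(features, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    y = _binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    est = _make_estimator(spec)
    est.fit(X, y)
    return est


def predict_labels(model, features: np.ndarray, threshold: float = 0.5) -> list[str]:
    """Class assignment by thresholding the positive-class probability at 0.5."""
    proba = model.predict_proba(np.asarray(features, dtype=float))[:, 1]
    return [POSITIVE if p >= threshold else NEGATIVE for p in proba]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    """Rows of (dataset, method) -> precision/recall/F1/specificity."""

    rows: list[dict] = field(default_factory=list)

    def add(self, dataset: str, method: str, counts: ConfusionCounts,
            metrics: dict) -> None:
        self.rows.append({"dataset": dataset, "method": method,
                          "tp": counts.tp, "fp": counts.fp,
                          "fn": counts.fn, "tn": counts.tn, **metrics})

    def row(self, dataset: str, method: str) -> dict:
        for r in self.rows:
            if r["dataset"] == dataset and r["method"] == method:
                return r
        raise KeyError((dataset, method))

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.rows, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_table(self) -> str:
        """Formatted dataset x method x 4-metric table, 3 decimals."""
        header = f"{'Dataset':<12}{'Method':<28}{'Precision':>10}{'Recall':>10}{'F1':>10}{'Specificity':>12}"
        lines = [header, "-" * len(header)]
        for r in self.rows:
            lines.append(
                f"{r['dataset']:<12}{r['method']:<28}"
                f"{r['precision']:>10.3f}{r['recall']:>10.3f}"
                f"{r['f1']:>10.3f}{r['specificity']:>12.3f}"
            )
        return "\n".join(lines)


def evaluate(
    predictions: Sequence[str],
    truth: Sequence[str],
    positive_class: str = POSITIVE,
) -> tuple[ConfusionCounts, dict]:
    """Confusion counts and precision/recall/F1/specificity.

    Undefined ratios (zero denominator) are reported as 0.0 with a
    ``degenerate`` warning flag in the metrics dict.
    """
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth must have equal length")
    tp = sum(1 for p, t in zip(predictions, truth) if p == positive_class and t == positive_class)
    fp = sum(1 for p, t in zip(predictions, truth) if p == positive_class and t != positive_class)
    fn = sum(1 for p, t in zip(predictions, truth) if p != positive_class and t == positive_class)
    tn = sum(1 for p, t in zip(predictions, truth) if p != positive_class and t != positive_class)
    counts = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)

    degenerate = False

    def ratio(num: int, den: int) -> float:
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    specificity = ratio(tn, tn + fp)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    if degenerate:
        warnings.warn("confusion matrix has a zero denominator; affected metrics set to 0")
    metrics = {"precision": precision, "recall": recall, "f1": f1,
               "specificity": specificity, "degenerate": degenerate}
    return counts, metrics


@dataclass
class CvPlan:
    """Stratified fold assignment for cross-validation."""

    n_folds: int
    seed: int
    fold_of: np.ndarray  # fold index per document row

    @classmethod
    def make(cls, labels: Sequence[str], n_folds: int = 10, seed: int = 0) -> "CvPlan":
        y = _binary(labels)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        fold_of = np.empty(len(y), dtype=np.int64)
        for f, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
            fold_of[test_idx] = f
        return cls(n_folds=n_folds, seed=seed, fold_of=fold_of)


def run_cv(
    dtm_full: DocTermMatrix,
    lda_cfg: LdaConfig,
    specs: Sequence[ClassifierSpec],
    plan: CvPlan,
    dataset: str = "synthetic",
    pool_confusion: bool = False,
) -> MetricsReport:
    """Preliminary protocol: LDA once on the full corpus, then rotated folds.

    Per method, metrics are averaged over folds (the pooled-confusion
    alternative is available via ``pool_confusion``).  Folds whose test
    part contains a single class are skipped with a warning.
    """
    if len(plan.fold_of) != dtm_full.n_docs:
        raise ValueError("fold plan does not cover the matrix rows")
    _, doc_topic, _ = fit_lda(dtm_full, lda_cfg)
    X = scale_features(doc_topic.gamma)
    labels = np.array(dtm_full.labels)

    report = MetricsReport()
    for spec in specs:
        fold_metrics: list[dict] = []
        pooled_pred: list[str] = []
        pooled_truth: list[str] = []
        for f in range(plan.n_folds):
            test_mask = plan.fold_of == f
            truth = labels[test_mask]
            if len(set(truth)) < 2:
                warnings.warn(f"fold {f} has a single class in its test part; skipped")
                continue
            model = train_classifier(X[~test_mask], labels[~test_mask], spec)
            preds = predict_labels(model, X[test_mask])
            pooled_pred.extend(preds)
            pooled_truth.extend(truth)
            _, m = evaluate(preds, truth)
            fold_metrics.append(m)
        if pool_confusion:
            counts, m = evaluate(pooled_pred, pooled_truth)
        else:
            counts, _ = evaluate(pooled_pred, pooled_truth)
            m = {k: float(np.mean([fm[k] for fm in fold_metrics]))
                 for k in ("precision", "recall", "f1", "specificity")}
            m["degenerate"] = any(fm["degenerate"] for fm in fold_metrics)
        report.add(dataset, spec.method, counts, m)
        logger.info("cv %s/%s: averaged F1=%.3f over %d folds", dataset, spec.method,
                    m["f1"], len(fold_metrics))
    return report


def run_holdout(
    train_docs: Sequence[Document],
    test_docs: Sequence[Document],
    lda_cfg: LdaConfig,
    specs: Sequence[ClassifierSpec],
    smoothing_log: float = LOG_FLOOR_DEFAULT,
    min_df: int = 2,
    dataset: str = "synthetic",
    train_feature_mode: str = "transplant",
    feature_scale: str = "l1",
    stage_callback: Callable[[str], None] | None = None,
) -> tuple[MetricsReport, "HoldoutArtifacts"]:
    """Main protocol: topic modeling strictly after the train/test split.

    Vocabulary and topic model are built from training documents only; the
    held-out rows enter the classifier as transplanted weights.  With the
    default ``train_feature_mode='transplant'`` the training rows go
    through the same transplant formula, so train and test features come
    from one map and share a distribution; ``'variational'`` instead feeds
    the classifier the raw LDA gamma output for training rows (features on
    a different scale than the test rows — see the transplant module's
    scale note).  Rows are L1-scaled to topic proportions by default.

    ``stage_callback`` (if given) is invoked with stage names as each
    stage completes — the hook tests use to prove test tokens are
    untouched until transplantation.
    """
    if train_feature_mode not in ("transplant", "variational"):
        raise ValueError("train_feature_mode must be 'transplant' or 'variational'")
    train_ids = {d.doc_id for d in train_docs}
    overlap = train_ids & {d.doc_id for d in test_docs}
    if overlap:
        raise ValueError(f"train/test doc_id overlap (data leakage): {sorted(overlap)[:5]}")

    def stage(name: str) -> None:
        logger.info("holdout stage complete: %s", name)
        if stage_callback is not None:
            stage_callback(name)

    train_dtm = build_matrix(train_docs, min_df=min_df)
    stage("index_train")
    model, train_features, diag = fit_lda(train_dtm, lda_cfg)
    stage("fit_lda")

    # test tokens are first touched here, after the topic model is fixed
    test_dtm = build_matrix(test_docs, min_df=1)
    transplanted = transplant_gamma(test_dtm, model, smoothing_log=smoothing_log)
    stage("transplant")

    if train_feature_mode == "transplant":
        train_input = transplant_gamma(build_matrix(train_docs, min_df=1), model,
                                       smoothing_log=smoothing_log).gamma_tilde
    else:
        train_input = train_features.gamma
    X_train = scale_features(train_input, feature_scale)
    X_test = scale_features(transplanted.gamma_tilde, feature_scale)

    report = MetricsReport()
    truth = list(test_dtm.labels)
    for spec in specs:
        clf = train_classifier(X_train, train_features.labels, spec)
        preds = predict_labels(clf, X_test)
        counts, m = evaluate(preds, truth)
        report.add(dataset, spec.method, counts, m)
        logger.info("holdout %s/%s: F1=%.3f", dataset, spec.method, m["f1"])
    stage("classify")
    artifacts = HoldoutArtifacts(model=model, train_features=train_features,
                                 test_features=transplanted, diagnostics=diag)
    return report, artifacts


@dataclass
class HoldoutArtifacts:
    """Intermediate products of a held-out run, for inspection and export."""

    model: object
    train_features: DocTopicMatrix
    test_features: object
    diagnostics: object
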
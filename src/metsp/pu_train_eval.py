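"""Training-set evaluation: k-fold CV, ROC curves, and PU relabeling.

Only positive and unlabeled sentences are available for training, so the
unlabeled pool — which contains an unknown fraction of true transporter
sentences — is treated as the negative class and cleaned up by iterative
relabeling: train, score the unlabeled pool, promote confidently scored
sentences to the positive set, repeat until the process settles (by
default after four iterations or when nothing moves).

Cross-validation is stratified, seeded, and micro-averaged: confusion
counts are summed over folds and the aggregate precision/recall/accuracy
are computed from the summed counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classifiers import (
    MaxEntModel,
    NaiveBayesModel,
    SentenceClassifier,
    train_maxent,
    train_nb,
)
from .text_features import TextPipeline, default_stopwords
from .uniprot_io import LabeledInstance

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierConfig",
    "EvalReport",
    "IterationTrace",
    "RelabelError",
    "roc_curve",
    "stratified_folds",
    "cross_validate",
    "train_classifier",
    "iterate_relabel",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameters for one training run.

    kind: "maxent" or "nb".  prior_variance is the Gaussian prior sigma^2
    of the maximum-entropy model; alpha the NB Laplace constant;
    threshold the decision cut-off applied to P(positive).
    """

    kind: str = "maxent"
    prior_variance: float = 1.0
    alpha: float = 1.0
    tol: float = 1e-6
    max_iter: int = 500
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("maxent", "nb"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")


@dataclass
class EvalReport:
    """Confusion counts, derived metrics and a ROC curve."""

    tp: int
    fp: int
    tn: int
    fn: int
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    auc: float = float("nan")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else 0.0

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "precision": self.precision, "recall": self.recall,
            "accuracy": self.accuracy, "auc": self.auc,
        }


@dataclass(frozen=True)
class IterationTrace:
    """Bookkeeping for one relabeling iteration."""

    iteration: int  # 1-based
    moved: int
    precision: float
    recall: float
    positives: int
    unlabeled: int


class RelabelError(RuntimeError):
    """Relabeling emptied the unlabeled pool; traces so far attached."""

    def __init__(self, message: str, traces: list[IterationTrace]):
        super().__init__(message)
        self.traces = traces


# ---------------------------------------------------------------------------
# ROC


def roc_curve(
    scores: Sequence[float], true_labels: Sequence[int]
) -> tuple[list[tuple[float, float]], float]:
    """ROC points at descending distinct-score thresholds, plus AUC.

    Equal scores are grouped into a single step so ties contribute a
    diagonal segment; the area is the trapezoidal sum, which then equals
    the Mann-Whitney U statistic scaled by n+ * n-.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(true_labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires at least one instance of each class")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            tp += int(y[j] == 1)
            fp += int(y[j] == 0)
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    return points, float(auc)


# ---------------------------------------------------------------------------
# cross-validation


def stratified_folds(
    labels: Sequence[int], k: int, seed: int
) -> list[np.ndarray]:
    """Deterministic stratified partition into k validation index sets.

    Within each class the indices are shuffled with a seeded generator
    and dealt into contiguous blocks, so every instance is validated
    exactly once and fold sizes differ by at most one per class.
    """
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        splits = np.array_split(idx, k)
        for f, part in enumerate(splits):
            folds[f].extend(part.tolist())
    out = [np.array(sorted(f), dtype=int) for f in folds]
    # every training split must contain both classes
    for f, val in enumerate(out):
        train_y = np.delete(y, val)
        if np.unique(train_y).size < 2:
            raise ValueError(
                "a class is too small to appear in every training split; "
                "need at least 2 instances per class"
            )
    return out


def _fit_on_texts(
    texts: Sequence[str],
    y: Sequence[int],
    config: ClassifierConfig,
    stopwords: frozenset[str],
) -> SentenceClassifier:
    pipeline = TextPipeline(stopwords=stopwords).fit(list(texts))
    X = pipeline.transform_matrix(list(texts))
    if config.kind == "maxent":
        model: MaxEntModel | NaiveBayesModel = train_maxent(
            X, y, prior_variance=config.prior_variance,
            tol=config.tol, max_iter=config.max_iter,
            vocabulary=pipeline.vocabulary,
        )
    else:
        model = train_nb(
            X, y, alpha=config.alpha, vocabulary=pipeline.vocabulary
        )
    return SentenceClassifier(
        pipeline=pipeline, model=model, threshold=config.threshold
    )


def train_classifier(
    instances: Sequence[LabeledInstance],
    config: ClassifierConfig = ClassifierConfig(),
    stopwords: frozenset[str] | None = None,
) -> SentenceClassifier:
    """Train a production classifier on labeled instances.

    "unlabeled" instances are presented to the model as the negative
    class.
    """
    sw = default_stopwords() if stopwords is None else stopwords
    texts = [inst.text for inst in instances]
    y = [1 if inst.label == "positive" else 0 for inst in instances]
    return _fit_on_texts(texts, y, config, sw)


def cross_validate(
    instances: Sequence[LabeledInstance],
    k: int = 10,
    seed: int = 42,
    config: ClassifierConfig = ClassifierConfig(),
    stopwords: frozenset[str] | None = None,
    train_fn=None,
) -> tuple[EvalReport, list[EvalReport]]:
    """k-fold stratified CV; returns (aggregate report, per-fold reports).

    The vocabulary is rebuilt from each fold's training split only, so no
    validation text leaks into the features.  The aggregate ROC is
    computed over the pooled out-of-fold scores.  ``train_fn(instances,
    config, stopwords)`` may replace the default per-fold training, e.g.
    to evaluate the harness itself with a fixed scorer.
    """
    sw = default_stopwords() if stopwords is None else stopwords
    texts = [inst.text for inst in instances]
    y = np.array([1 if inst.label == "positive" else 0 for inst in instances])
    folds = stratified_folds(y, k, seed)

    fold_reports: list[EvalReport] = []
    pooled_scores = np.zeros(len(texts))
    agg = np.zeros(4, dtype=int)  # tp, fp, tn, fn
    for val_idx in folds:
        train_mask = np.ones(len(texts), dtype=bool)
        train_mask[val_idx] = False
        train_idx = np.flatnonzero(train_mask)
        if train_fn is None:
            clf = _fit_on_texts(
                [texts[i] for i in train_idx], y[train_idx], config, sw
            )
        else:
            clf = train_fn(
                [instances[i] for i in train_idx], config, sw
            )
        scores = clf.score_many([texts[i] for i in val_idx])
        pooled_scores[val_idx] = scores
        pred = (scores >= config.threshold).astype(int)
        truth = y[val_idx]
        tp = int(((pred == 1) & (truth == 1)).sum())
        fp = int(((pred == 1) & (truth == 0)).sum())
        tn = int(((pred == 0) & (truth == 0)).sum())
        fn = int(((pred == 0) & (truth == 1)).sum())
        agg += (tp, fp, tn, fn)
        report = EvalReport(tp, fp, tn, fn)
        if np.unique(truth).size == 2:
            report.roc_points, report.auc = roc_curve(scores, truth)
        fold_reports.append(report)

    aggregate = EvalReport(*(int(v) for v in agg))
    aggregate.roc_points, aggregate.auc = roc_curve(pooled_scores, y)
    return aggregate, fold_reports


# ---------------------------------------------------------------------------
# PU iterative relabeling


def iterate_relabel(
    positives: Sequence[LabeledInstance],
    unlabeled: Sequence[LabeledInstance],
    config: ClassifierConfig = ClassifierConfig(),
    max_iter: int = 4,
    stop_delta: int = 0,
    cv_k: int = 10,
    seed: int = 42,
    stopwords: frozenset[str] | None = None,
    train_fn=None,
    compute_cv: bool = True,
) -> tuple[list[LabeledInstance], list[IterationTrace]]:
    """Iteratively promote confidently scored unlabeled sentences.

    Per iteration: train on (positive, unlabeled-as-negative); score the
    unlabeled pool; relabel every sentence scoring at or above the
    decision threshold as positive; record a trace with the moved count
    and the CV precision/recall of the updated set.  Stops when the move
    count drops to ``stop_delta`` or after ``max_iter`` iterations.

    Returns the final training set (positives first, then the remaining
    unlabeled) and the per-iteration traces.

    ``train_fn(instances, config, stopwords)`` may replace the default
    classifier training (used to study the loop with a fixed scorer);
    ``compute_cv=False`` skips the per-iteration CV metrics (traces then
    carry NaN) when only the relabeling itself is of interest.
    """
    if not positives or not unlabeled:
        raise ValueError("both the positive and unlabeled sets must be nonempty")
    sw = default_stopwords() if stopwords is None else stopwords
    pos = list(positives)
    unl = list(unlabeled)
    traces: list[IterationTrace] = []

    if train_fn is None:
        train_fn = train_classifier

    for it in range(1, max_iter + 1):
        clf = train_fn(pos + unl, config, sw)
        scores = np.asarray(clf.score_many([inst.text for inst in unl]))
        move_mask = scores >= config.threshold
        moved = int(move_mask.sum())
        promoted = [
            LabeledInstance("positive", u.accession, u.field_flag, u.text)
            for u, m in zip(unl, move_mask)
            if m
        ]
        unl = [u for u, m in zip(unl, move_mask) if not m]
        pos = pos + promoted
        if not unl:
            raise RelabelError(
                "relabeling emptied the unlabeled pool; no negative class left",
                traces,
            )
        if compute_cv:
            aggregate, _ = cross_validate(
                pos + unl, k=cv_k, seed=seed, config=config, stopwords=sw
            )
            precision, recall = aggregate.precision, aggregate.recall
        else:
            precision = recall = float("nan")
        traces.append(
            IterationTrace(
                iteration=it,
                moved=moved,
                precision=precision,
                recall=recall,
                positives=len(pos),
                unlabeled=len(unl),
            )
        )
        logger.info(
            "relabel iteration %d: moved=%d, precision=%.4f, recall=%.4f",
            it, moved, precision, recall,
        )
        if moved <= stop_delta:
            break
    return pos + unl, traces
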
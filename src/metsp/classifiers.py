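"""Binary sentence classifiers: maximum entropy and multinomial Naïve Bayes.

The maximum-entropy model is the conditional-probability classifier that,
subject to matching the training feature expectations, assumes nothing
else — equivalently a two-class softmax (multinomial logistic) model.  It
is trained by maximizing the penalized conditional log-likelihood

    L(W, b) = sum_i log P(y_i | x_i; W, b) - ||W||^2 / (2 sigma^2)

with a Gaussian prior of variance ``sigma^2`` on the weights (biases
unpenalized), from a zero initialization, with a deterministic
limited-memory quasi-Newton optimizer.  The Naïve Bayes model uses the
closed-form multinomial estimates with Laplace smoothing.

Both models output P(positive | sentence); a threshold ``t`` (default
0.5, inclusive) turns scores into labels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
from scipy import optimize, sparse

from .text_features import FeatureVector, TextPipeline, Vocabulary

logger = logging.getLogger(__name__)

__all__ = [
    "MaxEntModel",
    "NaiveBayesModel",
    "Prediction",
    "train_maxent",
    "train_nb",
    "classify",
    "stack_features",
    "SentenceClassifier",
]

POSITIVE, NEGATIVE = 1, 0

ArrayLike = Union[sparse.spmatrix, np.ndarray]


def stack_features(
    vectors: Sequence[FeatureVector], n_features: int
) -> sparse.csr_matrix:
    """Stack sparse FeatureVectors into an (n, n_features) CSR matrix."""
    rows, cols, data = [], [], []
    for i, fv in enumerate(vectors):
        rows.extend([i] * len(fv.indices))
        cols.extend(fv.indices)
        data.extend(fv.values)
    return sparse.csr_matrix(
        (np.asarray(data, dtype=float), (rows, cols)),
        shape=(len(vectors), n_features),
    )


def _as_matrix(x: ArrayLike, n_features: int) -> sparse.csr_matrix:
    if isinstance(x, FeatureVector):
        return stack_features([x], n_features)
    if sparse.issparse(x):
        return x.tocsr()
    arr = np.atleast_2d(np.asarray(x, dtype=float))
    return sparse.csr_matrix(arr)


@dataclass
class Prediction:
    """A scored, thresholded classification of one sentence."""

    score: float
    threshold: float

    @property
    def label(self) -> str:
        return "positive" if self.score >= self.threshold else "negative"


def classify(score: float, t: float) -> str:
    """Positive iff score >= t (boundary inclusive)."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {t}")
    return "positive" if score >= t else "negative"


# ---------------------------------------------------------------------------
# maximum entropy


@dataclass
class MaxEntModel:
    """Two-class softmax model with Gaussian-prior regularized weights."""

    weights: np.ndarray  # (2, n_features); row POSITIVE, row NEGATIVE
    bias: np.ndarray  # (2,)
    prior_variance: float
    vocabulary: Vocabulary | None = None
    objective_path: list[float] = field(default_factory=list)
    termination: str = ""

    @property
    def n_features(self) -> int:
        return self.weights.shape[1]

    def decision_scores(self, x: ArrayLike) -> np.ndarray:
        X = _as_matrix(x, self.n_features)
        return X @ self.weights.T + self.bias

    def predict_proba(self, x: ArrayLike) -> np.ndarray:
        """P(positive) per row; an all-zero row scores softmax of biases."""
        z = self.decision_scores(x)
        z = z - z.max(axis=1, keepdims=True)
        ez = np.exp(z)
        p = ez / ez.sum(axis=1, keepdims=True)
        return p[:, POSITIVE]

    def predict(self, x: ArrayLike, t: float = 0.5) -> Prediction:
        score = float(self.predict_proba(x)[0])
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {t}")
        return Prediction(score=score, threshold=t)


def maxent_objective(
    params: np.ndarray,
    X: sparse.csr_matrix,
    Y: np.ndarray,
    sigma2: float,
) -> tuple[float, np.ndarray]:
    """Penalized negative conditional log-likelihood and its gradient.

    ``params`` packs the (2, V) weight matrix then the 2 biases.  The
    Gaussian prior contributes ||W||^2/(2 sigma^2); biases are free.
    """
    n_features = X.shape[1]
    W = params[: 2 * n_features].reshape(2, n_features)
    b = params[2 * n_features :]
    Z = X @ W.T + b  # (n, 2)
    Zs = Z - Z.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(Zs).sum(axis=1)) + Z.max(axis=1)
    loglik = (Z * Y).sum() - logsumexp.sum()
    nll = -loglik + (W * W).sum() / (2.0 * sigma2)
    if not np.isfinite(nll):
        bad = np.flatnonzero(~np.isfinite(W).all(axis=0))
        raise FloatingPointError(
            f"non-finite objective; first offending feature index: "
            f"{bad[0] if bad.size else 'bias'}"
        )
    P = np.exp(Z - logsumexp[:, None])
    D = P - Y  # (n, 2)
    gW = D.T @ X + W / sigma2
    gW = np.asarray(gW)
    gb = D.sum(axis=0)
    return float(nll), np.concatenate([gW.ravel(), gb])


def train_maxent(
    x: ArrayLike | Sequence[FeatureVector],
    y: Sequence[int],
    prior_variance: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 500,
    vocabulary: Vocabulary | None = None,
) -> MaxEntModel:
    """Fit the maximum-entropy model from a zero initialization.

    ``y`` holds 1 for positive and 0 for negative (unlabeled-as-negative)
    instances; both classes must be present.  Training stops when the
    gradient infinity-norm drops below ``tol`` or after ``max_iter``
    quasi-Newton iterations; the reason is logged and recorded.
    """
    if prior_variance <= 0:
        raise ValueError("prior_variance must be positive")
    if isinstance(x, (list, tuple)) and (not x or isinstance(x[0], FeatureVector)):
        if vocabulary is None:
            raise ValueError("vocabulary required with FeatureVector input")
        X = stack_features(list(x), vocabulary.size)
    else:
        X = _as_matrix(x, 0)
    yarr = np.asarray(y, dtype=int)
    classes = np.unique(yarr)
    if classes.size < 2:
        raise ValueError("training data must contain both classes")
    n, V = X.shape
    Y = np.zeros((n, 2))
    Y[np.arange(n), yarr] = 1.0

    path: list[float] = []

    def record(params: np.ndarray) -> None:
        val, _ = maxent_objective(params, X, Y, prior_variance)
        path.append(val)

    x0 = np.zeros(2 * V + 2)
    record(x0)
    if max_iter == 0:
        model = MaxEntModel(
            weights=np.zeros((2, V)), bias=np.zeros(2),
            prior_variance=prior_variance, vocabulary=vocabulary,
            objective_path=path, termination="max_iter",
        )
        return model
    res = optimize.minimize(
        maxent_objective,
        x0,
        args=(X, Y, prior_variance),
        jac=True,
        method="L-BFGS-B",
        callback=record,
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-12},
    )
    grad_norm = float(np.abs(res.jac).max())
    reason = "gradient" if grad_norm < max(tol, 1e-5) else (
        "max_iter" if res.nit >= max_iter else str(res.message)
    )
    logger.info(
        "maxent training stopped after %d iterations (%s, |grad|=%.2e)",
        res.nit, reason, grad_norm,
    )
    W = res.x[: 2 * V].reshape(2, V)
    b = res.x[2 * V :]
    if not np.isfinite(W).all():
        raise FloatingPointError("non-finite weights after optimization")
    return MaxEntModel(
        weights=W, bias=b, prior_variance=prior_variance,
        vocabulary=vocabulary, objective_path=path, termination=reason,
    )


# ---------------------------------------------------------------------------
# Naïve Bayes


@dataclass
class NaiveBayesModel:
    """Multinomial Naïve Bayes with Laplace-smoothed word likelihoods."""

    class_log_priors: np.ndarray  # (2,)
    feature_log_likelihoods: np.ndarray  # (2, n_features)
    alpha: float
    vocabulary: Vocabulary | None = None

    @property
    def n_features(self) -> int:
        return self.feature_log_likelihoods.shape[1]

    def predict_proba(self, x: ArrayLike) -> np.ndarray:
        X = _as_matrix(x, self.n_features)
        joint = X @ self.feature_log_likelihoods.T + self.class_log_priors
        joint = np.asarray(joint)
        m = joint.max(axis=1, keepdims=True)
        p = np.exp(joint - m)
        p /= p.sum(axis=1, keepdims=True)
        return p[:, POSITIVE]

    def predict(self, x: ArrayLike, t: float = 0.5) -> Prediction:
        score = float(self.predict_proba(x)[0])
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {t}")
        return Prediction(score=score, threshold=t)


def train_nb(
    x: ArrayLike | Sequence[FeatureVector],
    y: Sequence[int],
    alpha: float = 1.0,
    vocabulary: Vocabulary | None = None,
) -> NaiveBayesModel:
    """Closed-form multinomial NB: priors from class counts, smoothed
    per-class word frequencies for likelihoods."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if isinstance(x, (list, tuple)) and (not x or isinstance(x[0], FeatureVector)):
        if vocabulary is None:
            raise ValueError("vocabulary required with FeatureVector input")
        X = stack_features(list(x), vocabulary.size)
    else:
        X = _as_matrix(x, 0)
    yarr = np.asarray(y, dtype=int)
    if np.unique(yarr).size < 2:
        raise ValueError("training data must contain both classes")
    n, V = X.shape
    log_priors = np.zeros(2)
    log_lik = np.zeros((2, V))
    for c in (NEGATIVE, POSITIVE):
        mask = yarr == c
        log_priors[c] = np.log(mask.sum() / n)
        counts = np.asarray(X[mask].sum(axis=0)).ravel()
        log_lik[c] = np.log(counts + alpha) - np.log(counts.sum() + alpha * V)
    return NaiveBayesModel(
        class_log_priors=log_priors,
        feature_log_likelihoods=log_lik,
        alpha=alpha,
        vocabulary=vocabulary,
    )


# ---------------------------------------------------------------------------
# text-level wrapper and serialization

_FORMAT_VERSION = 1


@dataclass
class SentenceClassifier:
    """A text pipeline plus a trained model: scores raw sentences.

    This is the object the extraction pipeline carries around; it owns
    the frozen vocabulary, the stop-word list and the fitted weights, and
    round-trips losslessly through a single JSON file.
    """

    pipeline: TextPipeline
    model: MaxEntModel | NaiveBayesModel
    threshold: float = 0.5

    @property
    def kind(self) -> str:
        return "maxent" if isinstance(self.model, MaxEntModel) else "nb"

    def score(self, sentence: str) -> float:
        fv = self.pipeline.transform(sentence)
        return float(self.model.predict_proba(fv)[0])

    def score_many(self, sentences: Sequence[str]) -> np.ndarray:
        if not sentences:
            return np.zeros(0)
        X = self.pipeline.transform_matrix(sentences)
        return self.model.predict_proba(X)

    def predict(self, sentence: str, t: float | None = None) -> Prediction:
        t = self.threshold if t is None else t
        return Prediction(score=self.score(sentence), threshold=t)

    def save(self, path: str | Path) -> None:
        vocab = self.pipeline.vocabulary
        assert vocab is not None, "cannot save an unfitted classifier"
        stems = [None] * vocab.size
        for s, i in vocab.stem_to_index.items():
            stems[i] = s
        payload: dict = {
            "format_version": _FORMAT_VERSION,
            "kind": self.kind,
            "threshold": self.threshold,
            "stopwords": sorted(self.pipeline.stopwords),
            "vocabulary": stems,
        }
        if isinstance(self.model, MaxEntModel):
            payload["maxent"] = {
                "weights": self.model.weights.tolist(),
                "bias": self.model.bias.tolist(),
                "prior_variance": self.model.prior_variance,
            }
        else:
            payload["nb"] = {
                "class_log_priors": self.model.class_log_priors.tolist(),
                "feature_log_likelihoods":
                    self.model.feature_log_likelihoods.tolist(),
                "alpha": self.model.alpha,
            }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "SentenceClassifier":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format_version") != _FORMAT_VERSION:
            raise ValueError(
                f"unsupported model file version: {payload.get('format_version')}"
            )
        vocab = Vocabulary({s: i for i, s in enumerate(payload["vocabulary"])})
        pipeline = TextPipeline(
            stopwords=frozenset(payload["stopwords"]), vocabulary=vocab
        )
        model: MaxEntModel | NaiveBayesModel
        if payload["kind"] == "maxent":
            m = payload["maxent"]
            model = MaxEntModel(
                weights=np.asarray(m["weights"]),
                bias=np.asarray(m["bias"]),
                prior_variance=m["prior_variance"],
                vocabulary=vocab,
            )
        else:
            m = payload["nb"]
            model = NaiveBayesModel(
                class_log_priors=np.asarray(m["class_log_priors"]),
                feature_log_likelihoods=np.asarray(
                    m["feature_log_likelihoods"]
                ),
                alpha=m["alpha"],
                vocabulary=vocab,
            )
        return cls(pipeline=pipeline, model=model,
                   threshold=payload["threshold"])
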
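"""Bag-of-stems sentence features.

Sentences are turned into sparse count vectors by a fixed pipeline:
lowercase tokenization, stop-word removal, Porter stemming, and counting
against a vocabulary frozen at training time.  Word order is discarded
(bag of words); unseen stems at prediction time are silently dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

from ._porter import porter_stem

__all__ = [
    "Vocabulary",
    "FeatureVector",
    "TextPipeline",
    "tokenize",
    "stem",
    "remove_stopwords",
    "load_stopwords",
    "default_stopwords",
    "build_vocabulary",
    "vectorize",
]

# Maximal runs of alphanumerics; internal hyphens kept so chemical names
# like "d-glucose" stay one token.
_TOKEN_RE = re.compile(r"[0-9a-z]+(?:-[0-9a-z]+)*")


def tokenize(text: str) -> list[str]:
    """Lowercase a string and return its alphanumeric tokens.

    Punctuation is discarded; hyphens joining alphanumeric runs are kept
    inside a single token.
    """
    return _TOKEN_RE.findall(text.lower())


def stem(token: str) -> str:
    """Porter stem of a lowercase token."""
    return porter_stem(token)


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Read a stop-word file: one word per line, '#' comments allowed."""
    words = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            word = line.strip()
            if word and not word.startswith("#"):
                words.add(word.lower())
    return frozenset(words)


def default_stopwords() -> frozenset[str]:
    """The packaged SMART-style English stop-word list."""
    text = (resources.files("metsp") / "data" / "stopwords.txt").read_text(
        encoding="utf-8"
    )
    return frozenset(
        w.strip().lower()
        for w in text.splitlines()
        if w.strip() and not w.startswith("#")
    )


def remove_stopwords(
    tokens: Sequence[str], stopwords: frozenset[str]
) -> list[str]:
    """Drop stop-listed tokens, preserving order."""
    return [t for t in tokens if t not in stopwords]


@dataclass(frozen=True)
class Vocabulary:
    """Frozen stem -> dense index mapping built from training data."""

    stem_to_index: dict[str, int]

    @property
    def size(self) -> int:
        return len(self.stem_to_index)

    def __contains__(self, s: str) -> bool:
        return s in self.stem_to_index

    def __getitem__(self, s: str) -> int:
        return self.stem_to_index[s]


@dataclass(frozen=True)
class FeatureVector:
    """Sparse bag-of-stems counts: sorted distinct indices, counts >= 1."""

    indices: tuple[int, ...]
    values: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.indices) != len(self.values):
            raise ValueError("indices and values must align")

    @property
    def total(self) -> int:
        return int(sum(self.values))


def build_vocabulary(corpus: Iterable[Sequence[str]]) -> Vocabulary:
    """Assign dense indices to distinct stems in first-occurrence order.

    Deterministic given corpus order; an empty corpus is an error because
    a model cannot be trained without features.
    """
    mapping: dict[str, int] = {}
    seen_any = False
    for doc in corpus:
        seen_any = True
        for s in doc:
            if s not in mapping:
                mapping[s] = len(mapping)
    if not seen_any:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    return Vocabulary(mapping)


@dataclass
class TextPipeline:
    """Tokenize -> stop-word filter -> stem -> count, with a frozen vocab.

    ``vocabulary`` is None until :meth:`fit` is called; prediction-time
    stems absent from the vocabulary are dropped, never an error.
    """

    stopwords: frozenset[str] = field(default_factory=default_stopwords)
    vocabulary: Vocabulary | None = None

    def stems(self, text: str) -> list[str]:
        return [
            stem(t) for t in remove_stopwords(tokenize(text), self.stopwords)
        ]

    def fit(self, texts: Sequence[str]) -> "TextPipeline":
        self.vocabulary = build_vocabulary([self.stems(t) for t in texts])
        return self

    def transform(self, text: str) -> FeatureVector:
        if self.vocabulary is None:
            raise RuntimeError("pipeline vocabulary is not fitted")
        return vectorize_stems(self.stems(text), self.vocabulary)

    def transform_matrix(self, texts: Sequence[str]) -> sparse.csr_matrix:
        """Stack per-sentence vectors into an (n, vocab) CSR count matrix."""
        if self.vocabulary is None:
            raise RuntimeError("pipeline vocabulary is not fitted")
        rows, cols, data = [], [], []
        for i, text in enumerate(texts):
            fv = self.transform(text)
            rows.extend([i] * len(fv.indices))
            cols.extend(fv.indices)
            data.extend(fv.values)
        return sparse.csr_matrix(
            (np.asarray(data, dtype=float), (rows, cols)),
            shape=(len(texts), self.vocabulary.size),
        )


def vectorize_stems(stems: Sequence[str], vocabulary: Vocabulary) -> FeatureVector:
    counts: dict[int, int] = {}
    for s in stems:
        idx = vocabulary.stem_to_index.get(s)
        if idx is not None:
            counts[idx] = counts.get(idx, 0) + 1
    items = sorted(counts.items())
    return FeatureVector(
        indices=tuple(i for i, _ in items), values=tuple(v for _, v in items)
    )


def vectorize(
    sentence: str,
    vocabulary: Vocabulary,
    stopwords: frozenset[str] | None = None,
) -> FeatureVector:
    """Count in-vocabulary stems of a sentence (tokenize -> filter -> stem)."""
    sw = default_stopwords() if stopwords is None else stopwords
    stems = [stem(t) for t in remove_stopwords(tokenize(sentence), sw)]
    return vectorize_stems(stems, vocabulary)
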
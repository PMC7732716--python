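"""Linear classifiers and the document -> sentence screening pipeline.

Both tasks use L2-regularized logistic regression at unit strength (the
scikit-learn defaults), kept deliberately simple and interpretable: the
fitted model is exportable as (feature name, weight) pairs, and rebuilding
it from that export reproduces every probability.

The sentence model is trained only on sentences of ADE-containing
training articles — the negative articles contribute no positive
sentences and would otherwise swamp the positive class — while
prediction can run over every sentence ("flat" mode, used in evaluation)
or only over sentences of articles the document model accepted
("pipeline" mode, the deployed behavior).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.feature_extraction import DictVectorizer
from sklearn.linear_model import LogisticRegression

from .corpus import Article, corpus_hash
from .features import (DOCUMENT_GROUPS, SENTENCE_GROUPS, Tokenizer,
                       Vocabulary, default_tokenizer, featurize_document,
                       featurize_sentence, filter_groups,
                       fit_vocabulary_on_articles)

DEFAULT_THRESHOLD = 0.5


class LinearClassifier:
    """A fitted sparse logistic-regression model over named features.

    Stores an explicit feature-name -> weight map plus intercept, so the
    model is fully inspectable and round-trips through JSON exactly.
    """

    def __init__(self, weights: dict[str, float], intercept: float,
                 threshold: float = DEFAULT_THRESHOLD,
                 metadata: dict | None = None):
        self.weights = weights
        self.intercept = intercept
        self.threshold = threshold
        self.metadata = metadata or {}

    # -- training ----------------------------------------------------------
    @classmethod
    def fit(cls, vectors: Sequence[dict[str, float]], y: Sequence[int],
            seed: int = 0, threshold: float = DEFAULT_THRESHOLD,
            metadata: dict | None = None) -> "LinearClassifier":
        y = np.asarray(y)
        if len(set(y.tolist())) < 2:
            raise ValueError("training set contains a single class")
        vec = DictVectorizer()
        X = vec.fit_transform(vectors)
        lr = LogisticRegression(random_state=seed)  # library defaults: L2, C=1
        lr.fit(X, y)
        pos = list(lr.classes_).index(1)
        sign = 1.0 if pos == 1 else -1.0
        coef = lr.coef_[0] * sign
        intercept = float(lr.intercept_[0] * sign)
        names = vec.get_feature_names_out()
        weights = {name: float(w) for name, w in zip(names, coef) if w != 0.0}
        meta = dict(metadata or {})
        meta.setdefault("seed", seed)
        meta.setdefault("regularization", {"penalty": "l2", "C": 1.0})
        return cls(weights, intercept, threshold, meta)

    # -- prediction --------------------------------------------------------
    def decision(self, vector: dict[str, float]) -> float:
        w = self.weights
        return self.intercept + sum(v * w[k] for k, v in vector.items() if k in w)

    def predict_proba(self, vectors: Sequence[dict[str, float]]) -> np.ndarray:
        z = np.array([self.decision(v) for v in vectors])
        return 1.0 / (1.0 + np.exp(-z))

    def predict(self, vectors: Sequence[dict[str, float]]) -> np.ndarray:
        return (self.predict_proba(vectors) >= self.threshold).astype(int)

    # -- interpretability --------------------------------------------------
    def coefficients(self) -> list[tuple[str, float]]:
        """(feature, weight) pairs sorted by decreasing |weight|."""
        return sorted(self.weights.items(), key=lambda kv: (-abs(kv[1]), kv[0]))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({"weights": self.weights, "intercept": self.intercept,
                              "threshold": self.threshold, "metadata": self.metadata},
                             ensure_ascii=False)
        if path is not None:
            Path(path).write_text(payload, encoding="utf-8")
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "LinearClassifier":
        if isinstance(source, Path) or not source.lstrip().startswith("{"):
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = source
        rec = json.loads(text)
        return cls(rec["weights"], rec["intercept"], rec.get("threshold", 0.5),
                   rec.get("metadata", {}))


# ---------------------------------------------------------------------------
# estimators

class _AdeClassifierBase(BaseEstimator, ClassifierMixin):
    def __init__(self, groups=None, min_count: int = 1,
                 tokenizer: Tokenizer | None = None,
                 vocabulary: Vocabulary | None = None,
                 binary: bool = True,
                 threshold: float = DEFAULT_THRESHOLD, random_state: int = 0):
        self.groups = groups
        self.min_count = min_count
        self.tokenizer = tokenizer
        self.vocabulary = vocabulary
        self.binary = binary
        self.threshold = threshold
        self.random_state = random_state

    def _tok(self) -> Tokenizer:
        return self.tokenizer if self.tokenizer is not None else default_tokenizer

    def _fit_vocab(self, articles: Sequence[Article]) -> Vocabulary:
        if self.vocabulary is not None:
            return self.vocabulary
        return fit_vocabulary_on_articles(articles, self._tok(), self.min_count)


class AdeDocumentClassifier(_AdeClassifierBase):
    """ADE-containing article classifier (bag-of-words + entity features).

    Fitted attributes: ``vocab_``, ``model_`` (LinearClassifier),
    ``classes_``, ``train_hash_``.
    """

    def _groups(self):
        return tuple(self.groups) if self.groups is not None else DOCUMENT_GROUPS

    def _vectors(self, articles: Sequence[Article]) -> list[dict[str, float]]:
        tok = self._tok()
        return [filter_groups(featurize_document(a, self.vocab_, tok, self.binary),
                              self._groups())
                for a in articles]

    def fit(self, articles: Sequence[Article], y=None) -> "AdeDocumentClassifier":
        articles = list(articles)
        if not articles:
            raise ValueError("empty training set")
        if y is None:
            y = [a.doc_label for a in articles]
        self.train_hash_ = corpus_hash(articles)
        self.vocab_ = self._fit_vocab(articles)
        self.model_ = LinearClassifier.fit(
            self._vectors(articles), y, seed=self.random_state,
            threshold=self.threshold,
            metadata={"task": "document", "groups": list(self._groups()),
                      "train_hash": self.train_hash_})
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, articles: Sequence[Article]) -> np.ndarray:
        p = self.model_.predict_proba(self._vectors(articles))
        return np.column_stack([1.0 - p, p])

    def predict(self, articles: Sequence[Article]) -> np.ndarray:
        return self.model_.predict(self._vectors(articles))


class AdeSentenceClassifier(_AdeClassifierBase):
    """ADE-suggesting sentence classifier.

    Training instances are every sentence of the ADE-containing training
    articles only; prediction covers whichever sentences it is given.
    Fitted attributes: ``vocab_``, ``model_``, ``classes_``,
    ``train_hash_``, ``n_train_instances_``.
    """

    def _groups(self):
        return tuple(self.groups) if self.groups is not None else SENTENCE_GROUPS

    def _vectors(self, articles: Sequence[Article]) -> list[dict[str, float]]:
        tok = self._tok()
        return [filter_groups(featurize_sentence(a, i, self.vocab_, tok, self.binary),
                              self._groups())
                for a in articles for i in range(len(a.sentences))]

    def fit(self, articles: Sequence[Article], y=None) -> "AdeSentenceClassifier":
        positives = [a for a in list(articles) if a.doc_label == 1]
        if not positives:
            raise ValueError("no ADE-containing articles in the training set")
        self.train_hash_ = corpus_hash(positives)
        self.vocab_ = self._fit_vocab(positives)
        vectors = self._vectors(positives)
        labels = [s.sent_label for a in positives for s in a.sentences]
        self.n_train_instances_ = len(vectors)
        self.model_ = LinearClassifier.fit(
            vectors, labels, seed=self.random_state, threshold=self.threshold,
            metadata={"task": "sentence", "groups": list(self._groups()),
                      "train_hash": self.train_hash_})
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, articles: Sequence[Article]) -> np.ndarray:
        """P(non-ADE), P(ADE) per sentence, articles flattened in order."""
        p = self.model_.predict_proba(self._vectors(articles))
        return np.column_stack([1.0 - p, p])

    def predict(self, articles: Sequence[Article]) -> np.ndarray:
        return self.model_.predict(self._vectors(articles))


# ---------------------------------------------------------------------------
# screening pipeline

@dataclass
class SentencePrediction:
    sent_id: int
    label: int
    probability: float


@dataclass
class ScreeningResult:
    """Per-article screening outcome; ``sentences`` is None for articles
    the pipeline rejected at the document stage."""

    doc_id: str
    doc_label: int
    doc_probability: float
    sentences: list[SentencePrediction] | None = None


def screen(articles: Sequence[Article], doc_model: AdeDocumentClassifier,
           sent_model: AdeSentenceClassifier,
           mode: str = "pipeline") -> list[ScreeningResult]:
    """Run the two-stage screen.

    ``pipeline``: sentences are classified only inside articles the
    document model accepted (deployment behavior).  ``flat``: every
    sentence of every article is classified (evaluation behavior).
    """
    if mode not in ("pipeline", "flat"):
        raise ValueError(f"unknown mode {mode!r}")
    articles = list(articles)
    doc_p = doc_model.predict_proba(articles)[:, 1]
    results = []
    for article, p in zip(articles, doc_p):
        label = int(p >= doc_model.threshold)
        sent_preds = None
        if mode == "flat" or label == 1:
            sp = sent_model.predict_proba([article])[:, 1]
            sent_preds = [
                SentencePrediction(s.sent_id, int(q >= sent_model.threshold), float(q))
                for s, q in zip(article.sentences, sp)
            ]
        results.append(ScreeningResult(article.doc_id, label, float(p), sent_preds))
    return results


# ---------------------------------------------------------------------------
# functional wrappers

def train_document_model(train_articles: Sequence[Article],
                         vocab: Vocabulary | None = None,
                         config: dict | None = None,
                         seed: int = 0) -> AdeDocumentClassifier:
    config = dict(config or {})
    config.setdefault("random_state", seed)
    return AdeDocumentClassifier(vocabulary=vocab, **config).fit(train_articles)


def train_sentence_model(train_articles: Sequence[Article],
                         vocab: Vocabulary | None = None,
                         config: dict | None = None,
                         seed: int = 0) -> AdeSentenceClassifier:
    config = dict(config or {})
    config.setdefault("random_state", seed)
    return AdeSentenceClassifier(vocabulary=vocab, **config).fit(train_articles)
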
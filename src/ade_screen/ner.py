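"""Character-level named entity recognition for disease and drug names.

Sentences are tagged per character in the IOB2 scheme over the 5-tag
space {B-disease, I-disease, B-drug, I-drug, O}.  The trainable tagger,
:class:`CharNerTagger`, is a windowed maximum-entropy sequence labeler:
a multinomial logistic regression over sparse character features
(identity, script class, and character n-grams in a +/-window), decoded
with deterministic IOB2 repair.  One joint model covers both entity
types; ``joint=False`` trains a separate model per type.

``GoldSpanTagger`` is an oracle mode that returns the gold annotation,
so downstream normalization, featurization and classification can be
exercised independently of tagging quality.
"""

from __future__ import annotations

import pickle
from pathlib import Path
from typing import Iterable, Sequence

from sklearn.base import BaseEstimator
from sklearn.feature_extraction import DictVectorizer
from sklearn.linear_model import LogisticRegression

from .corpus import Article, EntitySpan, Sentence, corpus_hash

TAGS = ("O", "B-disease", "I-disease", "B-drug", "I-drug")

_PAD_LEFT = "<s>"
_PAD_RIGHT = "</s>"


class TagSequenceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# IOB2 encode / decode

def encode_iob2(sentence: Sentence) -> list[str]:
    """Map a sentence's spans to one IOB2 tag per character.

    Span [s, e) of type t becomes B-t at s and I-t at s+1..e-1; every
    other character is O.  Overlapping spans are rejected.
    """
    tags = ["O"] * len(sentence.text)
    prev_end = -1
    for span in sorted(sentence.spans, key=lambda sp: sp.start):
        if span.start < prev_end:
            raise TagSequenceError(
                f"overlapping spans at offset {span.start} in {sentence.text!r}")
        prev_end = span.end
        tags[span.start] = f"B-{span.etype}"
        for i in range(span.start + 1, span.end):
            tags[i] = f"I-{span.etype}"
    return tags


def repair_iob2(tags: Sequence[str]) -> list[str]:
    """Rewrite ill-formed I-x tags (no preceding B-x/I-x of the same type)
    as B-x.  Deterministic; keeps decoding total."""
    repaired: list[str] = []
    prev_type = None
    for tag in tags:
        if tag.startswith("I-"):
            etype = tag[2:]
            if prev_type != etype:
                tag = f"B-{etype}"
            prev_type = etype
        elif tag.startswith("B-"):
            prev_type = tag[2:]
        else:
            prev_type = None
        repaired.append(tag)
    return repaired


def decode_iob2(tags: Sequence[str], text: str) -> list[EntitySpan]:
    """Decode an IOB2 tag sequence into entity spans (after repair)."""
    if len(tags) != len(text):
        raise TagSequenceError(
            f"tag sequence length {len(tags)} != text length {len(text)}")
    tags = repair_iob2(tags)
    spans: list[EntitySpan] = []
    start = None
    etype = None
    for i, tag in enumerate(tags):
        if tag.startswith("B-"):
            if start is not None:
                spans.append(EntitySpan(start, i, etype, text[start:i]))
            start, etype = i, tag[2:]
        elif tag.startswith("I-"):
            pass  # same entity continues (repair guarantees type match)
        else:
            if start is not None:
                spans.append(EntitySpan(start, i, etype, text[start:i]))
            start = etype = None
    if start is not None:
        spans.append(EntitySpan(start, len(tags), etype, text[start:len(tags)]))
    return spans


# ---------------------------------------------------------------------------
# feature template

def char_class(ch: str) -> str:
    cp = ord(ch)
    if 0x3040 <= cp <= 0x309F:
        return "hiragana"
    if 0x30A0 <= cp <= 0x30FF:
        return "katakana"
    if 0x4E00 <= cp <= 0x9FFF:
        return "kanji"
    if ch.isdigit():
        return "digit"
    if ch.isalpha():
        return "latin" if cp < 0x3000 else "other-letter"
    if ch.isspace():
        return "space"
    return "symbol"


def _char_at(text: str, j: int) -> str:
    if j < 0:
        return _PAD_LEFT
    if j >= len(text):
        return _PAD_RIGHT
    return text[j]


_SEG_MAX = 24  # cap segment-feature length; long segments (e.g. Japanese
               # text without spaces) contribute prefix/suffix only


def _segment(text: str, i: int) -> tuple[int, int]:
    """Bounds of the maximal delimiter-free segment containing ``i``
    (delimiters: whitespace and sentence punctuation)."""
    delim = " \t\n。、．，.,"
    s = i
    while s > 0 and text[s - 1] not in delim and i - (s - 1) <= _SEG_MAX:
        s -= 1
    e = i + 1
    while e < len(text) and text[e] not in delim and e - s <= _SEG_MAX:
        e += 1
    return s, e


def char_features(text: str, i: int, window: int = 2) -> dict[str, float]:
    """Sparse features for position ``i``: character identities and script
    classes at offsets within +/-window (with boundary padding), character
    bigrams spanning the window, and enclosing-segment features (segment
    identity when short, prefix/suffix, and the position of ``i`` within
    the segment) that carry token-level evidence a single character
    window cannot."""
    if not 0 <= i < len(text):
        raise IndexError(f"position {i} out of range for text of length {len(text)}")
    feats: dict[str, float] = {}
    for d in range(-window, window + 1):
        ch = _char_at(text, i + d)
        feats[f"c[{d}]={ch}"] = 1.0
        cls = char_class(ch) if len(ch) == 1 else "pad"
        feats[f"t[{d}]={cls}"] = 1.0
    for d in range(-window, window):
        a = _char_at(text, i + d)
        b = _char_at(text, i + d + 1)
        feats[f"c[{d}:{d + 1}]={a}|{b}"] = 1.0
    s, e = _segment(text, i)
    seg = text[s:e]
    if len(seg) <= _SEG_MAX:
        feats[f"seg={seg}"] = 1.0
    feats[f"seg.prefix={seg[:3]}"] = 1.0
    feats[f"seg.suffix={seg[-3:]}"] = 1.0
    feats[f"seg.pos={'start' if i == s else ('end' if i == e - 1 else 'mid')}"] = 1.0
    feats[f"seg.len={min(len(seg), _SEG_MAX)}"] = 1.0
    return feats


FEATURE_TEMPLATE = ("char unigrams/bigrams in +/-window, script classes, boundary "
                    "padding, enclosing-segment identity/prefix/suffix/position")


# ---------------------------------------------------------------------------
# trainable tagger

class CharNerTagger(BaseEstimator):
    """Windowed maximum-entropy character tagger with IOB2 decoding.

    Parameters
    ----------
    window : int
        Half-width of the character context window.
    C : float
        Inverse L2 regularization strength of the underlying multinomial
        logistic regression.
    joint : bool
        If True (default) one model covers the 5-tag space; if False a
        separate binary-entity model is trained per entity type.
    random_state : int
        Recorded in the model metadata; training itself is deterministic
        given a fixed corpus.
    """

    def __init__(self, window: int = 2, C: float = 1.0, max_iter: int = 200,
                 joint: bool = True, random_state: int = 0):
        self.window = window
        self.C = C
        self.max_iter = max_iter
        self.joint = joint
        self.random_state = random_state

    # -- training ----------------------------------------------------------
    def _collect(self, articles: Iterable[Article], etypes: tuple[str, ...]):
        X: list[dict[str, float]] = []
        y: list[str] = []
        for article in articles:
            for sent in article.sentences:
                spans = [sp for sp in sent.spans if sp.etype in etypes]
                tags = encode_iob2(Sentence(sent.sent_id, sent.text,
                                            sent.sent_label, sent.criterion,
                                            tuple(spans)))
                for i in range(len(sent.text)):
                    X.append(char_features(sent.text, i, self.window))
                    y.append(tags[i])
        return X, y

    def _fit_one(self, X, y):
        vec = DictVectorizer()
        Xm = vec.fit_transform(X)
        labels = sorted(set(y))
        if len(labels) == 1:
            return {"vectorizer": vec, "clf": None, "constant": labels[0]}
        clf = LogisticRegression(C=self.C, max_iter=self.max_iter,
                                 random_state=self.random_state)
        clf.fit(Xm, y)
        return {"vectorizer": vec, "clf": clf, "constant": None}

    def fit(self, articles: Sequence[Article], y=None) -> "CharNerTagger":
        articles = list(articles)
        if not articles:
            raise ValueError("empty training set")
        if self.joint:
            X, ytags = self._collect(articles, ("disease", "drug"))
            self.models_ = {"joint": self._fit_one(X, ytags)}
        else:
            self.models_ = {}
            for etype in ("disease", "drug"):
                X, ytags = self._collect(articles, (etype,))
                self.models_[etype] = self._fit_one(X, ytags)
        self.meta_ = {
            "seed": self.random_state,
            "corpus_hash": corpus_hash(articles),
            "feature_template": FEATURE_TEMPLATE,
            "window": self.window,
            "joint": self.joint,
        }
        return self

    # -- prediction --------------------------------------------------------
    def _predict_tags_one(self, model, text: str) -> list[str]:
        if not text:
            return []
        if model["constant"] is not None:
            return [model["constant"]] * len(text)
        X = [char_features(text, i, self.window) for i in range(len(text))]
        Xm = model["vectorizer"].transform(X)
        return list(model["clf"].predict(Xm))

    def predict_tags(self, text: str) -> list[str]:
        """IOB2 tags for each character (repaired, well-formed)."""
        if self.joint:
            tags = self._predict_tags_one(self.models_["joint"], text)
            return repair_iob2(tags)
        # merge per-type predictions; earlier-starting span wins conflicts
        spans: list[EntitySpan] = []
        for etype in ("disease", "drug"):
            tags = self._predict_tags_one(self.models_[etype], text)
            spans.extend(decode_iob2(tags, text))
        spans.sort(key=lambda sp: (sp.start, sp.end))
        merged: list[EntitySpan] = []
        prev_end = 0
        for sp in spans:
            if sp.start >= prev_end:
                merged.append(sp)
                prev_end = sp.end
        sent = Sentence(0, text, 0, "none", tuple(merged))
        return encode_iob2(sent)

    def predict_spans(self, text: str) -> list[EntitySpan]:
        """Decoded, repaired, non-overlapping spans with surfaces filled."""
        return decode_iob2(self.predict_tags(text), text)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "CharNerTagger":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, CharNerTagger):
            raise TypeError(f"{path} does not contain a CharNerTagger")
        return model


class GoldSpanTagger:
    """Oracle tagger: returns the gold spans stored on each sentence."""

    def predict_spans(self, sentence: Sentence) -> list[EntitySpan]:
        return list(sentence.spans)


# ---------------------------------------------------------------------------
# functional wrappers

def train_ner(train: Sequence[Article], config: dict | None = None,
              seed: int = 0) -> CharNerTagger:
    """Train a tagger on articles carrying gold spans."""
    config = dict(config or {})
    config.setdefault("random_state", seed)
    return CharNerTagger(**config).fit(train)


def predict_spans(model: CharNerTagger, sentence_text: str) -> list[EntitySpan]:
    return model.predict_spans(sentence_text)


def apply_ner(model: CharNerTagger, articles: Sequence[Article]) -> list[Article]:
    """Replace gold spans with predicted spans throughout a corpus."""
    out = []
    for article in articles:
        sentences = tuple(
            Sentence(s.sent_id, s.text, s.sent_label, s.criterion,
                     tuple(model.predict_spans(s.text)))
            for s in article.sentences
        )
        out.append(Article(article.doc_id, article.raw_text, sentences,
                           article.doc_label))
    return out
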
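"""Sparse feature construction for document- and sentence-level classifiers.

Six feature groups are produced:

==================  ==========================================================
word_tokens         bag of word tokens in the unit's text
std_name            bag of standard disease/drug names of normalized mentions
sum_name            two features: total disease-mention and drug-mention counts
ctx_word_tokens     word tokens of the previous and next sentence, pooled
ctx_std_name        standard names in the previous and next sentence, pooled
ctx_sum_name        mention counts in the previous and next sentence, pooled
==================  ==========================================================

Document vectors use only the first three groups; sentence vectors use
all six.  ``sum_name`` counts every recognized mention whether or not it
was normalized; ``std_name`` covers only normalized mentions, so the two
groups are not redundant.  Feature names are "<group>:<key>", which is
what group filtering and ablation key on.

Bag groups (word_tokens, std_name and their context versions) default to
presence indicators rather than raw counts: article lengths span two
orders of magnitude here, and raw counts make the feature scale track
document length, drowning sparse cue words under the L2 penalty.  The
sum_name groups are counts by definition — the count is the feature.
``binary=False`` switches the bag groups back to count semantics.

The tokenizer is pluggable.  The default splits on whitespace and
separates sentence punctuation — adequate for whitespace-delimited text;
a morphological-analyzer adapter can be supplied for real Japanese prose.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .corpus import Article, Sentence, corpus_hash

GROUPS = ("word_tokens", "std_name", "sum_name",
          "ctx_word_tokens", "ctx_std_name", "ctx_sum_name")
DOCUMENT_GROUPS = GROUPS[:3]
SENTENCE_GROUPS = GROUPS

Tokenizer = Callable[[str], list[str]]

_TOKEN_RE = re.compile(r"[^\s。、．，.,;:!?()\[\]{}\"']+")


def default_tokenizer(text: str) -> list[str]:
    """Whitespace-and-punctuation word segmentation (deterministic, total)."""
    return _TOKEN_RE.findall(text)


@dataclass
class Vocabulary:
    """Token -> column-index map fitted on training folds only.

    Tokens whose training-corpus frequency is <= ``min_count`` are
    excluded; the default (1) removes words that appear only once.
    """

    index: dict[str, int]
    min_count: int = 1
    source_hash: str = ""

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def __len__(self) -> int:
        return len(self.index)


def fit_vocabulary(texts: Sequence[str], tokenizer: Tokenizer = default_tokenizer,
                   min_count: int = 1, source_hash: str = "") -> Vocabulary:
    """Build a vocabulary of tokens with corpus frequency > ``min_count``."""
    texts = list(texts)
    if not texts:
        raise ValueError("cannot fit a vocabulary on an empty text list")
    counts: Counter[str] = Counter()
    for text in texts:
        counts.update(tokenizer(text))
    kept = sorted(tok for tok, c in counts.items() if c > min_count)
    return Vocabulary(index={tok: i for i, tok in enumerate(kept)},
                      min_count=min_count, source_hash=source_hash)


def fit_vocabulary_on_articles(articles: Sequence[Article],
                               tokenizer: Tokenizer = default_tokenizer,
                               min_count: int = 1) -> Vocabulary:
    texts = [s.text for a in articles for s in a.sentences]
    return fit_vocabulary(texts, tokenizer, min_count,
                          source_hash=corpus_hash(articles))


# ---------------------------------------------------------------------------
# group construction

def _add_unit(feats: dict[str, float], sentences: Iterable[Sentence],
              vocab: Vocabulary, tokenizer: Tokenizer, prefix: str = "",
              binary: bool = True) -> None:
    """Accumulate word_tokens/std_name/sum_name features for a text unit
    (one sentence, a pooled context, or a whole article)."""
    for sent in sentences:
        for tok in tokenizer(sent.text):
            if tok in vocab:
                key = f"{prefix}word_tokens:{tok}"
                feats[key] = feats.get(key, 0.0) + 1.0
        for span in sent.spans:
            key = f"{prefix}sum_name:{span.etype}"
            feats[key] = feats.get(key, 0.0) + 1.0
            if span.standard is not None:
                key = f"{prefix}std_name:{span.standard}"
                feats[key] = feats.get(key, 0.0) + 1.0
    if binary:
        for key in feats:
            if "sum_name" not in feature_group(key):
                feats[key] = 1.0


def featurize_document(article: Article, vocab: Vocabulary,
                       tokenizer: Tokenizer = default_tokenizer,
                       binary: bool = True) -> dict[str, float]:
    """Document feature vector: the three in-text groups over the whole
    article; context groups never appear at the document level."""
    feats: dict[str, float] = {}
    _add_unit(feats, article.sentences, vocab, tokenizer, binary=binary)
    return feats


def featurize_sentence(article: Article, i: int, vocab: Vocabulary,
                       tokenizer: Tokenizer = default_tokenizer,
                       binary: bool = True) -> dict[str, float]:
    """Sentence feature vector: in-sentence groups for sentence ``i`` plus
    pooled context groups from sentences i-1 and i+1 (missing neighbors
    contribute nothing)."""
    n = len(article.sentences)
    if not 0 <= i < n:
        raise IndexError(f"sentence index {i} out of range (article has {n})")
    feats: dict[str, float] = {}
    _add_unit(feats, [article.sentences[i]], vocab, tokenizer, binary=binary)
    context = [article.sentences[j] for j in (i - 1, i + 1) if 0 <= j < n]
    _add_unit(feats, context, vocab, tokenizer, prefix="ctx_", binary=binary)
    return feats


def feature_group(name: str) -> str:
    """Group tag of a feature name ("<group>:<key>")."""
    return name.split(":", 1)[0]


def filter_groups(vector: dict[str, float], groups: Iterable[str]) -> dict[str, float]:
    """Keep only the features belonging to ``groups``."""
    keep = set(groups)
    return {k: v for k, v in vector.items() if feature_group(k) in keep}
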
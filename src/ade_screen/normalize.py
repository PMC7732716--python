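"""Dictionary normalization of disease/drug mentions by edit-distance similarity.

A mention surface is linked to the dictionary surface with the highest
similarity, where similarity(a, b) = 1 - Levenshtein(a, b) / max(|a|, |b|),
and replaced by that entry's standard name when the similarity strictly
exceeds the threshold (default 0.3).  Ties are broken toward the
lexicographically smallest dictionary surface, independent of file order.
"""

from __future__ import annotations

from typing import Sequence

import edlib

from .corpus import Article, Dictionary, EntitySpan, Sentence

DEFAULT_THRESHOLD = 0.3


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insert/delete/substitute)."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b)["editDistance"]


def similarity(a: str, b: str) -> float:
    """Length-normalized edit similarity in [0, 1]; 1.0 iff the strings
    are equal; symmetric."""
    if not a or not b:
        raise ValueError("similarity is undefined for empty strings")
    return 1.0 - levenshtein(a, b) / max(len(a), len(b))


def best_match(surface: str, dictionary: Dictionary) -> tuple[str | None, float]:
    """Highest-similarity dictionary surface for ``surface``.

    Returns (dictionary surface, similarity), or (None, 0.0) on an empty
    dictionary.  Equal-similarity ties go to the lexicographically
    smallest surface.
    """
    if not dictionary.entries:
        return None, 0.0
    if surface in dictionary.entries:
        return surface, 1.0
    best_surf: str | None = None
    best_sim = -1.0
    n = len(surface)
    for cand in sorted(dictionary.entries):
        # |len difference| lower-bounds the edit distance; a candidate whose
        # bound already caps similarity at or below the current best cannot win
        m = len(cand)
        if best_sim >= 0 and 1.0 - abs(n - m) / max(n, m) <= best_sim:
            continue
        sim = similarity(surface, cand)
        if sim > best_sim:
            best_surf, best_sim = cand, sim
    return best_surf, best_sim


def normalize_mention(span: EntitySpan, dictionary: Dictionary,
                      threshold: float = DEFAULT_THRESHOLD) -> EntitySpan:
    """Attach the standard name of the best dictionary match, if its
    similarity strictly exceeds ``threshold``; otherwise leave the mention
    unnormalized (standard = None)."""
    if dictionary.etype != span.etype:
        raise ValueError(
            f"dictionary etype {dictionary.etype!r} != span etype {span.etype!r}")
    surf, sim = best_match(span.surface, dictionary)
    if surf is not None and sim > threshold:
        return span.with_standard(dictionary.entries[surf])
    return span.with_standard(None)


def normalize_article(article: Article, disease_dict: Dictionary,
                      drug_dict: Dictionary,
                      threshold: float = DEFAULT_THRESHOLD) -> Article:
    """Normalize every mention in an article; returns a new Article."""
    dicts = {"disease": disease_dict, "drug": drug_dict}
    sentences = tuple(
        Sentence(s.sent_id, s.text, s.sent_label, s.criterion,
                 tuple(normalize_mention(sp, dicts[sp.etype], threshold)
                       for sp in s.spans))
        for s in article.sentences
    )
    return Article(article.doc_id, article.raw_text, sentences, article.doc_label)


def normalize_corpus(articles: Sequence[Article], disease_dict: Dictionary,
                     drug_dict: Dictionary,
                     threshold: float = DEFAULT_THRESHOLD) -> list[Article]:
    cache: dict[tuple[str, str], str | None] = {}
    dicts = {"disease": disease_dict, "drug": drug_dict}

    def norm_span(sp: EntitySpan) -> EntitySpan:
        key = (sp.etype, sp.surface)
        if key not in cache:
            cache[key] = normalize_mention(sp, dicts[sp.etype], threshold).standard
        return sp.with_standard(cache[key])

    out = []
    for article in articles:
        sentences = tuple(
            Sentence(s.sent_id, s.text, s.sent_label, s.criterion,
                     tuple(norm_span(sp) for sp in s.spans))
            for s in article.sentences
        )
        out.append(Article(article.doc_id, article.raw_text, sentences,
                           article.doc_label))
    return out
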
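"""Corpus data model and I/O.

An annotated corpus is a JSON-lines file (UTF-8, one article per line).
Each article carries its raw text, ordered sentences, a binary document
label ("ADE containing"), per-sentence binary labels ("ADE suggesting")
with an annotation-criterion tag, and gold disease/drug entity spans.
Term dictionaries are two-column TSV files mapping surface forms to
standard names, one per entity type.

Character offsets are 0-based, half-open, relative to the sentence text.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

ENTITY_TYPES = ("disease", "drug")
CRITERIA = ("A", "B", "none")


class CorpusFormatError(ValueError):
    """A record could not be parsed (message names the offending line)."""


class CorpusValidationError(ValueError):
    """A parsed record violates a corpus invariant (message names doc_id and rule)."""


@dataclass(frozen=True)
class EntitySpan:
    """A disease or drug mention located by character offsets in a sentence.

    ``standard`` is the canonical dictionary name assigned by normalization,
    or ``None`` when the mention is unnormalized.
    """

    start: int
    end: int
    etype: str
    surface: str
    standard: str | None = None

    def with_standard(self, standard: str | None) -> "EntitySpan":
        return dataclasses.replace(self, standard=standard)


@dataclass(frozen=True)
class Sentence:
    """One sentence with its ADE-suggesting label and gold entity spans.

    ``criterion`` records why a sentence was labeled positive: "A" (an
    adverse event mentioned after a drug prescription), "B" (an explicit
    statement of a suspicious ADE), or "none" for negative sentences.
    """

    sent_id: int
    text: str
    sent_label: int
    criterion: str = "none"
    spans: tuple[EntitySpan, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "spans", tuple(self.spans))


@dataclass(frozen=True)
class Article:
    """A medical article: raw text, ordered sentences, document label."""

    doc_id: str
    raw_text: str
    sentences: tuple[Sentence, ...]
    doc_label: int

    def __post_init__(self):
        object.__setattr__(self, "sentences", tuple(self.sentences))


@dataclass
class Dictionary:
    """Surface-form -> standard-name map for one entity type.

    Lookup is exact-string on surface forms; fuzzy matching is the job of
    the normalize module.  Many surfaces may share one standard name.
    """

    etype: str
    entries: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# validation

def _fail(doc_id: str, rule: str):
    raise CorpusValidationError(f"article {doc_id!r}: {rule}")


def validate_article(article: Article) -> None:
    """Enforce all type invariants; raise CorpusValidationError naming the rule."""
    if not article.doc_id:
        _fail(article.doc_id, "doc_id must be non-empty")
    if article.doc_label not in (0, 1):
        _fail(article.doc_id, f"doc_label must be 0 or 1, got {article.doc_label}")
    any_positive = False
    for pos, sent in enumerate(article.sentences):
        if sent.sent_id != pos:
            _fail(article.doc_id,
                  f"sentence at position {pos} has sent_id {sent.sent_id}; "
                  "sent_id must equal 0-based position")
        if not sent.text:
            _fail(article.doc_id, f"sentence {pos} has empty text")
        if sent.sent_label not in (0, 1):
            _fail(article.doc_id, f"sentence {pos}: sent_label must be 0 or 1")
        if sent.criterion not in CRITERIA:
            _fail(article.doc_id, f"sentence {pos}: unknown criterion {sent.criterion!r}")
        if (sent.criterion in ("A", "B")) != (sent.sent_label == 1):
            _fail(article.doc_id,
                  f"sentence {pos}: criterion {sent.criterion!r} inconsistent with "
                  f"sent_label {sent.sent_label} (criterion A/B iff label 1)")
        any_positive = any_positive or sent.sent_label == 1
        prev_end = -1
        for span in sent.spans:
            if span.etype not in ENTITY_TYPES:
                _fail(article.doc_id, f"sentence {pos}: unknown etype {span.etype!r}")
            if not (0 <= span.start < span.end <= len(sent.text)):
                _fail(article.doc_id,
                      f"sentence {pos}: span [{span.start},{span.end}) out of "
                      f"bounds for text of length {len(sent.text)}")
            if span.start < prev_end:
                _fail(article.doc_id,
                      f"sentence {pos}: spans overlap or are unsorted at offset {span.start}")
            prev_end = span.end
            if sent.text[span.start:span.end] != span.surface:
                _fail(article.doc_id,
                      f"sentence {pos}: span surface {span.surface!r} != text slice "
                      f"{sent.text[span.start:span.end]!r}")
    if article.doc_label != (1 if any_positive else 0):
        _fail(article.doc_id,
              f"doc_label {article.doc_label} inconsistent with sentence labels "
              "(doc_label 1 iff some sentence is ADE suggesting)")


def corpus_hash(articles: Iterable[Article]) -> str:
    """Stable content hash of a corpus, used for train/test leakage bookkeeping."""
    h = hashlib.sha256()
    for a in articles:
        h.update(a.doc_id.encode("utf-8"))
        h.update(b"\x00")
        for s in a.sentences:
            h.update(s.text.encode("utf-8"))
            h.update(b"\x01")
    return h.hexdigest()


# ---------------------------------------------------------------------------
# JSON-lines serialization

def _span_to_dict(s: EntitySpan) -> dict:
    return {"start": s.start, "end": s.end, "etype": s.etype,
            "surface": s.surface, "standard": s.standard}


def article_to_dict(article: Article) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "doc_id": article.doc_id,
        "raw_text": article.raw_text,
        "doc_label": article.doc_label,
        "sentences": [
            {
                "sent_id": s.sent_id,
                "text": s.text,
                "sent_label": s.sent_label,
                "criterion": s.criterion,
                "spans": [_span_to_dict(sp) for sp in s.spans],
            }
            for s in article.sentences
        ],
    }


def article_from_dict(rec: dict, schema_version: str = SCHEMA_VERSION) -> Article:
    if rec.get("schema_version") != schema_version:
        raise CorpusFormatError(
            f"schema_version {rec.get('schema_version')!r} != expected {schema_version!r}")
    try:
        sentences = tuple(
            Sentence(
                sent_id=s["sent_id"],
                text=s["text"],
                sent_label=s["sent_label"],
                criterion=s.get("criterion", "none"),
                spans=tuple(
                    EntitySpan(sp["start"], sp["end"], sp["etype"],
                               sp["surface"], sp.get("standard"))
                    for sp in s.get("spans", [])
                ),
            )
            for s in rec["sentences"]
        )
        article = Article(doc_id=rec["doc_id"], raw_text=rec["raw_text"],
                          sentences=sentences, doc_label=rec["doc_label"])
    except (KeyError, TypeError) as exc:
        raise CorpusFormatError(f"missing or malformed field: {exc}") from exc
    validate_article(article)
    return article


def read_corpus(path: str | Path, schema_version: str = SCHEMA_VERSION) -> list[Article]:
    """Read a JSON-lines corpus, validating every record.

    Raises CorpusFormatError naming the line on parse failure, and
    CorpusValidationError naming the doc_id and rule on invariant violation.
    """
    articles: list[Article] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"{path}: line {lineno}: invalid JSON: {exc}") from exc
            try:
                article = article_from_dict(rec, schema_version=schema_version)
            except CorpusFormatError as exc:
                raise CorpusFormatError(f"{path}: line {lineno}: {exc}") from exc
            if article.doc_id in seen:
                raise CorpusValidationError(
                    f"article {article.doc_id!r}: duplicate doc_id (line {lineno})")
            seen.add(article.doc_id)
            articles.append(article)
    return articles


def write_corpus(articles: Iterable[Article], path: str | Path) -> None:
    """Write articles as JSON lines; read_corpus(write_corpus(x)) round-trips."""
    with open(path, "w", encoding="utf-8") as fh:
        for article in articles:
            validate_article(article)
            fh.write(json.dumps(article_to_dict(article), ensure_ascii=False))
            fh.write("\n")


# ---------------------------------------------------------------------------
# dictionaries

def read_dictionary(path: str | Path, etype: str) -> Dictionary:
    """Read a two-column (surface TAB standard) TSV dictionary.

    Duplicate surface forms keep the first occurrence; a conflicting
    duplicate is logged as a warning.
    """
    if etype not in ENTITY_TYPES:
        raise ValueError(f"unknown entity type {etype!r}")
    entries: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise CorpusFormatError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns, got {len(cols)}")
            surface, standard = cols
            if not surface or not standard:
                raise CorpusFormatError(
                    f"{path}: line {lineno}: empty surface or standard name")
            if surface in entries:
                if entries[surface] != standard:
                    logger.warning(
                        "%s: line %d: duplicate surface %r with conflicting standard "
                        "%r; keeping first (%r)", path, lineno, surface, standard,
                        entries[surface])
                continue
            entries[surface] = standard
    return Dictionary(etype=etype, entries=entries)


def write_dictionary(dictionary: Dictionary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for surface, standard in dictionary.entries.items():
            fh.write(f"{surface}\t{standard}\n")
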
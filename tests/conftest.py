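"""Shared fixtures: small seeded synthetic corpora and dictionaries."""

import pytest

from ade_screen.corpus import Article, validate_article
from ade_screen.normalize import normalize_corpus
from ade_screen.synthetic import (GeneratorConfig, generate_corpus,
                                  generate_dictionaries)


@pytest.fixture(scope="session")
def small_setup():
    """60-document strong-signal corpus with its dictionaries (seed 1)."""
    cfg = GeneratorConfig(n_docs=60, seed=1)
    dicts = generate_dictionaries(cfg)
    corpus = generate_corpus(cfg, dicts)
    return cfg, dicts, corpus


@pytest.fixture(scope="session")
def small_corpus(small_setup):
    return small_setup[2]


@pytest.fixture(scope="session")
def small_dicts(small_setup):
    return small_setup[1]


@pytest.fixture(scope="session")
def small_norm_corpus(small_setup):
    _, dicts, corpus = small_setup
    return normalize_corpus(corpus, *dicts)


def truncate_articles(articles, k=8):
    """Keep the first k sentences of each article (recomputing the document
    label), for tests that need short articles."""
    out = []
    for a in articles:
        sents = a.sentences[:k]
        label = 1 if any(s.sent_label for s in sents) else 0
        art = Article(a.doc_id, "".join(s.text for s in sents), sents, label)
        validate_article(art)
        out.append(art)
    return out


@pytest.fixture(scope="session")
def ner_corpus():
    """Short articles over a closed mention vocabulary (no surface noise),
    split into train/test for tagger recovery checks."""
    cfg = GeneratorConfig(n_docs=60, seed=3, bg_entity_rate=0.5,
                          variant_noise=0.0)
    dicts = generate_dictionaries(cfg)
    arts = truncate_articles(generate_corpus(cfg, dicts))
    return arts[:45], arts[45:]
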
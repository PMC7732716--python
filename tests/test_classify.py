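"""Document/sentence classifiers and the screening pipeline."""

import numpy as np
import pytest

from ade_screen.classify import (AdeDocumentClassifier, AdeSentenceClassifier,
                                 LinearClassifier, screen,
                                 train_document_model, train_sentence_model)
from ade_screen.evaluate import _f1_from_predictions
from ade_screen.normalize import normalize_corpus
from ade_screen.synthetic import (GeneratorConfig, generate_corpus,
                                  generate_dictionaries)


@pytest.fixture(scope="module")
def split_corpus():
    """120 strong-signal articles, normalized, split 80/40 (seed 42)."""
    cfg = GeneratorConfig(n_docs=120, seed=42)
    dicts = generate_dictionaries(cfg)
    arts = normalize_corpus(generate_corpus(cfg, dicts), *dicts)
    return arts[:80], arts[80:]


class TestDocumentClassifier:
    def test_recovers_cue_signal_on_held_out_articles(self, split_corpus):
        train, test = split_corpus
        clf = AdeDocumentClassifier(random_state=42).fit(train)
        f1 = _f1_from_predictions([a.doc_label for a in test],
                                  clf.predict(test))
        assert f1 >= 0.9, f"held-out F1 {f1:.3f}"

    def test_permuted_labels_give_no_spurious_signal(self, split_corpus):
        """With labels shuffled, held-out F1 must not beat the trivial
        always-positive screen by more than noise."""
        train, test = split_corpus
        rng = np.random.default_rng(0)
        y = rng.permutation([a.doc_label for a in train])
        clf = AdeDocumentClassifier(random_state=42).fit(train, y=y)
        f1 = _f1_from_predictions([a.doc_label for a in test],
                                  clf.predict(test))
        p = np.mean([a.doc_label for a in test])
        baseline = 2 * p / (1 + p)
        assert f1 <= baseline + 0.1

    def test_same_seed_gives_identical_weights(self, split_corpus):
        train, _ = split_corpus
        m1 = train_document_model(train, seed=3)
        m2 = train_document_model(train, seed=3)
        assert m1.model_.weights == m2.model_.weights
        assert m1.model_.intercept == m2.model_.intercept

    def test_single_class_training_rejected(self, split_corpus):
        train, _ = split_corpus
        positives = [a for a in train if a.doc_label == 1]
        with pytest.raises(ValueError, match="single class"):
            AdeDocumentClassifier().fit(positives)

    def test_vocabulary_fitted_on_training_articles_only(self, split_corpus):
        from ade_screen.corpus import corpus_hash
        train, _ = split_corpus
        clf = AdeDocumentClassifier().fit(train)
        assert clf.vocab_.source_hash == corpus_hash(train)


class TestSentenceClassifier:
    def test_training_instances_are_positive_article_sentences(self, split_corpus):
        train, _ = split_corpus
        clf = AdeSentenceClassifier(random_state=0).fit(train)
        expected = sum(len(a.sentences) for a in train if a.doc_label == 1)
        assert clf.n_train_instances_ == expected

    def test_recovers_sentence_signal(self, split_corpus):
        train, test = split_corpus
        clf = AdeSentenceClassifier(random_state=42).fit(train)
        y = [s.sent_label for a in test for s in a.sentences]
        f1 = _f1_from_predictions(y, clf.predict(test))
        assert f1 >= 0.6, f"held-out sentence F1 {f1:.3f}"

    def test_same_seed_gives_identical_weights(self, split_corpus):
        train, _ = split_corpus
        m1 = train_sentence_model(train, seed=3)
        m2 = train_sentence_model(train, seed=3)
        assert m1.model_.weights == m2.model_.weights

    def test_no_positive_articles_rejected(self, split_corpus):
        train, _ = split_corpus
        negatives = [a for a in train if a.doc_label == 0]
        with pytest.raises(ValueError, match="ADE-containing"):
            AdeSentenceClassifier().fit(negatives)


class TestLinearClassifierInterpretability:
    def test_export_round_trip_reproduces_probabilities(self, split_corpus,
                                                        tmp_path):
        train, test = split_corpus
        clf = AdeDocumentClassifier(random_state=0).fit(train)
        path = tmp_path / "model.json"
        clf.model_.to_json(path)
        rebuilt = LinearClassifier.from_json(path)
        vectors = clf._vectors(test)
        np.testing.assert_allclose(rebuilt.predict_proba(vectors),
                                   clf.model_.predict_proba(vectors),
                                   rtol=0, atol=1e-12)

    def test_coefficients_sorted_by_magnitude(self, split_corpus):
        train, _ = split_corpus
        clf = AdeDocumentClassifier(random_state=0).fit(train)
        mags = [abs(w) for _, w in clf.model_.coefficients()]
        assert mags == sorted(mags, reverse=True)

    def test_adding_top_positive_feature_never_lowers_probability(self, split_corpus):
        train, test = split_corpus
        model = AdeDocumentClassifier(random_state=0).fit(train).model_
        top = max(model.weights, key=lambda k: model.weights[k])
        vec = dict(AdeDocumentClassifier(random_state=0).fit(train)._vectors(test[:1])[0])
        p0 = model.predict_proba([vec])[0]
        vec[top] = vec.get(top, 0.0) + 1.0
        assert model.predict_proba([vec])[0] >= p0


@pytest.fixture(scope="module")
def models(split_corpus):
    train, _ = split_corpus
    return (AdeDocumentClassifier(random_state=0).fit(train),
            AdeSentenceClassifier(random_state=0).fit(train))


class TestScreeningPipeline:
    def test_pipeline_skips_rejected_articles(self, split_corpus, models):
        _, test = split_corpus
        results = screen(test, *models, mode="pipeline")
        for r in results:
            assert (r.sentences is None) == (r.doc_label == 0)

    def test_flat_mode_scores_every_sentence(self, split_corpus, models):
        _, test = split_corpus
        results = screen(test, *models, mode="flat")
        for art, r in zip(test, results):
            assert len(r.sentences) == len(art.sentences)
            assert all(0.0 <= s.probability <= 1.0 for s in r.sentences)

    def test_modes_agree_on_accepted_articles(self, split_corpus, models):
        _, test = split_corpus
        flat = screen(test, *models, mode="flat")
        pipe = screen(test, *models, mode="pipeline")
        for f, p in zip(flat, pipe):
            assert f.doc_probability == p.doc_probability
            if p.sentences is not None:
                assert [s.probability for s in f.sentences] == \
                       [s.probability for s in p.sentences]

    def test_unknown_mode_rejected(self, split_corpus, models):
        with pytest.raises(ValueError, match="mode"):
            screen(split_corpus[1][:1], *models, mode="cascade")
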
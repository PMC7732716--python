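"""Folding, metrics, cross-validation, ablation and learning curves."""

import numpy as np
import pytest

from ade_screen.corpus import Article, Sentence
from ade_screen.evaluate import (EvalConfig, ablation, cohen_kappa,
                                 cross_validate, learning_curve, pr_curve,
                                 prf, stratified_kfold)


def label_only_articles(labels):
    arts = []
    for i, y in enumerate(labels):
        sent = Sentence(0, "x。", y, "A" if y else "none", ())
        arts.append(Article(f"a{i}", sent.text, (sent,), y))
    return arts


class TestStratifiedKFold:
    def test_proportion_kept_within_one_document(self):
        arts = label_only_articles([1] * 6 + [0] * 4)
        fa = stratified_kfold(arts, k=5, seed=0)
        for fold in range(5):
            _, test = fa.split(arts, fold)
            assert len(test) == 2
            assert 1 <= sum(a.doc_label for a in test) <= 2

    def test_two_folds_on_four_balanced_articles(self):
        arts = label_only_articles([1, 1, 0, 0])
        fa = stratified_kfold(arts, k=2, seed=1)
        for fold in range(2):
            _, test = fa.split(arts, fold)
            assert sum(a.doc_label for a in test) == 1
            assert len(test) == 2

    def test_deterministic_given_seed(self):
        arts = label_only_articles([1, 0] * 10)
        assert stratified_kfold(arts, 5, 9).folds == \
               stratified_kfold(arts, 5, 9).folds

    def test_small_class_warns(self):
        arts = label_only_articles([1, 1, 1, 0])
        with pytest.warns(UserWarning, match="fewer than"):
            stratified_kfold(arts, k=2, seed=0)

    def test_missing_class_rejected(self):
        arts = label_only_articles([1, 1, 1, 1])
        with pytest.raises(ValueError, match="both classes"):
            stratified_kfold(arts, k=2, seed=0)

    def test_proportion_on_synthetic_corpus(self, small_corpus):
        fa = stratified_kfold(small_corpus, k=5, seed=0)
        n_pos = sum(a.doc_label for a in small_corpus)
        share = n_pos / len(small_corpus)
        for fold in range(5):
            _, test = fa.split(small_corpus, fold)
            expected = share * len(test)
            assert abs(sum(a.doc_label for a in test) - expected) <= 1


class TestPrf:
    @pytest.mark.parametrize("counts,expected", [
        ((5, 0, 0), (1.0, 1.0, 1.0)),
        ((3, 1, 2), (0.75, 0.6, 2 * 0.75 * 0.6 / 1.35)),
        ((0, 0, 0), (0.0, 0.0, 0.0)),
        ((0, 5, 0), (0.0, 0.0, 0.0)),
    ])
    def test_known_values(self, counts, expected):
        assert prf(*counts) == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            prf(-1, 0, 0)


def brute_force_pr(scores, labels):
    points = []
    for t in sorted(set(scores)):
        pred = [s >= t for s in scores]
        tp = sum(p and y for p, y in zip(pred, labels))
        fp = sum(p and not y for p, y in zip(pred, labels))
        fn = sum((not p) and y for p, y in zip(pred, labels))
        points.append((t, tp / (tp + fp) if tp + fp else 0.0,
                       tp / (tp + fn)))
    return points


class TestPrCurve:
    def test_perfect_separation_contains_ideal_point(self):
        curve = pr_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert any(p == 1.0 and r == 1.0 for _, p, r in curve.points)

    def test_constant_scores_collapse_to_single_point(self):
        curve = pr_curve([0.5] * 4, [1, 0, 1, 0])
        assert curve.points == [(0.5, 0.5, 1.0)]

    def test_agrees_with_brute_force_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(2, 30))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)
            curve = pr_curve(scores, labels)
            assert curve.points == pytest.approx(
                brute_force_pr(list(scores), list(labels)))

    def test_invariants(self):
        rng = np.random.default_rng(6)
        scores = rng.random(50)
        labels = rng.integers(0, 2, size=50)
        labels[0], labels[1] = 0, 1
        curve = pr_curve(scores, labels)
        ts = curve.thresholds()
        assert all(a < b for a, b in zip(ts, ts[1:]))
        recalls = [r for _, _, r in curve.points]
        assert all(a >= b for a, b in zip(recalls, recalls[1:]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            pr_curve([0.1, 0.9], [1, 1])


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa([1, 0, 1, 0], [1, 0, 1, 0]) == 1.0

    def test_chance_level_agreement(self):
        assert cohen_kappa([1, 1, 0, 0], [1, 0, 1, 0]) == 0.0

    def test_symmetric_and_matches_brute_force(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            n = int(rng.integers(2, 40))
            a = rng.integers(0, 2, size=n)
            b = rng.integers(0, 2, size=n)
            pa, pb = a.mean(), b.mean()
            pe = pa * pb + (1 - pa) * (1 - pb)
            if pe == 1.0:
                continue
            po = (a == b).mean()
            expected = (po - pe) / (1 - pe)
            assert cohen_kappa(a, b) == pytest.approx(expected)
            assert cohen_kappa(a, b) == pytest.approx(cohen_kappa(b, a))

    def test_undefined_when_both_raters_constant_and_equal(self):
        with pytest.raises(ValueError, match="undefined"):
            cohen_kappa([1, 1, 1], [1, 1, 1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa([1, 0], [1])


class TestCrossValidate:
    def test_sentence_task_evaluates_every_test_sentence(self, small_norm_corpus):
        res = cross_validate(small_norm_corpus, "sentence", seed=0)
        assert sum(res.n_eval) == sum(len(a.sentences)
                                      for a in small_norm_corpus)

    def test_sd_uses_population_formula(self, small_norm_corpus):
        res = cross_validate(small_norm_corpus, "document", seed=0)
        assert len(res.fold_f1) == 5
        assert res.sd_f1 == pytest.approx(float(np.std(res.fold_f1)))
        assert res.metadata["sd_formula"] == "population"

    def test_unknown_task_rejected(self, small_norm_corpus):
        with pytest.raises(ValueError, match="task"):
            cross_validate(small_norm_corpus, "paragraph")

    def test_repeat_run_is_bit_identical(self, small_norm_corpus):
        r1 = cross_validate(small_norm_corpus, "document", seed=4)
        r2 = cross_validate(small_norm_corpus, "document", seed=4)
        assert r1.fold_f1 == r2.fold_f1
        assert r1.pr_curve.points == r2.pr_curve.points


class TestAblation:
    def test_removing_unused_dummy_group_changes_nothing(self, small_norm_corpus):
        cfg = EvalConfig(extra_groups=("dummy",))
        report = ablation(small_norm_corpus, "document", ["dummy"], cfg, seed=0)
        assert report.delta_f1["dummy"] == 0.0

    def test_unknown_group_rejected(self, small_norm_corpus):
        with pytest.raises(ValueError, match="unknown"):
            ablation(small_norm_corpus, "document", ["nonexistent"], seed=0)

    def test_document_task_rejects_context_groups(self, small_norm_corpus):
        with pytest.raises(ValueError, match="ctx_word_tokens"):
            ablation(small_norm_corpus, "document", ["ctx_word_tokens"], seed=0)


class TestLearningCurve:
    def test_full_fraction_reproduces_cross_validation(self, small_norm_corpus):
        res = cross_validate(small_norm_corpus, "document", seed=2)
        [(frac, _, val_f1)] = learning_curve(small_norm_corpus, "document",
                                             [1.0], seed=2)
        assert frac == 1.0
        assert val_f1 == res.mean_f1

    def test_fraction_out_of_range_rejected(self, small_norm_corpus):
        with pytest.raises(ValueError):
            learning_curve(small_norm_corpus, "document", [0.0], seed=0)
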
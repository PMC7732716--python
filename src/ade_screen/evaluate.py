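"""Evaluation harness: stratified k-fold CV, F1, PR curves, ablation,
learning curves, and Cohen kappa.

Cross-validation folds articles (never sentences), keeping the
document-label proportion within one article of the global proportion.
For the sentence task, each fold's model trains only on sentences of
ADE-containing training articles while every sentence of the test fold
is evaluated, so the reported sentence F1 reflects the full screening
population.  Per-fold vocabularies are fitted on training folds only;
a corpus-hash assertion guards against leakage.

The positive class throughout is "ADE containing" / "ADE suggesting".
The across-fold standard deviation uses the population formula
(divide by k), recorded in the result metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classify import AdeDocumentClassifier, AdeSentenceClassifier
from .corpus import Article, corpus_hash
from .features import DOCUMENT_GROUPS, SENTENCE_GROUPS

TASKS = ("document", "sentence")


@dataclass
class EvalConfig:
    """Knobs of the CV harness; defaults follow the classifier defaults."""

    k: int = 5
    groups: tuple[str, ...] | None = None   # None = all groups valid for the task
    min_count: int = 1
    tokenizer: object = None
    binary: bool = True
    threshold: float = 0.5
    extra_groups: tuple[str, ...] = ()      # extra ablatable group names (e.g. a dummy)


@dataclass
class FoldAssignment:
    """doc_id -> fold index in 0..k-1, stratified by document label."""

    folds: dict[str, int]
    k: int
    seed: int

    def split(self, articles: Sequence[Article], fold: int):
        train = [a for a in articles if self.folds[a.doc_id] != fold]
        test = [a for a in articles if self.folds[a.doc_id] == fold]
        return train, test


@dataclass
class PRCurve:
    """Precision/recall at each distinct decision threshold.

    Thresholds are strictly increasing; recall is non-increasing along
    the curve (predictions are positive when score >= threshold).
    """

    points: list[tuple[float, float, float]]  # (threshold, precision, recall)

    def thresholds(self):
        return [p[0] for p in self.points]


@dataclass
class CVResult:
    mean_f1: float
    sd_f1: float
    fold_f1: list[float]
    best_fold: int
    pr_curve: PRCurve
    n_eval: list[int]
    metadata: dict = field(default_factory=dict)


@dataclass
class AblationReport:
    """Change in mean CV F1 when one feature group is removed.

    delta_f1[g] = mean F1 without group g  -  baseline mean F1, computed
    on identical folds with the same seed.
    """

    task: str
    baseline_mean_f1: float
    delta_f1: dict[str, float]
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# folding and elementary metrics

def stratified_kfold(articles: Sequence[Article], k: int = 5,
                     seed: int = 0) -> FoldAssignment:
    """Assign articles to k folds, keeping the label proportion
    (each fold's positive count within 1 of the proportional share)."""
    articles = list(articles)
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.array([a.doc_label for a in articles])
    for cls in (0, 1):
        n_cls = int((y == cls).sum())
        if n_cls == 0:
            raise ValueError("both classes must be present")
        if n_cls < k:
            warnings.warn(f"class {cls} has {n_cls} articles, fewer than "
                          f"k={k}; some folds will lack it")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: dict[str, int] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # sklearn repeats ours
        splits = list(skf.split(np.zeros(len(y)), y))
    for fold, (_, test_idx) in enumerate(splits):
        for i in test_idx:
            folds[articles[i].doc_id] = fold
    return FoldAssignment(folds=folds, k=k, seed=seed)


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall, F1 with the zero-denominator convention of 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def _f1_from_predictions(y_true, y_pred) -> float:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    return prf(tp, fp, fn)[2]


def pr_curve(scores: Sequence[float], labels: Sequence[int]) -> PRCurve:
    """Precision-recall curve with one point per distinct score, treating
    each distinct score as the decision threshold (positive iff
    score >= threshold)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores) != len(labels):
        raise ValueError("scores and labels must have equal length")
    if len(set(labels.tolist())) < 2:
        raise ValueError("labels contain a single class; PR curve undefined")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    l = labels[order]
    cum_tp = np.cumsum(l)          # positives among the top-i scores
    n_pos = int(labels.sum())
    points = []
    # walk thresholds from high to low; at threshold t, predictions positive
    # are exactly the scores >= t
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j + 1 < n and s[j + 1] == s[i]:
            j += 1
        t = float(s[i])
        npred = j + 1
        tp = int(cum_tp[j])
        precision = tp / npred
        recall = tp / n_pos
        points.append((t, precision, recall))
        i = j + 1
    points.reverse()  # strictly increasing thresholds
    return PRCurve(points=points)


def cohen_kappa(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Chance-corrected agreement between two binary annotations."""
    a = np.asarray(labels_a, dtype=int)
    b = np.asarray(labels_b, dtype=int)
    if len(a) != len(b) or len(a) == 0:
        raise ValueError("label lists must be non-empty and of equal length")
    po = float((a == b).mean())
    pa1, pb1 = float(a.mean()), float(b.mean())
    pe = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    if pe == 1.0:
        raise ValueError("kappa undefined: both annotators constant and equal "
                         "(chance agreement is 1)")
    return (po - pe) / (1 - pe)


# ---------------------------------------------------------------------------
# cross-validation

def _task_groups(task: str, config: EvalConfig) -> tuple[str, ...]:
    if config.groups is not None:
        return tuple(config.groups)
    return DOCUMENT_GROUPS if task == "document" else SENTENCE_GROUPS


def _make_estimator(task: str, groups, config: EvalConfig, seed: int):
    cls = AdeDocumentClassifier if task == "document" else AdeSentenceClassifier
    return cls(groups=groups, min_count=config.min_count,
               tokenizer=config.tokenizer, binary=config.binary,
               threshold=config.threshold, random_state=seed)


def _fit_and_score(task, groups, config, seed, train, test):
    """Fit one fold's model; return (test scores, test labels, model)."""
    est = _make_estimator(task, groups, config, seed)
    est.fit(train)
    # leakage guard: the fitted vocabulary must come from the training fold
    expected = corpus_hash(train if task == "document"
                           else [a for a in train if a.doc_label == 1])
    assert est.vocab_.source_hash == expected, "vocabulary fitted outside training fold"
    scores = est.predict_proba(test)[:, 1]
    if task == "document":
        y = [a.doc_label for a in test]
    else:
        y = [s.sent_label for a in test for s in a.sentences]
    return scores, np.asarray(y), est


def cross_validate(articles: Sequence[Article], task: str,
                   config: EvalConfig | None = None, seed: int = 0,
                   folds: FoldAssignment | None = None) -> CVResult:
    """Stratified k-fold CV; returns mean/SD/per-fold F1 and the PR curve
    of the best fold."""
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    config = config or EvalConfig()
    articles = list(articles)
    if folds is None:
        folds = stratified_kfold(articles, k=config.k, seed=seed)
    groups = _task_groups(task, config)
    fold_f1: list[float] = []
    n_eval: list[int] = []
    fold_scores = []
    for fold in range(folds.k):
        train, test = folds.split(articles, fold)
        scores, y, _ = _fit_and_score(task, groups, config, seed, train, test)
        preds = (scores >= config.threshold).astype(int)
        fold_f1.append(_f1_from_predictions(y, preds))
        n_eval.append(len(y))
        fold_scores.append((scores, y))
    best = int(np.argmax(fold_f1))
    curve = pr_curve(*fold_scores[best])
    return CVResult(
        mean_f1=float(np.mean(fold_f1)),
        sd_f1=float(np.std(fold_f1)),  # population formula (divide by k)
        fold_f1=[float(f) for f in fold_f1],
        best_fold=best,
        pr_curve=curve,
        n_eval=n_eval,
        metadata={"task": task, "k": folds.k, "seed": seed,
                  "fold_seed": folds.seed, "groups": list(groups),
                  "sd_formula": "population"},
    )


def ablation(articles: Sequence[Article], task: str,
             groups: Sequence[str], config: EvalConfig | None = None,
             seed: int = 0) -> AblationReport:
    """Remove each named feature group in turn and report the change in
    mean CV F1 against an all-groups baseline on identical folds."""
    config = config or EvalConfig()
    task_groups = _task_groups(task, config)
    valid = set(task_groups) | set(config.extra_groups)
    for g in groups:
        if g not in valid:
            raise ValueError(f"unknown or invalid feature group for {task} task: {g!r}")
    articles = list(articles)
    folds = stratified_kfold(articles, k=config.k, seed=seed)
    baseline = cross_validate(articles, task, config, seed=seed, folds=folds)
    delta: dict[str, float] = {}
    for g in groups:
        reduced = tuple(x for x in task_groups if x != g)
        rcfg = EvalConfig(k=config.k, groups=reduced, min_count=config.min_count,
                          tokenizer=config.tokenizer, binary=config.binary,
                          threshold=config.threshold)
        res = cross_validate(articles, task, rcfg, seed=seed, folds=folds)
        delta[g] = res.mean_f1 - baseline.mean_f1
    return AblationReport(task=task, baseline_mean_f1=baseline.mean_f1,
                          delta_f1=delta,
                          metadata={"k": config.k, "seed": seed})


# ---------------------------------------------------------------------------
# learning curve

def _stratified_subsample(articles: Sequence[Article], fraction: float,
                          rng: np.random.Generator) -> list[Article]:
    if fraction >= 1.0:
        return list(articles)
    out: list[Article] = []
    for cls in (0, 1):
        members = [a for a in articles if a.doc_label == cls]
        n = max(1, round(fraction * len(members))) if members else 0
        if members:
            idx = rng.choice(len(members), size=n, replace=False)
            out.extend(members[i] for i in sorted(idx))
    return out


def learning_curve(articles: Sequence[Article], task: str,
                   fractions: Sequence[float],
                   config: EvalConfig | None = None,
                   seed: int = 0) -> list[tuple[float, float, float]]:
    """Train on stratified subsamples of each training fold and report
    (fraction, training F1, validation F1) averaged over folds.

    Fraction 1.0 reproduces cross_validate's mean F1 exactly (same folds,
    same seed).  A fraction whose subsample is single-class is skipped
    with a warning.
    """
    config = config or EvalConfig()
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError(f"fractions must lie in (0, 1], got {f}")
    articles = list(articles)
    folds = stratified_kfold(articles, k=config.k, seed=seed)
    groups = _task_groups(task, config)
    results: list[tuple[float, float, float]] = []
    for frac_i, frac in enumerate(fractions):
        train_f1s, val_f1s = [], []
        skipped = False
        for fold in range(folds.k):
            train, test = folds.split(articles, fold)
            rng = np.random.default_rng((seed, frac_i, fold))
            sub = _stratified_subsample(train, frac, rng)
            try:
                scores, y, est = _fit_and_score(task, groups, config, seed, sub, test)
            except ValueError as exc:
                warnings.warn(f"fraction {frac}: fold {fold} skipped ({exc})")
                skipped = True
                break
            if task == "document":
                train_scores = est.predict_proba(sub)[:, 1]
                y_train = [a.doc_label for a in sub]
            else:
                pos = [a for a in sub if a.doc_label == 1]
                train_scores = est.predict_proba(pos)[:, 1]
                y_train = [s.sent_label for a in pos for s in a.sentences]
            tpred = (train_scores >= config.threshold).astype(int)
            vpred = (scores >= config.threshold).astype(int)
            train_f1s.append(_f1_from_predictions(y_train, tpred))
            val_f1s.append(_f1_from_predictions(y, vpred))
        if skipped:
            continue
        results.append((frac, float(np.mean(train_f1s)), float(np.mean(val_f1s))))
    return results
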
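"""Per-fold cross-validation with feature engineering inside each fold.

Feature selection is refit on every training fold, and test samples are
projected onto that fold's selection only after the fact, so no test
information reaches the selection (leakage-free by construction).
Classifiers are thin adapters over scikit-learn estimators with their
library defaults; decision tree (``dt``), random forest (``rf``) and
Gaussian naive Bayes (``nb``) are provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.tree import DecisionTreeClassifier

from .core import HFEResult, aggregate_taxa, run_hfe
from .io import AbundanceTable, LabelVector, normalize_relative
from .taxonomy import TaxonomyTree

__all__ = [
    "FoldPlan",
    "EvaluationReport",
    "make_folds",
    "evaluate",
    "feature_intersection",
    "make_classifier",
]

CLASSIFIERS = ("dt", "rf", "nb")


def make_classifier(name: str, seed: int = 0):
    """Instantiate a classifier adapter by short name with library defaults."""
    if name == "dt":
        return DecisionTreeClassifier(random_state=seed)
    if name == "rf":
        return RandomForestClassifier(random_state=seed)
    if name == "nb":
        return GaussianNB()
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


@dataclass(frozen=True)
class FoldPlan:
    """A reproducible stratified partition of the samples into k folds."""

    k: int
    assignments: dict[str, int]
    seed: int
    stratified: bool = True

    def fold_samples(self, fold: int) -> list[str]:
        return [s for s, f in self.assignments.items() if f == fold]

    def split(self, fold: int) -> tuple[list[str], list[str]]:
        """(train sample ids, test sample ids) for one fold."""
        train = [s for s, f in self.assignments.items() if f != fold]
        test = [s for s, f in self.assignments.items() if f == fold]
        return train, test


def make_folds(
    labels: LabelVector, k: int = 10, seed: int = 0, *, stratified: bool = True
) -> FoldPlan:
    """Partition the labelled samples into k stratified folds.

    Each class's members are shuffled and dealt round-robin across folds,
    preserving class proportions within one sample.  ``k == n`` gives
    leave-one-out; otherwise, stratification requires every class to have
    at least k members.
    """
    samples = list(labels.mapping)
    n = len(samples)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available samples")
    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}
    if stratified and k < n:
        counts = {c: sum(1 for v in labels.mapping.values() if v == c) for c in labels.classes}
        small = [c for c, m in counts.items() if m < k]
        if small:
            raise ValueError(
                f"classes {small} have fewer than k={k} members; use a smaller k"
            )
    pointer = 0
    for cls in labels.classes:
        members = [s for s in samples if labels.mapping[s] == cls]
        order = rng.permutation(len(members))
        for idx in order:
            assignments[members[idx]] = pointer % k
            pointer += 1
    assignments = {s: assignments[s] for s in samples}  # restore input order
    return FoldPlan(k=k, assignments=assignments, seed=seed, stratified=stratified)


@dataclass
class EvaluationReport:
    """Per-fold and aggregate classification metrics for one configuration."""

    classifier: str
    settings: dict
    fold_metrics: list[dict[str, float]]
    fold_feature_counts: list[int]
    fold_selections: list[tuple[str, ...]]
    classes: tuple[str, ...]

    _METRICS = ("auc", "precision", "recall", "f1")

    def per_fold(self, metric: str) -> np.ndarray:
        return np.array([m[metric] for m in self.fold_metrics])

    def mean(self, metric: str) -> float:
        return float(np.mean(self.per_fold(metric)))

    def std(self, metric: str) -> float:
        """Sample standard deviation (ddof=1) across folds."""
        return float(np.std(self.per_fold(metric), ddof=1))

    @property
    def intersection(self) -> tuple[str, ...]:
        return feature_intersection(self.fold_selections)

    def summary(self) -> dict:
        return {
            "classifier": self.classifier,
            "settings": self.settings,
            "folds": len(self.fold_metrics),
            "metrics": {
                m: {"mean": self.mean(m), "std": self.std(m)} for m in self._METRICS
            },
            "feature_counts": {
                "per_fold": self.fold_feature_counts,
                "mean": float(np.mean(self.fold_feature_counts)),
                "std": float(np.std(self.fold_feature_counts, ddof=1)),
            },
            "intersection_size": len(self.intersection),
            "intersection": list(self.intersection),
        }


def feature_intersection(selections: Sequence[Sequence[str]]) -> tuple[str, ...]:
    """Features common to every fold's selection (order of the first fold)."""
    if len(selections) < 2:
        raise ValueError("need selections from at least 2 folds")
    common = set(selections[0])
    for sel in selections[1:]:
        common &= set(sel)
    return tuple(f for f in selections[0] if f in common)


def _fold_metrics(
    clf, X_train, y_train, X_test, y_test, classes: tuple[str, ...]
) -> dict[str, float]:
    if X_train.shape[1] == 0:
        # empty selection: predict the training majority class with prior scores
        values, counts = np.unique(y_train, return_counts=True)
        majority = values[np.argmax(counts)]
        y_pred = np.full(len(y_test), majority, dtype=object)
        prior = np.array([np.mean(y_train == c) for c in classes])
        proba = np.tile(prior, (len(y_test), 1))
    else:
        clf.fit(X_train, y_train)
        proba_raw = clf.predict_proba(X_test)
        # align estimator class order with the report's class order
        order = [list(clf.classes_).index(c) for c in classes]
        proba = proba_raw[:, order]
        y_pred = np.asarray(classes, dtype=object)[np.argmax(proba, axis=1)]
    if len(classes) == 2:
        auc = roc_auc_score((y_test == classes[1]).astype(int), proba[:, 1])
    else:
        auc = roc_auc_score(
            y_test, proba, multi_class="ovr", average="macro", labels=list(classes)
        )
    common = dict(average="weighted", labels=list(classes), zero_division=0)
    return {
        "auc": float(auc),
        "precision": float(precision_score(y_test, y_pred, **common)),
        "recall": float(recall_score(y_test, y_pred, **common)),
        "f1": float(f1_score(y_test, y_pred, **common)),
    }


def evaluate(
    table: AbundanceTable,
    labels: LabelVector,
    tree: TaxonomyTree,
    classifier: str = "rf",
    plan: FoldPlan | None = None,
    theta: float = 0.7,
    *,
    baseline: bool = False,
    phase3_average: str = "per-path",
) -> EvaluationReport:
    """Cross-validated evaluation of engineered (or baseline OTU) features.

    For every fold, feature engineering runs on the training partition
    only; the training and test samples are then projected onto that
    fold's selection (taxon aggregates are per-sample sums, so test-side
    columns never see training statistics and vice versa).  In
    ``baseline`` mode selection is disabled and the raw OTU features are
    used.  Multi-class AUC is macro-averaged one-vs-rest;
    precision/recall/F are weighted averages.
    """
    if plan is None:
        plan = make_folds(labels, 10, 0)
    table = normalize_relative(table)
    extended_all = aggregate_taxa(table, tree)
    classes = labels.classes
    fold_metrics: list[dict[str, float]] = []
    counts: list[int] = []
    selections: list[tuple[str, ...]] = []
    for fold in range(plan.k):
        train_ids, test_ids = plan.split(fold)
        train_ext = extended_all.subset_samples(train_ids)
        if baseline:
            selected: tuple[str, ...] = tuple(table.feature_ids)
        else:
            result: HFEResult = run_hfe(
                table.subset_samples(train_ids),
                labels.subset(train_ids),
                tree,
                theta,
                phase3_average=phase3_average,
                _extended=train_ext,
            )
            selected = result.selected
        X_train = train_ext.data[list(selected)].to_numpy(dtype=float)
        X_test = (
            extended_all.subset_samples(test_ids).data[list(selected)].to_numpy(dtype=float)
        )
        y_train = labels.for_samples(train_ids)
        y_test = labels.for_samples(test_ids)
        clf = make_classifier(classifier, seed=(plan.seed * 1009 + fold) % (2**31))
        try:
            fold_metrics.append(
                _fold_metrics(clf, X_train, y_train, X_test, y_test, classes)
            )
        except Exception as exc:  # surface classifier contract violations with context
            raise RuntimeError(f"classifier {classifier!r} failed on fold {fold}") from exc
        counts.append(len(selected))
        selections.append(selected)
    return EvaluationReport(
        classifier=classifier,
        settings={
            "theta": theta,
            "baseline": baseline,
            "folds": plan.k,
            "seed": plan.seed,
            "phase3_average": phase3_average,
        },
        fold_metrics=fold_metrics,
        fold_feature_counts=counts,
        fold_selections=selections,
        classes=classes,
    )
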
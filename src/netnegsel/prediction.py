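"""Protein-function prediction from network features.

Each GO term is a binary classification problem: positives are the term's
old-release annotations, everything else is treated as negative.  Two
families are used so results are not biased toward one inductive principle:
a linear SVM with class weights (1 for negatives, (n - p)/p for the p
positives, counterbalancing class imbalance) and a random forest.  The
regularization constant C (SVM) and mtry, the number of features tried per
split (RF), are tuned by an inner 3-fold CV nested in a 3-fold outer CV;
F1 drives both tuning and evaluation because positives are rare.

A leave-one-feature-out ablation re-runs the experiment dropping each
feature in turn, quantifying the marginal contribution of each feature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import LinearSVC

from .annotations import AnnotationRelease
from .features import TermFeatureMatrix
from .relevance import DegenerateTermError, _f1, stratified_folds

logger = logging.getLogger(__name__)

MODEL_FAMILIES = ("linear_svm", "random_forest")
DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class ClassifierSpec:
    """Model family plus hyperparameter grid and seeding."""

    family: str = "linear_svm"
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    mtry_grid: tuple[int, ...] | None = None  # None: derived from sqrt(d)
    n_estimators: int = 500
    #: leaf-size regularization for the forest; fully grown trees (1) fit
    #: hardest, larger leaves give graded class-frequency estimates, which
    #: matters when forest probabilities are used to *rank* proteins
    rf_min_samples_leaf: int = 1
    class_weighted: bool = True  # applies to the SVM only
    seed: int = 0

    def __post_init__(self):
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.family == "linear_svm" and not self.c_grid:
            raise ValueError("empty C grid")

    def grid(self, n_features: int) -> tuple:
        if self.family == "linear_svm":
            return self.c_grid
        if self.mtry_grid is not None:
            return tuple(int(np.clip(m, 1, n_features)) for m in self.mtry_grid)
        base = math.isqrt(n_features)
        base = base if base * base == n_features else base + 1
        cand = [max(1, base // 2), base, 2 * base, max(1, n_features // 2)]
        return tuple(sorted({int(np.clip(m, 1, n_features)) for m in cand}))


@dataclass
class PredictionMetrics:
    """Per-fold and averaged F1 / precision / recall for one experiment."""

    term: str
    representation: str
    family: str
    f1: list[float] = field(default_factory=list)
    precision: list[float] = field(default_factory=list)
    recall: list[float] = field(default_factory=list)

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.f1))

    @property
    def mean_precision(self) -> float:
        return float(np.mean(self.precision))

    @property
    def mean_recall(self) -> float:
        return float(np.mean(self.recall))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.term,
                "representation": self.representation,
                "model": self.family,
                "fold": range(len(self.f1)),
                "F1": self.f1,
                "precision": self.precision,
                "recall": self.recall,
            }
        )


def class_weight_for_term(older: AnnotationRelease, term: str) -> tuple[float, float]:
    """SVM class weights (negative, positive) = (1, (n - p)/p)."""
    p = int(older.term_column(term).sum())
    n = older.n_proteins
    if p == 0:
        raise DegenerateTermError(f"term {term}: no positives, class weight undefined")
    if p == n:
        raise DegenerateTermError(f"term {term}: no negatives")
    return 1.0, (n - p) / p


def make_estimator(spec: ClassifierSpec, param, pos_weight: float | None = None):
    """Instantiate the classifier for one grid point."""
    if spec.family == "linear_svm":
        weights = {0: 1.0, 1: pos_weight} if (spec.class_weighted and pos_weight) else None
        return LinearSVC(
            C=param, class_weight=weights, max_iter=20000, random_state=spec.seed % (2**31)
        )
    return RandomForestClassifier(
        n_estimators=spec.n_estimators,
        max_features=param,
        min_samples_leaf=spec.rf_min_samples_leaf,
        random_state=spec.seed % (2**31),
        n_jobs=1,
    )


def _precision_recall_f1(y_true, y_pred) -> tuple[float, float, float]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1


def tune_hyperparameter(
    x: np.ndarray,
    labels: np.ndarray,
    spec: ClassifierSpec,
    pos_weight: float | None = None,
    folds: int = 3,
):
    """Grid point maximizing mean F1 over a stratified CV (ties: first)."""
    grid = spec.grid(x.shape[1])
    splits = stratified_folds(labels, folds, spec.seed + 97)
    best_param, best_score = grid[0], -1.0
    for param in grid:
        vals = []
        for tr, te in splits:
            clf = make_estimator(spec, param, pos_weight)
            clf.fit(x[tr], labels[tr])
            vals.append(_f1(labels[te], clf.predict(x[te])))
        mean = float(np.mean(vals))
        if mean > best_score + 1e-12:
            best_param, best_score = param, mean
    return best_param


def nested_cv_evaluate(
    x: np.ndarray,
    labels: np.ndarray,
    spec: ClassifierSpec,
    term: str = "",
    representation: str = "",
    pos_weight: float | None = None,
) -> PredictionMetrics:
    """3-fold outer CV with an inner 3-fold CV selecting the hyperparameter.

    ``pos_weight`` defaults to (n - p)/p computed from ``labels`` when the
    spec requests a class-weighted SVM.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise DegenerateTermError(f"term {term}: single-class labels")
    if pos_weight is None and spec.family == "linear_svm" and spec.class_weighted:
        p = int(labels.sum())
        pos_weight = (len(labels) - p) / p
    metrics = PredictionMetrics(term=term, representation=representation, family=spec.family)
    outer = stratified_folds(labels, 3, spec.seed)
    for tr, te in outer:
        inner_spec = replace(spec, seed=spec.seed + 131)
        param = tune_hyperparameter(x[tr], labels[tr], inner_spec, pos_weight)
        clf = make_estimator(spec, param, pos_weight)
        clf.fit(x[tr], labels[tr])
        prec, rec, f1 = _precision_recall_f1(labels[te], clf.predict(x[te]))
        metrics.precision.append(prec)
        metrics.recall.append(rec)
        metrics.f1.append(f1)
    return metrics


def ablation_study(
    matrix: TermFeatureMatrix,
    labels: np.ndarray,
    spec: ClassifierSpec,
    pool: tuple[str, ...] = tuple(f"f{i}" for i in range(1, 15)),
) -> list[PredictionMetrics]:
    """Leave-one-feature-out over ``pool`` (3Prop features are not ablated).

    Each record is a nested-CV evaluation on the pool minus one feature,
    tagged ``ablation:-fk``.
    """
    pool = tuple(pool)
    missing = set(pool) - set(matrix.columns)
    if missing:
        raise KeyError(f"pool features absent from matrix: {sorted(missing)}")
    out = []
    for removed in pool:
        keep = [f for f in pool if f != removed]
        x = matrix.subset(keep)
        out.append(
            nested_cv_evaluate(
                x, labels, spec, term=matrix.term, representation=f"ablation:-{removed}"
            )
        )
    return out


def metrics_to_frame(records: list[PredictionMetrics]) -> pd.DataFrame:
    return pd.concat([m.to_frame() for m in records], ignore_index=True)
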
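"""Budgeted selection of reliable negative examples.

For each term a classifier is trained on the older release (positives vs
all non-positives) and the non-positives are ranked by their positive-class
score — the decision-function value for the SVM, the positive-class
probability for the random forest.  The bottom of the ranking is declared
"reliably negative" up to a budget of x% of the proteins.  Quality is the
number of *false negatives*: selected proteins that in fact acquired the
annotation in the newer release (members of C_np), averaged across terms.

Seven feature configurations are compared: the 3Prop walk features alone,
the 14 network features (full, top-5 by selection frequency, above-mean
frequency), and the same three variants of the full 17-feature set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .annotations import TemporalHoldout
from .features import FEATURE_NAMES, THREE_PROP, FeatureBuilder
from .prediction import ClassifierSpec, make_estimator, tune_hyperparameter
from .relevance import DegenerateTermError, FeatureFrequencyTable, subset_by_rule

logger = logging.getLogger(__name__)

F1_14 = tuple(f"f{i}" for i in range(1, 15))
DEFAULT_BUDGET_PERCENTAGES = (1, 5, 10, 15, 20, 25, 30)


@dataclass(frozen=True)
class FeatureConfiguration:
    """Named, resolved feature-column set."""

    name: str
    columns: tuple[str, ...]

    def __post_init__(self):
        if not self.columns:
            raise ValueError(f"configuration {self.name!r} resolved to an empty feature set")
        unknown = set(self.columns) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown features {sorted(unknown)}")


def standard_configurations(
    freq_f14: FeatureFrequencyTable,
    freq_f17: FeatureFrequencyTable,
    q: int = 5,
) -> list[FeatureConfiguration]:
    """The seven feature configurations of the negative-selection experiment."""
    return [
        FeatureConfiguration("f15-f17", THREE_PROP),
        FeatureConfiguration("f1-f14-topq", tuple(subset_by_rule(freq_f14, "top_q", q))),
        FeatureConfiguration("f1-f14-mean", tuple(subset_by_rule(freq_f14, "mean"))),
        FeatureConfiguration("f1-f14", F1_14),
        FeatureConfiguration("f1-f17-topq", tuple(subset_by_rule(freq_f17, "top_q", q))),
        FeatureConfiguration("f1-f17-mean", tuple(subset_by_rule(freq_f17, "mean"))),
        FeatureConfiguration("f1-f17", FEATURE_NAMES),
    ]


@dataclass
class BudgetGrid:
    """Budgets as percentages of the total protein count."""

    percentages: tuple[int, ...] = DEFAULT_BUDGET_PERCENTAGES

    def budgets(self, n_total: int) -> dict[int, int]:
        out = {}
        for x in self.percentages:
            b = math.floor(x * n_total / 100)
            if b < 1:
                logger.info("budget %d%% of %d rounds to 0; raised to 1", x, n_total)
                b = 1
            out[x] = b
        return out


@dataclass
class NegativeSelectionReport:
    """Per-term and aggregated false-negative counts."""

    frame: pd.DataFrame  # columns: term, configuration, model, budget_pct, budget, FN, baseline_FN
    n_terms: int
    skipped_terms: list[str]

    def summary(self) -> pd.DataFrame:
        g = (
            self.frame.groupby(["configuration", "model", "budget_pct"], sort=True)
            .agg(mean_FN=("FN", "mean"), baseline_FN=("baseline_FN", "mean"), n_terms=("term", "nunique"))
            .reset_index()
        )
        return g

    def to_tsv(self, path) -> None:
        self.summary().to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------


def rank_candidates(
    x: np.ndarray,
    labels: np.ndarray,
    node_labels: list[str],
    spec: ClassifierSpec,
    param=None,
    pos_weight: float | None = None,
) -> np.ndarray:
    """Train on all proteins; return candidate indices by ascending score.

    Candidates are the old-release non-positives (``labels == 0``).  Score
    ties are broken by protein identifier so rankings are deterministic.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise DegenerateTermError("degenerate labels: cannot train a ranking model")
    if pos_weight is None and spec.family == "linear_svm" and spec.class_weighted:
        p = int(labels.sum())
        pos_weight = (len(labels) - p) / p
    if param is None:
        param = tune_hyperparameter(x, labels, spec, pos_weight)
    clf = make_estimator(spec, param, pos_weight)
    candidates = np.flatnonzero(labels == 0)
    if spec.family == "linear_svm":
        clf.fit(x, labels)
        scores = clf.decision_function(x[candidates])
    else:
        # candidates are part of the training set: in-sample forest
        # probabilities just memorize the labels, so score them out-of-bag
        clf.set_params(oob_score=True)
        clf.fit(x, labels)
        pos_col = list(clf.classes_).index(1)
        oob = clf.oob_decision_function_[:, pos_col]
        nan = np.isnan(oob)
        if nan.any():  # samples never left out of a bootstrap draw
            oob[nan] = clf.predict_proba(x[nan])[:, pos_col]
        scores = oob[candidates]
    order = sorted(range(len(candidates)), key=lambda i: (scores[i], node_labels[candidates[i]]))
    return candidates[order]


def select_at_budget(
    ranking: np.ndarray, grid: BudgetGrid, n_total: int
) -> dict[int, np.ndarray]:
    """Prefixes of the ranking at each budget (capped at the pool size)."""
    if len(ranking) == 0:
        raise ValueError("empty candidate ranking")
    out = {}
    for x, b in grid.budgets(n_total).items():
        if b > len(ranking):
            logger.info("budget %d capped at candidate-pool size %d", b, len(ranking))
            b = len(ranking)
        out[x] = ranking[:b]
    return out


def count_false_negatives(selected, cnp_set) -> int:
    """Number of selected proteins that are in C_np."""
    return len(set(np.asarray(selected).tolist()) & set(np.asarray(cnp_set).tolist()))


def evaluate_configurations(
    builder: FeatureBuilder,
    holdout: TemporalHoldout,
    terms: list[str],
    configurations: list[FeatureConfiguration],
    specs: list[ClassifierSpec],
    grid: BudgetGrid = BudgetGrid(),
) -> NegativeSelectionReport:
    """Full cross of configuration x model x budget, averaged across terms.

    Each cell carries the random-selection expectation
    ``budget * |C_np ∩ candidates| / |candidates|`` as a baseline.
    """
    rows = []
    skipped = []
    n_total = builder.net.n_nodes
    for term in terms:
        j = holdout.older.terms.index(term)
        labels = holdout.older.y[:, j].astype(int)
        cnp = holdout.cnp[term]
        n_cand = int((labels == 0).sum())
        if labels.sum() == 0 or n_cand == 0:
            skipped.append(term)
            continue
        matrix = builder.term_matrix(term, features=FEATURE_NAMES)
        for config in configurations:
            x = matrix.subset(list(config.columns))
            for spec in specs:
                try:
                    ranking = rank_candidates(x, labels, builder.net.node_labels, spec)
                except DegenerateTermError as exc:
                    logger.info("term %s / %s: %s", term, spec.family, exc)
                    skipped.append(term)
                    continue
                selections = select_at_budget(ranking, grid, n_total)
                frac_cnp = len(set(cnp.tolist()) & set(ranking.tolist())) / len(ranking)
                for x_pct, sel in selections.items():
                    rows.append(
                        {
                            "term": term,
                            "configuration": config.name,
                            "model": spec.family,
                            "budget_pct": x_pct,
                            "budget": len(sel),
                            "FN": count_false_negatives(sel, cnp),
                            "baseline_FN": len(sel) * frac_cnp,
                        }
                    )
    frame = pd.DataFrame(rows)
    return NegativeSelectionReport(
        frame=frame,
        n_terms=frame["term"].nunique() if len(frame) else 0,
        skipped_terms=sorted(set(skipped)),
    )
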
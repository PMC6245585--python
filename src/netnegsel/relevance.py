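"""Wrapper feature-relevance analysis for the unreliable-negative class.

For each GO term the old-release non-positives form a binary classification
problem: label 1 if the protein is in C_np (it acquired the annotation
during the holdout, so it was an unreliable negative), 0 if it stayed
unannotated.  A CART decision tree wrapped in sequential floating forward
selection (SFFS) searches for the feature subset maximizing cross-validated
F1 — F1 because C_np positives are scarce.

The protocol is a triple loop: instances are partitioned into three
non-overlapping label-stratified subsets; within each subset a 3-fold outer
CV is run; on every outer-training portion SFFS (with an inner 3-fold CV as
its criterion) selects a subset, which is validated on the outer test fold.
Each selection event increments per-feature counters; features are finally
ranked by the proportion of events in which they were selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .annotations import TemporalHoldout
from .features import FEATURE_NAMES, FeatureBuilder, TermFeatureMatrix

logger = logging.getLogger(__name__)

_IMPROVE_TOL = 1e-12


class DegenerateTermError(ValueError):
    """Term cannot support the experiment (degenerate class structure)."""


@dataclass
class RelevanceInstanceSet:
    """Old-release non-positives of one term, labelled by C_np membership."""

    term: str
    x: np.ndarray  # n_instances x n_features
    labels: np.ndarray  # 1 iff instance in C_np
    feature_names: list[str]
    protein_indices: np.ndarray  # node indices of the instances


@dataclass
class SffsConfig:
    """Configuration of the CART + SFFS wrapper search."""

    inner_folds: int = 3
    max_subset_size: int | None = None
    min_samples_leaf: int = 2
    seed: int = 0


@dataclass
class FeatureFrequencyTable:
    """Per-feature selection counts over all (term, subset, fold) runs."""

    pool: tuple[str, ...]
    counts: dict[str, int]
    runs: int
    outer_f1: list[float] = field(default_factory=list)
    n_terms: int = 0

    @property
    def proportions(self) -> dict[str, float]:
        if self.runs == 0:
            return {f: 0.0 for f in self.pool}
        return {f: self.counts.get(f, 0) / self.runs for f in self.pool}

    @property
    def mean_proportion(self) -> float:
        props = self.proportions
        return float(np.mean([props[f] for f in self.pool]))

    def to_frame(self) -> pd.DataFrame:
        props = self.proportions
        mean = self.mean_proportion
        return pd.DataFrame(
            {
                "feature": list(self.pool),
                "count": [self.counts.get(f, 0) for f in self.pool],
                "runs": self.runs,
                "proportion": [props[f] for f in self.pool],
                "above_mean": [props[f] > mean for f in self.pool],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------


def build_instances(
    holdout: TemporalHoldout, term_matrix: TermFeatureMatrix, term: str
) -> RelevanceInstanceSet:
    """Instances are the term's old-release non-positives; label = in C_np."""
    j = holdout.older.terms.index(term)
    non_pos = np.flatnonzero(holdout.older.y[:, j] == 0)
    cnp = set(holdout.cnp[term].tolist())
    labels = np.array([1 if i in cnp else 0 for i in non_pos], dtype=int)
    n_pos, n_neg = int(labels.sum()), int((1 - labels).sum())
    if n_pos < 2 or n_neg < 2:
        raise DegenerateTermError(
            f"term {term}: {n_pos} C_np / {n_neg} stable negatives — too few for CV"
        )
    return RelevanceInstanceSet(
        term=term,
        x=term_matrix.values[non_pos],
        labels=labels,
        feature_names=list(term_matrix.columns),
        protein_indices=non_pos,
    )


def _f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Label-stratified K folds; K shrinks to the minority-class count.

    Raises :class:`DegenerateTermError` if even two folds are impossible.
    """
    min_class = int(np.bincount(labels, minlength=2).min())
    k_eff = min(k, min_class)
    if k_eff < 2:
        raise DegenerateTermError("minority class too small for a stratified split")
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed % (2**31))
    return list(skf.split(np.zeros(len(labels)), labels))


def sffs_select(
    instances: RelevanceInstanceSet, cfg: SffsConfig
) -> tuple[list[str], float]:
    """Sequential floating forward selection with a CART inner-CV criterion.

    Features are greedily added while the inner cross-validated F1 strictly
    improves; after each addition, features are conditionally removed while
    removal strictly improves the criterion.  The empty set scores 0, so the
    first step always picks the best single feature when it achieves any
    positive F1.  Ties are broken by canonical feature order.  Deterministic
    given ``cfg.seed``.
    """
    if instances.x.shape[1] == 0:
        raise ValueError("empty candidate feature pool")
    x, ylab = instances.x, instances.labels
    names = instances.feature_names
    folds = stratified_folds(ylab, cfg.inner_folds, cfg.seed)
    cache: dict[frozenset, float] = {}

    def score(cols: tuple[int, ...]) -> float:
        key = frozenset(cols)
        if key in cache:
            return cache[key]
        xs = x[:, list(cols)]
        vals = []
        for tr, te in folds:
            clf = DecisionTreeClassifier(
                random_state=cfg.seed % (2**31), min_samples_leaf=cfg.min_samples_leaf
            )
            clf.fit(xs[tr], ylab[tr])
            vals.append(_f1(ylab[te], clf.predict(xs[te])))
        out = float(np.mean(vals))
        cache[key] = out
        return out

    max_size = cfg.max_subset_size or len(names)
    selected: list[int] = []
    best = 0.0
    while len(selected) < max_size:
        candidates = [c for c in range(len(names)) if c not in selected]
        if not candidates:
            break
        scores = [(score(tuple(selected + [c])), -c) for c in candidates]
        j_add, neg_c = max(scores)
        if j_add <= best + _IMPROVE_TOL:
            break
        selected.append(-neg_c)
        best = j_add
        # floating removal: drop features while it strictly improves
        while len(selected) > 2:
            rm_scores = [
                (score(tuple(s for s in selected if s != r)), -r) for r in selected
            ]
            j_rm, neg_r = max(rm_scores)
            if j_rm <= best + _IMPROVE_TOL:
                break
            selected.remove(-neg_r)
            best = j_rm
    return [names[c] for c in sorted(selected)], best


def triple_loop_relevance(
    builder: FeatureBuilder,
    holdout: TemporalHoldout,
    terms: list[str],
    pool: tuple[str, ...],
    cfg: SffsConfig,
) -> FeatureFrequencyTable:
    """Run the three-subset x outer-3-fold x inner-3-fold relevance protocol.

    Returns the pooled selection-frequency table across all terms.
    """
    pool = tuple(f for f in FEATURE_NAMES if f in pool)
    counts: dict[str, int] = {f: 0 for f in pool}
    runs = 0
    outer_f1: list[float] = []
    n_used = 0
    for t_idx, term in enumerate(terms):
        term_seed = (cfg.seed * 100003 + t_idx * 7919) % (2**31)
        matrix = builder.term_matrix(term, features=pool)
        try:
            inst = build_instances(holdout, matrix, term)
            subset_folds = stratified_folds(inst.labels, 3, term_seed)
        except DegenerateTermError as exc:
            logger.info("skipping term: %s", exc)
            continue
        n_used += 1
        for s_idx, (_, subset_idx) in enumerate(subset_folds):
            sub_x, sub_y = inst.x[subset_idx], inst.labels[subset_idx]
            try:
                outer = stratified_folds(sub_y, 3, term_seed + 17 * s_idx + 1)
            except DegenerateTermError:
                continue
            for f_idx, (tr, te) in enumerate(outer):
                sub_inst = RelevanceInstanceSet(
                    term=term,
                    x=sub_x[tr],
                    labels=sub_y[tr],
                    feature_names=inst.feature_names,
                    protein_indices=inst.protein_indices[subset_idx][tr],
                )
                run_cfg = SffsConfig(
                    inner_folds=cfg.inner_folds,
                    max_subset_size=cfg.max_subset_size,
                    min_samples_leaf=cfg.min_samples_leaf,
                    seed=term_seed + 1009 * s_idx + 31 * f_idx,
                )
                try:
                    selected, _ = sffs_select(sub_inst, run_cfg)
                except DegenerateTermError:
                    continue
                runs += 1
                for f in selected:
                    counts[f] += 1
                # validate the selected subset on the outer test fold
                if selected:
                    cols = [inst.feature_names.index(f) for f in selected]
                    clf = DecisionTreeClassifier(
                        random_state=run_cfg.seed % (2**31),
                        min_samples_leaf=cfg.min_samples_leaf,
                    )
                    clf.fit(sub_x[tr][:, cols], sub_y[tr])
                    outer_f1.append(_f1(sub_y[te], clf.predict(sub_x[te][:, cols])))
                else:
                    outer_f1.append(0.0)
    return FeatureFrequencyTable(
        pool=pool, counts=counts, runs=runs, outer_f1=outer_f1, n_terms=n_used
    )


def subset_by_rule(table: FeatureFrequencyTable, rule: str, q: int = 5) -> list[str]:
    """Resolve a frequency table into a feature subset.

    ``top_q`` takes the ``q`` highest-proportion features (ties broken by
    canonical feature order); ``mean`` takes the features whose proportion
    strictly exceeds the mean proportion.
    """
    props = table.proportions
    if rule == "top_q":
        if q > len(table.pool):
            raise ValueError(f"q={q} exceeds pool size {len(table.pool)}")
        order = sorted(table.pool, key=lambda f: (-props[f], FEATURE_NAMES.index(f)))
        return sorted(order[:q], key=FEATURE_NAMES.index)
    if rule == "mean":
        mean = table.mean_proportion
        out = [f for f in table.pool if props[f] > mean]
        if not out:
            logger.warning("mean rule selected no features (all proportions equal)")
        return out
    raise ValueError(f"unknown subset rule {rule!r}")
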
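"""Temporal-holdout annotation handling.

Two releases of a protein-to-GO-term annotation table are aligned to the
network's protein universe.  The older release ``Y`` trains models; the
newer release ``Y_bar`` validates them.  For each term ``k`` the class

    C_np(k) = { i : Y_ik = 0 and Y_bar_ik = 1 }

collects the proteins that were unannotated at training time but received
the annotation during the holdout period — exactly the proteins that would
have been *false* negatives had they been picked as negative examples.

Annotation files are flat three-column TSVs (protein, term, evidence code);
no ontology reasoning (ancestor propagation, OBO parsing) is performed —
inputs are treated as already propagated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default experimental evidence-code whitelist (GO evidence ontology)
EXPERIMENTAL_EVIDENCE = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})


class AnnotationAlignmentError(ValueError):
    """Protein universes of annotations and network cannot be reconciled."""


@dataclass
class AnnotationRelease:
    """Binary protein x term annotation matrix for one release."""

    y: np.ndarray  # n x m, uint8
    terms: list[str]
    node_labels: list[str]
    tag: str = ""

    @property
    def n_proteins(self) -> int:
        return self.y.shape[0]

    @property
    def n_terms(self) -> int:
        return self.y.shape[1]

    def term_column(self, term: str) -> np.ndarray:
        return self.y[:, self.terms.index(term)]

    def positives(self, term: str) -> np.ndarray:
        return np.flatnonzero(self.term_column(term) == 1)


@dataclass
class TermFilter:
    """Term-selection rule.

    ``min_cnp`` keeps terms with at least ``min_cnp_size`` proteins in
    C_np (used for the negative-relevance experiment); ``annotation_range``
    keeps terms whose newer-release annotation count lies in ``range``
    inclusive (used for function prediction, excluding overly generic
    terms).
    """

    rule: str = "min_cnp"  # or "annotation_range"
    min_cnp_size: int = 20
    range: tuple[int, int] = (20, 200)

    def __post_init__(self):
        if self.rule not in ("min_cnp", "annotation_range"):
            raise ValueError(f"unknown term filter rule {self.rule!r}")
        if self.min_cnp_size <= 0 or self.range[0] > self.range[1] or self.range[0] <= 0:
            raise ValueError("term filter parameters must be positive and ordered")


@dataclass
class TemporalHoldout:
    """Paired releases plus the per-term C_np index sets."""

    older: AnnotationRelease
    newer: AnnotationRelease
    cnp: dict[str, np.ndarray] = field(default_factory=dict)
    revocations: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def terms(self) -> list[str]:
        return self.older.terms

    @property
    def node_labels(self) -> list[str]:
        return self.older.node_labels


def load_annotations(
    path,
    node_labels: list[str],
    experimental_only: bool = True,
    evidence_whitelist: frozenset[str] = EXPERIMENTAL_EVIDENCE,
    tag: str = "",
    column_indices: tuple[int, int, int] = (0, 1, 2),
) -> AnnotationRelease:
    """Read a protein/term/evidence TSV into a binary matrix.

    ``column_indices`` maps the (protein, term, evidence) fields to file
    columns — the default fits the flat 3-column format; ``(1, 4, 6)``
    reads GAF 2.x.  Comment lines starting with ``!`` are skipped.  Rows
    for proteins absent from ``node_labels`` are dropped (a count is
    logged); with ``experimental_only`` rows whose evidence code is outside
    the whitelist are dropped.  Duplicate rows are idempotent.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="!")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    if len(df):
        if max(column_indices) >= df.shape[1]:
            raise AnnotationAlignmentError(
                f"column mapping {column_indices} exceeds the file's "
                f"{df.shape[1]} columns"
            )
        df = df.iloc[:, list(column_indices)]
        df.columns = ["protein", "term", "evidence"]
    else:
        df = pd.DataFrame(columns=["protein", "term", "evidence"], dtype=str)
    if len(df) and experimental_only:
        df = df[df["evidence"].isin(evidence_whitelist)]
    index = {lab: i for i, lab in enumerate(node_labels)}
    known = df["protein"].isin(index) if len(df) else pd.Series(dtype=bool)
    n_unknown = int((~known).sum()) if len(df) else 0
    if len(df):
        if not known.any() and len(df) > 0:
            raise AnnotationAlignmentError(
                "no overlap between annotation proteins and network nodes"
            )
        if n_unknown:
            logger.info("%s: dropped %d rows for proteins not in the network", path, n_unknown)
        df = df[known]
    terms = sorted(df["term"].unique()) if len(df) else []
    tindex = {t: j for j, t in enumerate(terms)}
    y = np.zeros((len(node_labels), len(terms)), dtype=np.uint8)
    for p, t in zip(df["protein"], df["term"]):
        y[index[p], tindex[t]] = 1
    return AnnotationRelease(y=y, terms=terms, node_labels=list(node_labels), tag=tag)


def build_holdout(older: AnnotationRelease, newer: AnnotationRelease) -> TemporalHoldout:
    """Pair two releases and compute C_np per shared term.

    Term universes are intersected (terms present in only one release are
    dropped with a log line).  Annotations present in the older but not the
    newer release (revocations) are recorded; the protein keeps its
    old-release positive status, so it never enters a negative pool.
    """
    if older.node_labels != newer.node_labels:
        raise AnnotationAlignmentError("releases are aligned to different protein universes")
    shared = sorted(set(older.terms) & set(newer.terms))
    dropped = (set(older.terms) | set(newer.terms)) - set(shared)
    if dropped:
        logger.info("dropping %d terms absent from one release", len(dropped))

    def _restrict(rel: AnnotationRelease) -> AnnotationRelease:
        cols = [rel.terms.index(t) for t in shared]
        return AnnotationRelease(
            y=rel.y[:, cols].copy(), terms=shared, node_labels=rel.node_labels, tag=rel.tag
        )

    o, nw = _restrict(older), _restrict(newer)
    cnp, revocations = {}, {}
    for j, t in enumerate(shared):
        cnp[t] = np.flatnonzero((o.y[:, j] == 0) & (nw.y[:, j] == 1))
        rev = np.flatnonzero((o.y[:, j] == 1) & (nw.y[:, j] == 0))
        revocations[t] = rev
        if len(rev):
            logger.info("term %s: %d revoked annotations kept as old-release positives", t, len(rev))
    return TemporalHoldout(older=o, newer=nw, cnp=cnp, revocations=revocations)


def filter_terms(holdout: TemporalHoldout, flt: TermFilter) -> list[str]:
    """Return the terms passing the filter, in term order."""
    out = []
    for j, t in enumerate(holdout.terms):
        if flt.rule == "min_cnp":
            if len(holdout.cnp[t]) >= flt.min_cnp_size:
                out.append(t)
        else:
            count = int(holdout.newer.y[:, j].sum())
            if flt.range[0] <= count <= flt.range[1]:
                out.append(t)
    if not out:
        logger.warning("no terms pass filter %s", flt)
    return out
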
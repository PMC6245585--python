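"""Per-protein network features for negative-example selection.

Seventeen features are computed for every protein ``i`` of a normalized
weighted network, relative to a GO term ``k`` where term-aware:

term-unaware (f1-f9)
    f1  neighborhood mean        mean of W_ij over neighbors
    f2  neighborhood variance    sample variance of the same weights
    f3  weighted degree          sum of W_ij over neighbors
    f4  weighted clustering      weight of closed triples / weight of all
                                 triples centered at i (reduces to the local
                                 clustering coefficient for equal weights)
    f5  number of annotations    old-release annotation count, current term
                                 excluded (multifunctionality proxy)
    f6  closeness                1 / sum of distances within the component
    f7  Lin's index              closeness times squared component size
    f8  harmonic centrality      sum of reciprocal distances
    f9  betweenness              sum over pairs of the fraction of shortest
                                 paths through i

term-aware (f10-f17)
    f10 positive neighborhood    sum of W_ij over positively annotated
                                 neighbors (a guilt-by-association score)
    f11 mean of positive nbhd    f10 divided by the positive-neighbor count
    f12-f14                      positive variants of f6-f8 (distance sums
                                 restricted to positives in the component)
    f15-f17                      3Prop random-walk features: probability
                                 that a 1-, 2-, 3-step walk started at a
                                 random positive ends at i

Distances use the entries of ``W`` as edge costs by default (configurable).
Each feature column is finally normalized to sum to one across proteins so
ranges are comparable between features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import AnnotationRelease, TemporalHoldout
from .network import (
    ComponentIndex,
    ShortestPathCache,
    WeightedNetwork,
    connected_components,
    shortest_paths,
)

logger = logging.getLogger(__name__)

FEATURE_NAMES = tuple(f"f{i}" for i in range(1, 18))
TERM_UNAWARE = tuple(f"f{i}" for i in range(1, 10))
TERM_AWARE = tuple(f"f{i}" for i in range(10, 18))
LOCAL_FEATURES = ("f1", "f2", "f3", "f4")
GEOMETRIC_FEATURES = ("f6", "f7", "f8", "f9")
POSITIVE_FEATURES = ("f10", "f11", "f12", "f13", "f14")
THREE_PROP = ("f15", "f16", "f17")


@dataclass
class TermContext:
    """Positive structure of one term, taken from the *older* release."""

    term: str
    positives: np.ndarray  # node indices with Y_ik = 1
    is_positive: np.ndarray  # boolean mask, length n

    @classmethod
    def from_release(cls, release: AnnotationRelease, term: str) -> "TermContext":
        pos = release.positives(term)
        mask = np.zeros(release.n_proteins, dtype=bool)
        mask[pos] = True
        return cls(term=term, positives=pos, is_positive=mask)


@dataclass
class RandomWalkOperator:
    """Row-stochastic transition operator and positive start distribution."""

    p: np.ndarray  # row-stochastic transition matrix
    y: np.ndarray  # uniform distribution over positives

    def propagate(self, steps: int) -> np.ndarray:
        """End-point distribution of a ``steps``-long walk from ``y``.

        Applied as repeated operator-vector products; powers of ``p`` are
        never materialized.
        """
        v = self.y
        for _ in range(steps):
            v = self.p @ v
        return v


@dataclass
class TermFeatureMatrix:
    """n x |features| matrix of per-protein features for one term."""

    values: np.ndarray
    columns: list[str]
    term: str
    node_labels: list[str]
    normalized: bool = False

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.columns.index(name)]

    def subset(self, columns: list[str]) -> np.ndarray:
        idx = [self.columns.index(c) for c in columns]
        return self.values[:, idx]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns)
        df.insert(0, "protein_id", self.node_labels)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# raw feature computations


def local_features(net: WeightedNetwork) -> np.ndarray:
    """Columns f1-f4 (neighborhood mean/variance, weighted degree/clustering)."""
    n = net.n_nodes
    out = np.zeros((n, 4))
    w = net.w
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        wv = w[i, nbrs]
        k = len(nbrs)
        out[i, 0] = wv.mean()
        out[i, 1] = wv.var(ddof=1) if k > 1 else 0.0  # single neighbor: variance undefined, use 0
        out[i, 2] = wv.sum()
        if k >= 2:
            sub = w[np.ix_(nbrs, nbrs)]
            closed = sub > 0
            pair_w = wv[:, None] + wv[None, :]
            num = ((pair_w * closed).sum() + sub.sum()) / 3.0
            denom = (k - 1) * wv.sum()  # = sum over ordered pairs of (W_ij + W_ij')/2
            out[i, 3] = num / denom if denom > 0 else 0.0
    ones = np.flatnonzero((w > 0).sum(axis=1) == 1)
    if len(ones):
        logger.info("%d nodes with a single neighbor: f2 and f4 set to 0", len(ones))
    return out


def annotation_count(older: AnnotationRelease, term: str) -> np.ndarray:
    """Column f5: old-release annotation count excluding the current term."""
    j = older.terms.index(term)
    return older.y.sum(axis=1).astype(float) - older.y[:, j]


def geometric_centralities(
    net: WeightedNetwork, comps: ComponentIndex, paths: ShortestPathCache
) -> np.ndarray:
    """Columns f6-f9 (closeness, Lin's index, harmonic, betweenness)."""
    n = net.n_nodes
    out = np.zeros((n, 4))
    d = paths.dist
    for members in comps.members:
        dsub = d[np.ix_(members, members)]
        sums = dsub.sum(axis=1)
        out[members, 0] = 1.0 / sums
        out[members, 1] = len(members) ** 2 / sums
        with np.errstate(divide="ignore"):
            inv = np.where(dsub > 0, 1.0 / np.where(dsub > 0, dsub, 1.0), 0.0)
        out[members, 2] = inv.sum(axis=1)
    sigma = paths.sigma
    for i in range(n):
        thr = paths.sigma_through(i)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(thr > 0, thr / np.where(sigma > 0, sigma, 1.0), 0.0)
        out[i, 3] = frac.sum() / 2.0  # unordered pairs
    return out


def term_aware_features(
    net: WeightedNetwork,
    comps: ComponentIndex,
    paths: ShortestPathCache,
    ctx: TermContext,
) -> np.ndarray:
    """Columns f10-f14 (positive neighborhood and positive centralities)."""
    n = net.n_nodes
    out = np.zeros((n, 5))
    pos = ctx.positives
    wp = net.w[:, pos] if len(pos) else np.zeros((n, 0))
    out[:, 0] = wp.sum(axis=1)  # f10
    npos_nbrs = (wp > 0).sum(axis=1)
    nz = npos_nbrs > 0
    out[nz, 1] = out[nz, 0] / npos_nbrs[nz]  # f11, 0 when no positive neighbor
    d = paths.dist
    for i in range(n):
        others = pos[(pos != i) & (comps.component_id[pos] == comps.component_id[i])]
        n_comp_pos = int(ctx.is_positive[comps.component_of(i)].sum())
        if len(others) == 0:
            continue  # f12-f14 stay 0: no positive signal reachable
        dv = d[i, others]
        s = dv.sum()
        out[i, 2] = 1.0 / s
        out[i, 3] = n_comp_pos**2 / s
        out[i, 4] = (1.0 / dv).sum()
    return out


def build_random_walk(net: WeightedNetwork, ctx: TermContext) -> RandomWalkOperator:
    """Row-stochastic operator over ``W`` with a uniform positive start."""
    if len(ctx.positives) == 0:
        raise ValueError(f"3Prop undefined for unannotated term {ctx.term!r}")
    rowsum = net.w.sum(axis=1)
    p = net.w / rowsum[:, None]
    y = np.zeros(net.n_nodes)
    y[ctx.positives] = 1.0 / len(ctx.positives)
    return RandomWalkOperator(p=p, y=y)


def three_prop(net: WeightedNetwork, ctx: TermContext) -> np.ndarray:
    """Columns f15-f17: 1/2/3-step random-walk end-point probabilities."""
    op = build_random_walk(net, ctx)
    out = np.zeros((net.n_nodes, 3))
    v = op.y
    for j in range(3):
        v = op.p @ v
        out[:, j] = v
    return out


def normalize_features(mat: TermFeatureMatrix) -> TermFeatureMatrix:
    """Scale each column to sum to one across proteins.

    All-zero columns are left untouched with a warning; negative entries are
    rejected (every feature is non-negative by construction).
    """
    if np.any(mat.values < 0):
        raise ValueError("negative feature values: refusing to normalize")
    sums = mat.values.sum(axis=0)
    zero = sums == 0
    if np.any(zero):
        logger.warning(
            "term %s: all-zero feature columns left unnormalized: %s",
            mat.term,
            [c for c, z in zip(mat.columns, zero) if z],
        )
    scaled = mat.values / np.where(zero, 1.0, sums)[None, :]
    return TermFeatureMatrix(
        values=scaled,
        columns=list(mat.columns),
        term=mat.term,
        node_labels=list(mat.node_labels),
        normalized=True,
    )


# ---------------------------------------------------------------------------
# assembly


class FeatureBuilder:
    """Caches the term-unaware work shared by all terms of one network.

    Shortest paths, local features and geometric centralities are computed
    once; per-term matrices then only add the term-aware columns.
    """

    def __init__(
        self,
        net: WeightedNetwork,
        older: AnnotationRelease,
        cost_mode: str = "weight_as_cost",
    ):
        self.net = net
        self.older = older
        self.cost_mode = cost_mode
        self._comps: ComponentIndex | None = None
        self._paths: ShortestPathCache | None = None
        self._local: np.ndarray | None = None
        self._geom: np.ndarray | None = None

    @property
    def comps(self) -> ComponentIndex:
        if self._comps is None:
            self._comps = connected_components(self.net)
        return self._comps

    @property
    def paths(self) -> ShortestPathCache:
        if self._paths is None:
            self._paths = shortest_paths(self.net, self.comps, self.cost_mode)
        return self._paths

    def _local_block(self) -> np.ndarray:
        if self._local is None:
            self._local = local_features(self.net)
        return self._local

    def _geom_block(self) -> np.ndarray:
        if self._geom is None:
            self._geom = geometric_centralities(self.net, self.comps, self.paths)
        return self._geom

    def term_matrix(
        self,
        term: str,
        features: tuple[str, ...] = FEATURE_NAMES,
        normalized: bool = True,
    ) -> TermFeatureMatrix:
        features = tuple(features)
        unknown = set(features) - set(FEATURE_NAMES)
        if unknown:
            raise KeyError(f"unknown features {sorted(unknown)}")
        order = [f for f in FEATURE_NAMES if f in features]
        ctx = TermContext.from_release(self.older, term)
        cols: dict[str, np.ndarray] = {}
        if set(order) & set(LOCAL_FEATURES):
            block = self._local_block()
            for j, name in enumerate(LOCAL_FEATURES):
                cols[name] = block[:, j]
        if "f5" in order:
            cols["f5"] = annotation_count(self.older, term)
        if set(order) & set(GEOMETRIC_FEATURES):
            block = self._geom_block()
            for j, name in enumerate(GEOMETRIC_FEATURES):
                cols[name] = block[:, j]
        if set(order) & set(POSITIVE_FEATURES):
            block = term_aware_features(self.net, self.comps, self.paths, ctx)
            for j, name in enumerate(POSITIVE_FEATURES):
                cols[name] = block[:, j]
        if set(order) & set(THREE_PROP):
            block = three_prop(self.net, ctx)
            for j, name in enumerate(THREE_PROP):
                cols[name] = block[:, j]
        values = np.column_stack([cols[name] for name in order])
        mat = TermFeatureMatrix(
            values=values,
            columns=order,
            term=term,
            node_labels=list(self.net.node_labels),
            normalized=False,
        )
        return normalize_features(mat) if normalized else mat


def assemble_term_matrix(
    net: WeightedNetwork,
    holdout: TemporalHoldout,
    term: str,
    features: tuple[str, ...] = FEATURE_NAMES,
    cost_mode: str = "weight_as_cost",
    builder: FeatureBuilder | None = None,
    normalized: bool = True,
) -> TermFeatureMatrix:
    """One-shot convenience wrapper around :class:`FeatureBuilder`."""
    if builder is None:
        builder = FeatureBuilder(net, holdout.older, cost_mode=cost_mode)
    return builder.term_matrix(term, features=features, normalized=normalized)
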
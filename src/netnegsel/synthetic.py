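"""Synthetic networks and two-release annotations with planted structure.

The generator emulates the shape of a thresholded STRING network together
with a temporal annotation holdout:

* the network is a planted-partition (community) graph whose edge scores
  are integers in [threshold, 999] drawn from a scaled Beta distribution,
  mimicking combined scores surviving the confidence cutoff;
* per term, old-release positives are sampled inside a home community
  (option: grown assortatively across communities), plus a small uniform
  noise-annotation rate so the multifunctionality feature f5 has a
  non-degenerate distribution;
* the C_np class — non-positives that acquire the annotation in the newer
  release — is planted with a logistic conversion model

      Pr[i converts] = sigmoid(alpha + beta * z_i),

  where ``z`` is the standardized guilt-by-association score of ``i``
  (by default the positive-neighborhood weight f10) and ``alpha`` is
  calibrated by bisection so the expected |C_np| hits a target.  ``beta``
  is the planted effect size: beta = 0 yields uniform conversions, large
  beta ties conversions tightly to network proximity to positives.

All outputs are reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .annotations import AnnotationRelease, TemporalHoldout, build_holdout
from .network import RawNetwork, WeightedNetwork, symmetric_normalize

logger = logging.getLogger(__name__)

SCORE_FUNCTIONS = ("f10", "f10_per_degree", "f10_minus_study")
FIXTURE_NAMES = ("tiny", "relevance", "null", "afp", "negsel")


class SyntheticConfigError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Generation parameters; defaults give a small modular PPI-like graph."""

    community_sizes: tuple[int, ...] = (50, 50)
    p_within: float = 0.3
    p_between: float = 0.01
    #: number of trailing communities kept as separate components (no
    #: between-community edges), mimicking the small satellite components
    #: of thresholded interaction networks
    n_isolated_communities: int = 0
    weight_alpha: float = 2.0
    weight_beta: float = 2.0
    score_threshold: int = 700
    n_terms: int = 10
    pos_range: tuple[int, int] = (10, 14)
    positive_mode: str = "community"  # or "assortative"
    target_cnp: int = 25
    min_cnp: int | None = 20
    beta: float | tuple[float, ...] = 3.0  # per-SD log-odds; tuple cycles per term
    noise_rate: float = 0.02
    conversion_score: str = "f10"
    #: weight of the anti-study-intensity term in the "f10_minus_study"
    #: conversion model (annotation effort catching up on under-studied
    #: proteins during the holdout period)
    study_gamma: float = 1.0
    #: extra old-release-only terms (no conversions; excluded by any C_np
    #: filter) whose positives follow study intensity, giving the
    #: multifunctionality feature f5 a realistic spread
    n_background_terms: int = 0
    seed: int = 0

    @property
    def n_nodes(self) -> int:
        return int(sum(self.community_sizes))

    def beta_for_term(self, t: int) -> float:
        if isinstance(self.beta, (tuple, list)):
            return float(self.beta[t % len(self.beta)])
        return float(self.beta)

    def validate(self) -> None:
        if not (0 <= self.p_within <= 1 and 0 <= self.p_between <= 1):
            raise SyntheticConfigError("edge probabilities must be in [0,1]")
        if any(s < 2 for s in self.community_sizes):
            raise SyntheticConfigError("communities need at least 2 nodes")
        if self.positive_mode not in ("community", "assortative"):
            raise SyntheticConfigError(f"unknown positive_mode {self.positive_mode!r}")
        if self.conversion_score not in SCORE_FUNCTIONS:
            raise SyntheticConfigError(f"unknown conversion_score {self.conversion_score!r}")
        betas = self.beta if isinstance(self.beta, (tuple, list)) else (self.beta,)
        if any(b < 0 for b in betas):
            raise SyntheticConfigError("beta must be non-negative")


@dataclass
class SyntheticDataset:
    """A generated network + holdout pair with its generation log."""

    net: WeightedNetwork
    holdout: TemporalHoldout
    communities: np.ndarray
    config: SyntheticConfig
    log: list[dict] = field(default_factory=list)

    def raw_scores(self) -> np.ndarray:
        """Recover the integer combined scores from the normalized matrix."""
        d = np.sqrt(self.net.degree)
        return np.rint(1000 * self.net.w * d[:, None] * d[None, :]).astype(int)

    def to_dir(self, outdir) -> None:
        """Emit edges.tsv / annotations_old.tsv / annotations_new.tsv."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scores = self.raw_scores()
        labels = self.net.node_labels
        rows = []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                if scores[i, j] > 0:
                    rows.append((labels[i], labels[j], scores[i, j]))
        pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"]).to_csv(
            outdir / "edges.tsv", sep="\t", index=False, header=False
        )
        for rel, fname in ((self.holdout.older, "annotations_old.tsv"),
                           (self.holdout.newer, "annotations_new.tsv")):
            ii, jj = np.nonzero(rel.y)
            pd.DataFrame(
                {
                    "protein": [labels[i] for i in ii],
                    "term": [rel.terms[j] for j in jj],
                    "evidence": "IDA",
                }
            ).to_csv(outdir / fname, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# network generation


def _expected_isolation(cfg: SyntheticConfig) -> float:
    n = cfg.n_nodes
    first_iso = len(cfg.community_sizes) - cfg.n_isolated_communities
    n_core = sum(cfg.community_sizes[:first_iso])
    fracs = []
    for c, size in enumerate(cfg.community_sizes):
        p_iso = (1 - cfg.p_within) ** (size - 1)
        if c < first_iso:
            p_iso *= (1 - cfg.p_between) ** (n_core - size)
        fracs.append(p_iso * size)
    return sum(fracs) / n


def generate_network(cfg: SyntheticConfig, seed: int | None = None) -> WeightedNetwork:
    net, _, _ = generate_network_with_communities(cfg, seed)
    return net


def generate_network_with_communities(
    cfg: SyntheticConfig, seed: int | None = None
) -> tuple[WeightedNetwork, np.ndarray, RawNetwork]:
    """Planted-partition graph with Beta-distributed integer edge scores.

    Nodes left isolated by the Bernoulli draws are re-wired to a random
    member of their own community, so the normalized network never contains
    zero rows.
    """
    cfg.validate()
    if _expected_isolation(cfg) > 0.2:
        raise SyntheticConfigError(
            "edge probabilities too sparse: expected isolated fraction exceeds 20%"
        )
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_nodes
    comm = np.repeat(np.arange(len(cfg.community_sizes)), cfg.community_sizes)
    same = comm[:, None] == comm[None, :]
    p = np.where(same, cfg.p_within, cfg.p_between)
    if cfg.n_isolated_communities:
        first_iso = len(cfg.community_sizes) - cfg.n_isolated_communities
        iso = comm >= first_iso
        p[np.ix_(iso, ~iso)] = 0.0
        p[np.ix_(~iso, iso)] = 0.0
        p[np.ix_(iso, iso)] = np.where(
            same[np.ix_(iso, iso)], cfg.p_within, 0.0
        )
    upper = np.triu(rng.random((n, n)) < p, k=1)

    def draw_scores(k):
        b = rng.beta(cfg.weight_alpha, cfg.weight_beta, size=k)
        span = 999 - cfg.score_threshold
        return cfg.score_threshold + np.rint(span * b).astype(int)

    scores = np.zeros((n, n), dtype=int)
    ii, jj = np.nonzero(upper)
    scores[ii, jj] = draw_scores(len(ii))
    scores = scores + scores.T
    isolated = np.flatnonzero(scores.sum(axis=1) == 0)
    for i in isolated:
        mates = np.flatnonzero((comm == comm[i]) & (np.arange(n) != i))
        j = int(rng.choice(mates))
        s = int(draw_scores(1)[0])
        scores[i, j] = scores[j, i] = s
    if len(isolated):
        logger.info("re-wired %d isolated nodes into their communities", len(isolated))
    labels = [f"P{i + 1:04d}" for i in range(n)]
    raw = RawNetwork(node_labels=labels, weights=scores / 1000.0)
    return symmetric_normalize(raw), comm, raw


# ---------------------------------------------------------------------------
# annotation generation


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def _conversion_predictor(
    net: WeightedNetwork,
    positives: np.ndarray,
    cand: np.ndarray,
    cfg: SyntheticConfig,
    beta: float,
    study: np.ndarray,
) -> np.ndarray:
    """Per-candidate linear predictor (without intercept) of conversion."""
    f10 = net.w[:, positives].sum(axis=1)
    if cfg.conversion_score == "f10":
        return beta * _zscore(f10[cand])
    if cfg.conversion_score == "f10_per_degree":
        # guilt-by-association per unit of total connectivity: the same
        # positive neighborhood weight means more for a sparse protein
        ratio = f10 / (0.5 + net.w.sum(axis=1))
        return beta * _zscore(ratio[cand])
    # f10_minus_study: proximity to positives drives discovery, but
    # annotation effort concentrates on proteins little studied so far
    return beta * _zscore(f10[cand]) - cfg.study_gamma * _zscore(np.log(study[cand]))


def _calibrate_alpha(eta: np.ndarray, target: float) -> float:
    """Bisect the intercept so the expected conversion count hits target."""
    lo, hi = -60.0, 60.0
    if not expit(lo + eta).sum() <= target <= expit(hi + eta).sum():
        raise SyntheticConfigError(
            f"cannot calibrate intercept: target {target} outside achievable range "
            f"for {len(eta)} candidates"
        )
    for _ in range(100):
        mid = (lo + hi) / 2
        if expit(mid + eta).sum() < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _sample_positives(
    net: WeightedNetwork, comm: np.ndarray, cfg: SyntheticConfig, t: int, rng
) -> np.ndarray:
    n_pos = int(rng.integers(cfg.pos_range[0], cfg.pos_range[1] + 1))
    n_comm = len(cfg.community_sizes)
    if cfg.positive_mode == "community":
        home = t % n_comm
        members = np.flatnonzero(comm == home)
        return rng.choice(members, size=min(n_pos, len(members)), replace=False)
    # assortative growth: one random seed per community, then greedy
    # accretion of the node best connected to the current positive set —
    # positives form tight neighborhoods spread across communities, so the
    # positive-neighborhood weight is the separating signal
    pos = [int(rng.choice(np.flatnonzero(comm == c))) for c in range(n_comm)]
    while len(pos) < n_pos:
        rest = np.setdiff1d(np.arange(net.n_nodes), pos)
        wts = net.w[np.ix_(rest, pos)].sum(axis=1)
        pos.append(int(rest[int(np.argmax(wts))]))
    return np.array(sorted(pos))


def generate_two_release_annotations(
    net: WeightedNetwork,
    cfg: SyntheticConfig,
    communities: np.ndarray,
    seed: int | None = None,
) -> tuple[TemporalHoldout, list[dict]]:
    """Plant per-term positives and the logistic C_np conversion process."""
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed if seed is None else seed)
    m_total = cfg.n_terms + cfg.n_background_terms
    streams = ss.spawn(m_total + 1)
    n = net.n_nodes
    # per-protein study intensity: drives which proteins pick up incidental
    # (noise/background) annotations; log-normal like citation-style effort
    study = np.random.default_rng(streams[-1]).lognormal(0.0, 1.0, size=n)
    y_old = np.zeros((n, m_total), dtype=np.uint8)
    y_new = np.zeros((n, m_total), dtype=np.uint8)
    log = []
    for t in range(cfg.n_terms):
        rng = np.random.default_rng(streams[t])
        pos = _sample_positives(net, communities, cfg, t, rng)
        n_noise = rng.binomial(n, cfg.noise_rate)
        if n_noise:
            noise = rng.choice(np.arange(n), size=n_noise, replace=False,
                               p=study / study.sum())
            pos = np.union1d(pos, noise)
        cand = np.setdiff1d(np.arange(n), pos)
        if cfg.target_cnp >= len(cand):
            raise SyntheticConfigError("target |C_np| not smaller than the candidate pool")
        beta = cfg.beta_for_term(t)
        eta = _conversion_predictor(net, pos, cand, cfg, beta, study)
        alpha = _calibrate_alpha(eta, cfg.target_cnp)
        probs = expit(alpha + eta)
        for attempt in range(200):
            converted = rng.random(len(cand)) < probs
            if cfg.min_cnp is None or converted.sum() >= cfg.min_cnp:
                break
        else:
            raise SyntheticConfigError(
                f"term {t}: could not realize |C_np| >= {cfg.min_cnp} in 200 draws"
            )
        y_old[pos, t] = 1
        y_new[pos, t] = 1
        y_new[cand[converted], t] = 1
        log.append(
            {
                "term": f"T{t + 1:04d}",
                "beta": beta,
                "alpha": alpha,
                "n_positives": len(pos),
                "realized_cnp": int(converted.sum()),
                "draw_attempts": attempt + 1,
            }
        )
    for b in range(cfg.n_background_terms):
        rng = np.random.default_rng(streams[cfg.n_terms + b])
        n_pos = int(rng.integers(cfg.pos_range[0], cfg.pos_range[1] + 1))
        pos = rng.choice(np.arange(n), size=n_pos, replace=False, p=study / study.sum())
        col = cfg.n_terms + b
        y_old[pos, col] = 1
        y_new[pos, col] = 1
    terms = [f"T{t + 1:04d}" for t in range(cfg.n_terms)] + [
        f"B{b + 1:04d}" for b in range(cfg.n_background_terms)
    ]
    older = AnnotationRelease(y=y_old, terms=terms, node_labels=net.node_labels, tag="old")
    newer = AnnotationRelease(y=y_new, terms=terms, node_labels=net.node_labels, tag="new")
    return build_holdout(older, newer), log


def generate_dataset(cfg: SyntheticConfig, seed: int | None = None) -> SyntheticDataset:
    """Network + holdout from one config; the one entry point tests use."""
    base = cfg.seed if seed is None else seed
    net, comm, _ = generate_network_with_communities(cfg, seed=base)
    holdout, log = generate_two_release_annotations(net, cfg, comm, seed=base + 1)
    return SyntheticDataset(net=net, holdout=holdout, communities=comm, config=cfg, log=log)


# ---------------------------------------------------------------------------
# canned fixtures

_FIXTURE_CONFIGS: dict[str, SyntheticConfig] = {
    # tiny: exercises the full pipeline end-to-end in seconds; min_cnp 5
    # instead of 20 because only ~25 candidates exist per term
    "tiny": SyntheticConfig(
        community_sizes=(10, 10, 10),
        p_within=0.5,
        p_between=0.05,
        n_terms=2,
        pos_range=(4, 6),
        target_cnp=12,
        min_cnp=5,
        beta=2.5,
        noise_rate=0.05,
        seed=20301,
    ),
    # relevance: many terms with a strong planted guilt-by-association
    # effect, for feature-selection parameter recovery.  One large bridged
    # component plus two satellite components of different sizes, and
    # positives spread assortatively, so every feature (component-aware
    # Lin's index included) has a non-degenerate distribution
    "relevance": SyntheticConfig(
        community_sizes=(40, 35, 30, 20, 15, 10),
        p_within=0.30,
        p_between=0.02,
        n_isolated_communities=2,
        n_terms=55,
        pos_range=(12, 16),
        positive_mode="assortative",
        target_cnp=25,
        min_cnp=20,
        beta=3.0,
        noise_rate=0.05,
        seed=41007,
    ),
    # afp: assortative positive sets spread over all communities, so the
    # direct positive-neighborhood weight is the separating signal while
    # component-level positive centralities are flattened
    # dense between-community wiring keeps the graph diameter small, so
    # distance-to-positive features are flat and the direct positive
    # neighborhood carries the separating signal
    "afp": SyntheticConfig(
        community_sizes=(25,) * 4,
        p_within=0.35,
        p_between=0.10,
        n_terms=3,
        pos_range=(20, 24),
        positive_mode="assortative",
        target_cnp=20,
        min_cnp=None,
        beta=2.0,
        noise_rate=0.04,
        seed=52019,
    ),
    # negsel: graded guilt-by-association effect sizes across terms;
    # background terms give the multifunctionality feature a realistic
    # spread without adding conversion structure
    "negsel": SyntheticConfig(
        community_sizes=(40,) * 4,
        p_within=0.30,
        p_between=0.02,
        n_terms=8,
        pos_range=(10, 14),
        target_cnp=25,
        min_cnp=20,
        beta=(2.0, 3.0, 4.0),
        noise_rate=0.02,
        conversion_score="f10",
        n_background_terms=20,
        seed=63011,
    ),
}
# null: the beta = 0 twin of relevance (identical in everything else)
_FIXTURE_CONFIGS["null"] = replace(_FIXTURE_CONFIGS["relevance"], beta=0.0)

#: per-fixture C_np filter threshold used by the experiment drivers
FIXTURE_MIN_CNP = {"tiny": 5, "relevance": 20, "null": 20, "afp": 1, "negsel": 20}


def fixture_config(name: str) -> SyntheticConfig:
    if name not in _FIXTURE_CONFIGS:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return _FIXTURE_CONFIGS[name]


def make_fixture(name: str, seed: int | None = None) -> SyntheticDataset:
    """Generate a canned dataset; bit-identical for a given (name, seed)."""
    return generate_dataset(fixture_config(name), seed=seed)
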
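"""End-to-end driver chaining every stage on one dataset.

Mainly used for small-scale smoke runs and reproducibility checks: generate
a synthetic dataset, extract the 17 features for every retained term, run
the relevance analysis for both feature pools, the function-prediction
experiment, and the budgeted negative selection, writing each stage's
output as TSV under a target directory.  Byte-identical outputs across runs
with the same seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .annotations import TermFilter, filter_terms
from .features import FEATURE_NAMES, FeatureBuilder
from .negsel import BudgetGrid, evaluate_configurations, standard_configurations
from .prediction import ClassifierSpec, metrics_to_frame, nested_cv_evaluate
from .relevance import DegenerateTermError, SffsConfig, triple_loop_relevance
from .synthetic import FIXTURE_MIN_CNP, make_fixture

logger = logging.getLogger(__name__)

F1_14 = tuple(f"f{i}" for i in range(1, 15))


def run_pipeline(
    out_dir,
    fixture: str = "tiny",
    seed: int | None = None,
    rf_trees: int = 100,
) -> Path:
    """Run synth -> features -> relevance -> prediction -> negsel.

    Returns the output directory.  All stages derive their seeds from the
    dataset seed, so two runs with identical arguments produce identical
    files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset = make_fixture(fixture, seed=seed)
    base_seed = dataset.config.seed if seed is None else seed
    dataset.to_dir(out / "data")

    holdout = dataset.holdout
    flt = TermFilter(rule="min_cnp", min_cnp_size=FIXTURE_MIN_CNP[fixture])
    terms = filter_terms(holdout, flt)
    builder = FeatureBuilder(dataset.net, holdout.older)

    feat_dir = out / "features"
    feat_dir.mkdir(exist_ok=True)
    for term in terms:
        builder.term_matrix(term).to_tsv(feat_dir / f"{term}.features.tsv")

    sffs_cfg = SffsConfig(seed=base_seed + 11)
    freq_f14 = triple_loop_relevance(builder, holdout, terms, F1_14, sffs_cfg)
    freq_f17 = triple_loop_relevance(builder, holdout, terms, FEATURE_NAMES, sffs_cfg)
    freq_f14.to_tsv(out / "relevance_f1-f14.tsv")
    freq_f17.to_tsv(out / "relevance_f1-f17.tsv")

    specs = [
        ClassifierSpec(family="linear_svm", seed=base_seed + 23),
        ClassifierSpec(family="random_forest", n_estimators=rf_trees, seed=base_seed + 23),
    ]
    records = []
    for term in terms:
        j = holdout.older.terms.index(term)
        labels = holdout.older.y[:, j].astype(int)
        matrix = builder.term_matrix(term)
        for spec in specs:
            try:
                records.append(
                    nested_cv_evaluate(
                        matrix.subset(list(F1_14)), labels, spec,
                        term=term, representation="f1-f14",
                    )
                )
            except DegenerateTermError as exc:
                logger.info("prediction skipped: %s", exc)
    if records:
        metrics_to_frame(records).to_csv(
            out / "prediction_metrics.tsv", sep="\t", index=False, float_format="%.12g"
        )

    configs = standard_configurations(freq_f14, freq_f17)
    report = evaluate_configurations(builder, holdout, terms, configs, specs, BudgetGrid())
    report.to_tsv(out / "negative_selection.tsv")
    return out
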
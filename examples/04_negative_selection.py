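"""Select reliable negative examples under a budget and count mistakes.

Trains per-term rankers on the older annotation release, selects the
bottom-scored x% of proteins as "reliable negatives" for
x in {1,...,30}, and counts false negatives: selected proteins that in
fact acquired the annotation in the newer release.  Seven feature
configurations are compared; the random-baseline column shows the FN
count a blind selection would make on average.
"""

from netnegsel import (
    BudgetGrid,
    ClassifierSpec,
    FeatureBuilder,
    SffsConfig,
    TermFilter,
    evaluate_configurations,
    filter_terms,
    standard_configurations,
    triple_loop_relevance,
)
from netnegsel.features import FEATURE_NAMES
from netnegsel.synthetic import make_fixture

F14 = tuple(f"f{i}" for i in range(1, 15))

ds = make_fixture("negsel")
holdout = ds.holdout
terms = filter_terms(holdout, TermFilter(min_cnp_size=20))
builder = FeatureBuilder(ds.net, holdout.older)

# resolve the rule-based configurations from fresh relevance runs
sffs = SffsConfig(seed=17)
freq14 = triple_loop_relevance(builder, holdout, terms, F14, sffs)
freq17 = triple_loop_relevance(builder, holdout, terms, FEATURE_NAMES, sffs)
configs = standard_configurations(freq14, freq17)

specs = [
    ClassifierSpec(family="linear_svm", seed=29),
    ClassifierSpec(family="random_forest", n_estimators=200, rf_min_samples_leaf=10, seed=29),
]
report = evaluate_configurations(builder, holdout, terms, configs, specs, BudgetGrid())
summary = report.summary()
print(summary.pivot_table(index=["configuration", "model"],
                          columns="budget_pct", values="mean_FN").round(2).to_string())
print("\nrandom baseline per budget:",
      summary.groupby("budget_pct").baseline_FN.mean().round(2).to_dict())
# every cell below its baseline means the features steer the selection away
# from the proteins that were about to become positives
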
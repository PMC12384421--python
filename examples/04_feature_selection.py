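"""Run all four selector families against a planted ground truth.

The recovery fixture plants 5 informative features among 40 (+-1.5 SD shifts
for the pathologic/ecs classes); each strategy is asked for exactly 5
features and scored by its overlap with the planted set.
"""

from radefs import (
    ClassifierSpec,
    GAParams,
    SelectionRequest,
    ga_select,
    generate_cohort,
    importance_select,
    recovery_config,
    rfe_select,
    sda_select,
)

cohort, truth = generate_cohort(recovery_config(seed=0))
planted = truth.informative()
print(f"planted: {sorted(planted)}\n")

results = {
    "GA (10 runs, consensus)": ga_select(
        cohort, SelectionRequest("ga", p=5, runs=10, seed=0),
        params=GAParams(population=200, generations=50)),
    "RFE (linear SVM)": rfe_select(
        cohort, SelectionRequest("rfe", p=5, runs=1, seed=0,
                                 estimator=ClassifierSpec("svm_linear"))),
    "SDA (elastic-net scoring)": sda_select(
        cohort, SelectionRequest("sda", p=5, runs=1, seed=0)),
    "RF importance (10 runs)": importance_select(
        cohort, SelectionRequest("rf_importance", p=5, runs=10, seed=0)),
}
for name, res in results.items():
    overlap = len(set(res.selected) & planted)
    print(f"{name:<28} recovered {overlap}/5: {sorted(res.selected)}")

# Each family should recover at least 4 of the 5 planted features; the GA
# consensus additionally reports per-feature selection frequencies.
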
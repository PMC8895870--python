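"""Rank human targets by disease association with the balanced RF ensemble.

Runs the full prioritization recipe on a simulated cohort with 10 planted
differential targets: stratified 5-fold CV with grid search to confirm the
classifier separates cases from controls, then 100 class-balanced random
forests whose mean Gini importances select the disease-associated set
(strictly above the 90th percentile).
"""

from hmppi.association import (
    ModelConfig,
    balanced_importance_ensemble,
    crossval,
    mannwhitney_targets,
)
from hmppi.profiles import build_target_profiles, prevalence_filter
from hmppi.simulate import sim_cohort

matrix, network, manifest = sim_cohort(seed=1)  # n=100/100, 10 planted targets
profiles = prevalence_filter(build_target_profiles(matrix, network))
labels = profiles.sample_meta["label"]

config = ModelConfig(seed=1)
report = crossval(profiles.values, labels, config)
print(f"5-fold CV mean F1: {report.mean_f1:.3f} (best grid point {report.best_params})")

importances = balanced_importance_ensemble(
    profiles.values, labels, config, params=report.best_params
)
selected = importances.selected_targets()
recovered = sorted(set(manifest.planted_targets) & set(selected))
print(f"disease-associated set: {len(selected)} targets above the 90th percentile")
print(f"planted targets recovered: {len(recovered)}/{len(manifest.planted_targets)}")

mw = mannwhitney_targets(profiles.values, labels, recovered[:3])
print("\nMann-Whitney case-vs-control tests for three recovered targets:")
print(mw.to_string(float_format=lambda v: f"{v:.3g}"))
print("\nsmall p-values confirm the planted case/control abundance shift.")
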
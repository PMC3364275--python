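"""Classify a synthetic cohort with the nested leave-one-out SVM ensemble.

Runs the full pipeline — band decomposition, Fisher-z networks, clustering
coefficients, relevance ranking + SVM-RFE, nested LOOCV with an RBF-SVM
ensemble — on a cohort with a Band3-localized deficit, and prints the
cross-validated accuracy, AUC and the most frequently selected features.
Takes roughly half a minute.
"""

from bandconn import (
    PipelineConfig,
    SyntheticConfig,
    cohort_to_features,
    generate_cohort,
    nested_loocv,
)

config = SyntheticConfig(
    n_patients=13, n_controls=13, n_rois=12, n_timepoints=140,
    affected_roi_set=tuple(range(8)), within_band_coupling=0.6,
    effect_delta=0.4, noise_sd=0.5, seed=604,
)
cohort = generate_cohort(config)
table, _ = cohort_to_features(cohort, PipelineConfig(mode="multi"))
print(f"feature table: {table.n_subjects} subjects x {table.n_features} "
      "features (5 bands x 12 ROIs)")

result = nested_loocv(table, grid=[(0.5, 0.125), (8.0, 0.125)], top_m=6)
print(f"nested-LOOCV accuracy: {result.accuracy:.1f}%   AUC: {result.auc:.3f}")
print("\nmost frequently selected features (band, ROI, count over "
      f"{len(result.traces)} inner folds):")
for band, roi, count in result.selection_frequency[:6]:
    print(f"  {band:6} {roi:7} {count}")
print("\nThe deficit lives in Band3, so Band3 features of the affected ROIs "
      "should dominate the selections.")
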
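"""Compare multi-spectrum, full-spectrum and single-band classification.

The same cohort (Band3-localized deficit) is classified seven ways: from
the five sub-band networks jointly, from one full-band network, and from
each sub-band alone.  The printed table mirrors the method's central claim:
sub-band decomposition preserves a frequency-localized effect that full-band
averaging dilutes, and the affected band carries the discriminative signal.
Takes a few minutes.
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

print("Approach        Accuracy    AUC")
for mode in ["multi", "full", "band1", "band2", "band3", "band4", "band5"]:
    table, _ = cohort_to_features(cohort, PipelineConfig(mode=mode))
    result = nested_loocv(table, grid=[(0.5, 0.125), (8.0, 0.125)], top_m=6)
    label = {"multi": "Multi-Spectrum", "full": "Full-Spectrum"}.get(
        mode, mode.capitalize()
    )
    print(f"{label:14}  {result.accuracy:6.2f}   {result.auc:.4f}")
print("\nBand3 holds the planted group difference; multi-spectrum and "
      "Band3-only runs should lead, full-spectrum should trail.")
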
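"""Build per-band connectivity networks and clustering-coefficient features.

For one synthetic subject: decompose the regional series into five bands,
correlate every ROI pair per band, Fisher-transform, and reduce each
network to one weighted clustering coefficient per node.  Coupled ROIs
(0-3 here) show higher Band3 clustering than the uncoupled ones.
"""

import numpy as np

from bandconn import (
    SyntheticConfig,
    build_networks,
    clustering_coefficients,
    generate_cohort,
)

config = SyntheticConfig(
    n_patients=1, n_controls=1, n_rois=8, n_timepoints=600,
    affected_roi_set=(0, 1, 2, 3), within_band_coupling=0.0,
    effect_delta=-0.7, noise_sd=0.2, seed=3,
)  # patient group coupling: 0.0 - (-0.7) = 0.7, Band3 only
cohort = generate_cohort(config)

networks = build_networks(cohort.data[0], config.bands, config.tr_seconds,
                          mode="multi", subject_id=cohort.subject_ids[0])
print(f"built {len(networks)} networks of {networks[0].n_rois} ROIs "
      f"(Fisher-z weights, z sd ~ 1/sqrt(n-3) with n={networks[0].n_timepoints_used})")
print("\nper-node clustering coefficients (rows = bands):")
print("          " + "  ".join(f"ROI_{i+1:<3}" for i in range(8)))
for net in networks:
    c = clustering_coefficients(net)
    print(f"{net.band.name:8} " + "  ".join(f"{v:6.3f}" for v in c))
print("\nROIs 1-4 share a Band3-only latent signal: their Band3 clustering "
      "coefficients dominate the row.")
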
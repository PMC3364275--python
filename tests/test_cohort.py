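"""Synthetic cohort generator: determinism, spectra, coupling recovery, IO."""

import numpy as np
import pytest

from bandconn import (
    SyntheticConfig,
    decompose_bands,
    default_bands,
    generate_cohort,
    pearson_matrix,
    read_cohort,
    write_cohort,
)
from bandconn.cohort import _band_component


def _affected_coupling(cohort, cfg, subject_indices):
    """Mean pairwise correlation among affected ROIs in the affected band."""
    rois = list(cfg.affected_roi_set)
    iu = np.triu_indices(len(rois), 1)
    vals = []
    for i in subject_indices:
        comp = decompose_bands(cohort.data[i], cfg.bands, cfg.tr_seconds)[
            cfg.affected_band_index
        ]
        vals.append(pearson_matrix(comp[rois])[iu].mean())
    return float(np.mean(vals))


class TestGenerator:
    def test_deterministic_given_seed(self):
        cfg = SyntheticConfig(n_patients=2, n_controls=2, n_rois=6, n_timepoints=80, seed=7,
                              affected_roi_set=(0, 1, 2))
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        assert np.array_equal(a.data, b.data)
        assert a.subject_ids == b.subject_ids

    def test_labels_and_shapes(self):
        cfg = SyntheticConfig(n_patients=3, n_controls=4, n_rois=8, n_timepoints=100,
                              affected_roi_set=(0, 1))
        coh = generate_cohort(cfg)
        assert coh.data.shape == (7, 8, 100)
        assert (coh.labels[:3] == 1).all() and (coh.labels[3:] == -1).all()

    def test_band_component_spectrally_pure(self):
        cfg = SyntheticConfig(n_patients=1, n_controls=1, n_rois=4, n_timepoints=140,
                              affected_roi_set=(0, 1))
        rng = np.random.default_rng(3)
        for b, band in enumerate(cfg.bands):
            comp = _band_component(rng, cfg, band, 0.5)
            spec = np.abs(np.fft.rfft(comp, axis=-1)) ** 2
            mask = cfg._band_bins(band)
            out_of_band = spec[:, ~mask].sum()
            assert out_of_band < 1e-9 * spec.sum()

    def test_configured_coupling_recovered(self):
        # long series, no noise: measured in-band correlations match the
        # configured values within Monte-Carlo error over replicates
        pats, ctls = [], []
        for seed in range(50):
            cfg = SyntheticConfig(n_patients=1, n_controls=1, n_rois=6, n_timepoints=1000,
                                  affected_roi_set=(0, 1, 2, 3),
                                  within_band_coupling=0.6, effect_delta=0.4,
                                  noise_sd=0.0, seed=seed)
            coh = generate_cohort(cfg)
            pats.append(_affected_coupling(coh, cfg, [0]))
            ctls.append(_affected_coupling(coh, cfg, [1]))
        for observed, target in [(pats, 0.2), (ctls, 0.6)]:
            mean = np.mean(observed)
            se = np.std(observed, ddof=1) / np.sqrt(len(observed))
            assert abs(mean - target) < 4 * se + 0.02, (mean, target, se)

    def test_null_effect_shows_no_group_difference(self):
        diffs = []
        for seed in range(12):
            cfg = SyntheticConfig(n_patients=4, n_controls=4, n_rois=6, n_timepoints=140,
                                  affected_roi_set=(0, 1, 2), within_band_coupling=0.5,
                                  effect_delta=0.0, noise_sd=0.3, seed=seed)
            coh = generate_cohort(cfg)
            diffs.append(_affected_coupling(coh, cfg, range(4))
                         - _affected_coupling(coh, cfg, range(4, 8)))
        mean, se = np.mean(diffs), np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(mean) < 3 * se

    def test_effect_sign_recovered_across_replicates(self):
        # a 0.4 coupling reduction at 140 timepoints shows the right sign of
        # group difference in nearly every replicate cohort
        hits = 0
        n_rep = 30
        for seed in range(n_rep):
            cfg = SyntheticConfig(n_patients=5, n_controls=5, n_rois=8, n_timepoints=140,
                                  affected_roi_set=(0, 1, 2, 3),
                                  within_band_coupling=0.6, effect_delta=0.4,
                                  noise_sd=0.5, seed=1000 + seed)
            coh = generate_cohort(cfg)
            diff = (_affected_coupling(coh, cfg, range(5))
                    - _affected_coupling(coh, cfg, range(5, 10)))
            hits += diff < 0  # patients weaker-coupled
        assert hits >= 0.95 * n_rep

    @pytest.mark.parametrize(
        "override",
        [
            {"within_band_coupling": 0.2, "effect_delta": 1.3},  # invalid correlation
            {"n_rois": 2},
            {"affected_roi_set": (0,)},
            {"affected_roi_set": (0, 99)},
            {"n_timepoints": 8},  # cannot resolve 0.014 Hz-wide bands
        ],
    )
    def test_invalid_configs_rejected(self, override):
        params = dict(n_patients=2, n_controls=2, n_rois=6, n_timepoints=140,
                      affected_roi_set=(0, 1, 2))
        params.update(override)
        with pytest.raises(ValueError):
            SyntheticConfig(**params)


class TestCohortIO:
    def test_round_trip_preserves_values(self, tmp_path, small_cohort):
        manifest = write_cohort(small_cohort, tmp_path)
        back = read_cohort(manifest)
        # values are written with 12 significant digits
        assert np.allclose(back.data, small_cohort.data, rtol=1e-11, atol=1e-13)
        assert back.subject_ids == small_cohort.subject_ids
        assert np.array_equal(back.labels, small_cohort.labels)
        assert back.tr_seconds == small_cohort.tr_seconds
        assert back.region_names == small_cohort.region_names

    def test_manifest_row_per_subject(self, tmp_path, small_cohort):
        manifest = write_cohort(small_cohort, tmp_path)
        rows = manifest.read_text().strip().splitlines()
        assert len(rows) == 1 + small_cohort.n_subjects

    def test_refuses_overwrite_without_flag(self, tmp_path, small_cohort):
        write_cohort(small_cohort, tmp_path)
        with pytest.raises(FileExistsError):
            write_cohort(small_cohort, tmp_path)
        write_cohort(small_cohort, tmp_path, overwrite=True)

    def test_empty_cohort_rejected(self, tmp_path, small_cohort):
        import dataclasses

        empty = dataclasses.replace(
            small_cohort,
            subject_ids=[],
            data=np.empty((0, small_cohort.n_rois, small_cohort.n_timepoints)),
            labels=np.empty(0, dtype=int),
        )
        with pytest.raises(ValueError):
            write_cohort(empty, tmp_path / "empty")
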
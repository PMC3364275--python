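"""Synthetic two-group cohorts with band-localized connectivity differences.

The generator stands in for a clinical resting-state fMRI cohort: each
subject's regional series is a sum of independent band-limited components
plus white measurement noise.  Within each band, a chosen set of "coupled"
ROIs shares an equicorrelation (a single latent factor when the coupling is
non-negative); in exactly one band the patient group's coupling is reduced
by ``effect_delta``, mimicking a frequency-specific loss of functional
connectivity.  Everything downstream (band networks, clustering-coefficient
features, classification) can then be validated against this known ground
truth.

Band limiting is applied *after* correlating — the FFT of the correlated
white series is masked to the band — so the same orthogonal projection acts
on every ROI and the target pairwise correlation is preserved in
expectation within the band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bands import BandSpec, default_bands
from .signal import LABEL_CONTROL, LABEL_PATIENT, RegionalTimeSeriesSet

__all__ = ["SyntheticConfig", "generate_cohort", "add_common_contamination"]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    Defaults mirror a small clinical resting-state study: 12 patients and
    25 controls, 116 ROIs, 140 timepoints at TR = 2 s, with the group
    difference confined to the third of the five standard sub-bands.
    """

    n_patients: int = 12
    n_controls: int = 25
    n_rois: int = 116
    n_timepoints: int = 140
    tr_seconds: float = 2.0
    bands: list[BandSpec] = field(default_factory=default_bands)
    affected_band_index: int = 2
    affected_roi_set: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    within_band_coupling: float = 0.6
    effect_delta: float = 0.4
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 3:
            raise ValueError("n_rois must be >= 3")
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("both groups must be non-empty")
        if not self.bands:
            raise ValueError("need at least one band")
        if not 0 <= self.affected_band_index < len(self.bands):
            raise ValueError("affected_band_index out of range")
        roi_set = tuple(sorted(set(int(r) for r in self.affected_roi_set)))
        if len(roi_set) < 2:
            raise ValueError("affected_roi_set must contain >= 2 distinct ROIs")
        if not all(0 <= r < self.n_rois for r in roi_set):
            raise ValueError("affected_roi_set indices out of range")
        self.affected_roi_set = roi_set
        if not 0 <= self.within_band_coupling < 1:
            raise ValueError("within_band_coupling must lie in [0, 1)")
        patient_rho = self.within_band_coupling - self.effect_delta
        if not -1 < patient_rho < 1:
            raise ValueError(
                f"patient-group coupling {patient_rho} is not a valid correlation"
            )
        k = len(roi_set)
        if patient_rho <= -1.0 / (k - 1):
            raise ValueError(
                f"equicorrelation {patient_rho} over {k} ROIs is not positive definite"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        nyq = 1.0 / (2.0 * self.tr_seconds)
        if self.bands[-1].f_hi > nyq * (1 + 1e-12):
            raise ValueError("bands exceed the Nyquist frequency for this TR")
        for b in self.bands:
            if not self._band_bins(b).any():
                raise ValueError(
                    f"{self.n_timepoints} timepoints cannot resolve band {b.name!r}"
                )

    def _band_bins(self, band: BandSpec) -> np.ndarray:
        freqs = np.fft.rfftfreq(self.n_timepoints, d=self.tr_seconds)
        closed = band is self.bands[-1]
        hi_ok = freqs <= band.f_hi if closed else freqs < band.f_hi
        mask = (freqs >= band.f_lo) & hi_ok
        if band.f_lo > 0:
            mask[0] = False
        return mask


def _equicorrelated(rng: np.random.Generator, k: int, n: int, rho: float) -> np.ndarray:
    """k Gaussian series of length n with pairwise correlation rho."""
    white = rng.standard_normal((k, n))
    if rho == 0:
        return white
    if rho > 0:
        factor = rng.standard_normal(n)
        return np.sqrt(rho) * factor + np.sqrt(1 - rho) * white
    corr = np.full((k, k), rho) + (1 - rho) * np.eye(k)
    return np.linalg.cholesky(corr) @ white


def _band_component(
    rng: np.random.Generator, config: SyntheticConfig, band: BandSpec, rho: float
) -> np.ndarray:
    """One band-limited component (n_rois x n_timepoints), unit variance."""
    n, r = config.n_timepoints, config.n_rois
    coupled = np.asarray(config.affected_roi_set)
    series = rng.standard_normal((r, n))
    series[coupled] = _equicorrelated(rng, coupled.size, n, rho)
    mask = config._band_bins(band)
    spec = np.fft.rfft(series, axis=-1) * mask
    out = np.fft.irfft(spec, n=n, axis=-1)
    # rescale to unit expected variance: each retained bin carries 2 real
    # dof except DC and (even-n) Nyquist
    freqs_n = mask.sum() * 2
    if mask[0]:
        freqs_n -= 1
    if n % 2 == 0 and mask[-1]:
        freqs_n -= 1
    return out * np.sqrt(n / freqs_n)


def generate_cohort(config: SyntheticConfig) -> RegionalTimeSeriesSet:
    """Generate a labelled two-group cohort; deterministic given the seed.

    Patients are labelled +1 and listed first, controls -1.  Each subject's
    ROI series is the sum of one component per band plus white noise of
    standard deviation ``noise_sd``; in the affected band the patient
    group's coupling among ``affected_roi_set`` is reduced by
    ``effect_delta``.
    """
    rng = np.random.default_rng(config.seed)
    data, ids, labels = [], [], []
    groups = [(LABEL_PATIENT, "P", config.n_patients), (LABEL_CONTROL, "C", config.n_controls)]
    for label, prefix, count in groups:
        for s in range(count):
            subject = np.zeros((config.n_rois, config.n_timepoints))
            for b, band in enumerate(config.bands):
                rho = config.within_band_coupling
                if label == LABEL_PATIENT and b == config.affected_band_index:
                    rho -= config.effect_delta
                subject += _band_component(rng, config, band, rho)
            if config.noise_sd > 0:
                subject += config.noise_sd * rng.standard_normal(subject.shape)
            data.append(subject)
            ids.append(f"{prefix}{s + 1:03d}")
            labels.append(label)
    region_names = [f"ROI_{i + 1}" for i in range(config.n_rois)]
    return RegionalTimeSeriesSet(
        subject_ids=ids,
        data=np.stack(data),
        labels=np.asarray(labels),
        region_names=region_names,
        tr_seconds=config.tr_seconds,
    )


def add_common_contamination(
    cohort: RegionalTimeSeriesSet, sd: float, seed: int
) -> RegionalTimeSeriesSet:
    """Add a shared per-subject noise series to every ROI.

    A crude stand-in for the non-neuronal signal that tissue masking removes
    in voxel data: a common additive component inflates all pairwise
    correlations and dilutes group differences.
    """
    rng = np.random.default_rng(seed)
    data = cohort.data.copy()
    for i in range(cohort.n_subjects):
        data[i] += sd * rng.standard_normal(cohort.n_timepoints)
    return RegionalTimeSeriesSet(
        subject_ids=list(cohort.subject_ids),
        data=data,
        labels=cohort.labels.copy(),
        region_names=list(cohort.region_names),
        tr_seconds=cohort.tr_seconds,
    )
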
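"""Regional time-series containers, band-pass filtering and FFT decomposition.

The pipeline's entry point is a set of regional mean BOLD time series
(ROIs x timepoints per subject) with a known sampling interval (TR).
Filtering and sub-band decomposition use an ideal rectangular mask on the
real FFT: a frequency bin belongs to an interval iff its centre frequency
``k / (N * TR)`` falls inside it.  With an ideal mask the sub-bands form an
exact partition of the band-passed signal — the property the full- versus
multi-spectrum comparison rests on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .bands import BandSpec, validate_partition

__all__ = [
    "RegionalTimeSeriesSet",
    "discard_initial_volumes",
    "bandpass_filter",
    "decompose_bands",
    "extract_regional_means",
]

LABEL_PATIENT = 1
LABEL_CONTROL = -1


@dataclass
class RegionalTimeSeriesSet:
    """Per-subject regional mean time series with labels and sampling interval.

    Parameters
    ----------
    subject_ids : list of str
    data : ndarray, shape (n_subjects, n_rois, n_timepoints)
        Regional mean signal amplitudes.
    labels : ndarray of int, shape (n_subjects,)
        +1 patient, -1 control, 0 unknown.
    region_names : list of str, length n_rois
    tr_seconds : float
        Sampling interval (repetition time) in seconds.
    """

    subject_ids: list[str]
    data: np.ndarray
    labels: np.ndarray
    region_names: list[str]
    tr_seconds: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_subjects, n_rois, n_timepoints)")
        n_subj, n_rois, _ = self.data.shape
        if len(self.subject_ids) != n_subj or len(self.labels) != n_subj:
            raise ValueError("subject_ids/labels length mismatch with data")
        if len(self.region_names) != n_rois:
            raise ValueError("region_names length mismatch with data")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contain NaN/Inf")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")
        if not np.all(np.isin(self.labels, (-1, 0, 1))):
            raise ValueError("labels must be in {+1, -1, 0}")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)


def discard_initial_volumes(series: np.ndarray, n_discard: int) -> np.ndarray:
    """Drop the first ``n_discard`` timepoints (last axis) of a series.

    Early fMRI volumes are acquired before magnetization equilibrium and are
    conventionally discarded (e.g. 150 acquired volumes -> 140 retained).
    """
    if n_discard < 0:
        raise ValueError("n_discard must be >= 0")
    series = np.asarray(series)
    if n_discard >= series.shape[-1]:
        raise ValueError(
            f"cannot discard {n_discard} of {series.shape[-1]} timepoints (empty result)"
        )
    return series[..., n_discard:]


def _bin_mask(n: int, tr_seconds: float, f_lo: float, f_hi: float, closed_upper: bool) -> np.ndarray:
    """Boolean mask over rfft bins whose centre frequency lies in the interval.

    DC (bin 0) is retained only when ``f_lo == 0``.
    """
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    if closed_upper:
        mask = (freqs >= f_lo) & (freqs <= f_hi)
    else:
        mask = (freqs >= f_lo) & (freqs < f_hi)
    if f_lo > 0:
        mask[0] = False
    return mask


def _apply_mask(ts: np.ndarray, mask: np.ndarray) -> np.ndarray:
    spec = np.fft.rfft(ts, axis=-1)
    spec = spec * mask
    return np.fft.irfft(spec, n=ts.shape[-1], axis=-1)


def bandpass_filter(
    ts: np.ndarray, f_lo: float, f_hi: float, tr_seconds: float
) -> np.ndarray:
    """Ideal FFT band-pass filter on the closed interval ``[f_lo, f_hi]``.

    Fourier coefficients whose bin centre lies outside the interval are
    zeroed; the DC bin is always zeroed when ``f_lo > 0``.  The upper edge is
    inclusive so that filtering over ``[0, Nyquist]`` is the identity and the
    filter matches the union of a band partition whose last band is closed.
    Operates on the last axis; accepts a single series or a stack.

    The filter is linear, idempotent and returns a real series for real
    input (conjugate-symmetric masking via the real FFT).
    """
    ts = np.asarray(ts, dtype=float)
    if f_lo >= f_hi:
        raise ValueError(f"need f_lo < f_hi, got [{f_lo}, {f_hi}]")
    nyq = 1.0 / (2.0 * tr_seconds)
    if f_hi > nyq * (1 + 1e-12):
        raise ValueError(f"f_hi={f_hi} exceeds Nyquist frequency {nyq}")
    if ts.shape[-1] < 4:
        raise ValueError("series too short to filter (need >= 4 timepoints)")
    return _apply_mask(ts, _bin_mask(ts.shape[-1], tr_seconds, f_lo, f_hi, closed_upper=True))


def decompose_bands(
    ts: np.ndarray, bands: list[BandSpec], tr_seconds: float
) -> list[np.ndarray]:
    """Split a series into one band-limited component per band.

    Interior bands take bins on ``[f_lo, f_hi)``; the last band is closed at
    its upper edge.  Each rfft bin of the union interval is therefore
    assigned to exactly one band, so the components sum to
    ``bandpass_filter(ts, bands[0].f_lo, bands[-1].f_hi, tr)`` to machine
    precision.  Operates on the last axis.
    """
    ts = np.asarray(ts, dtype=float)
    validate_partition(bands)
    nyq = 1.0 / (2.0 * tr_seconds)
    if bands[-1].f_hi > nyq * (1 + 1e-12):
        raise ValueError(f"band {bands[-1].name!r} exceeds Nyquist frequency {nyq}")
    n = ts.shape[-1]
    out = []
    for k, band in enumerate(bands):
        closed = k == len(bands) - 1
        mask = _bin_mask(n, tr_seconds, band.f_lo, band.f_hi, closed_upper=closed)
        if not mask.any():
            raise ValueError(
                f"series of {n} timepoints at TR={tr_seconds}s has no frequency bin "
                f"inside band {band.name!r} [{band.f_lo}, {band.f_hi})"
            )
        out.append(_apply_mask(ts, mask))
    return out


def extract_regional_means(
    functional: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Average a 4D functional volume over each labelled region.

    Parameters
    ----------
    functional : ndarray, shape (x, y, z, t)
    labels : integer ndarray, shape (x, y, z)
        ROI label volume (e.g. an anatomical parcellation); 0 = background.
    mask : boolean/integer ndarray, shape (x, y, z), optional
        Tissue mask (e.g. gray matter); voxels outside it are excluded from
        every regional average.

    Returns
    -------
    (series, names) : ndarray of shape (n_rois, t) and the label names.
        Labels are taken in ascending numeric order.  A label whose voxels
        all fall outside the mask yields an all-zero series and a warning.
    """
    functional = np.asarray(functional, dtype=float)
    labels = np.asarray(labels)
    if functional.ndim != 4:
        raise ValueError("functional must be 4D (x, y, z, t)")
    if labels.shape != functional.shape[:3]:
        raise ValueError("label volume grid does not match functional grid")
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != functional.shape[:3]:
            raise ValueError("mask grid does not match functional grid")
    roi_values = np.unique(labels)
    roi_values = roi_values[roi_values != 0]
    if roi_values.size == 0:
        raise ValueError("label volume contains no nonzero labels")
    n_t = functional.shape[3]
    series = np.zeros((roi_values.size, n_t))
    for i, val in enumerate(roi_values):
        sel = labels == val
        if mask is not None:
            sel &= mask
        if not sel.any():
            warnings.warn(
                f"ROI label {val} has no voxels inside the mask; series set to zero",
                stacklevel=2,
            )
            continue
        series[i] = functional[sel].mean(axis=0)
    names = [f"ROI_{int(v)}" for v in roi_values]
    return series, names
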
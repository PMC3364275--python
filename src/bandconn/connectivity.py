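"""Per-band functional connectivity networks (Pearson correlation, Fisher z).

A connectivity network for one subject and one band is the matrix of
pairwise Pearson correlations between the band-limited regional series,
passed through the Fisher r-to-z transform ``z = arctanh(r)`` to normalize
the sampling distribution of the coefficients.  Negative z-weights are kept
in the stored network — they are excluded later, when clustering
coefficients are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import BandSpec
from .signal import bandpass_filter, decompose_bands

__all__ = [
    "ConnectivityNetwork",
    "pearson_matrix",
    "fisher_z",
    "build_networks",
    "FISHER_CLIP",
]

#: correlations are clipped to +/-(1 - FISHER_CLIP) before arctanh so that
#: perfectly correlated pairs stay finite
FISHER_CLIP = 1e-7

FULL_BAND_NAME = "Full"


@dataclass
class ConnectivityNetwork:
    """Symmetric Fisher-z edge-weight matrix over ROIs, one subject, one band.

    The diagonal is fixed at 0: self-connections never enter downstream
    computation.  The Fisher z of a Pearson r estimated from n timepoints is
    approximately normal with standard deviation ``1 / sqrt(n - 3)``, which
    is why ``n_timepoints_used`` is carried along.
    """

    z_matrix: np.ndarray
    band: BandSpec
    subject_id: str
    n_timepoints_used: int

    def __post_init__(self) -> None:
        z = np.asarray(self.z_matrix, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("z_matrix must be square")
        if not np.allclose(z, z.T, atol=1e-12):
            raise ValueError("z_matrix must be symmetric")
        if not np.all(np.isfinite(z)):
            raise ValueError("z_matrix must be finite")
        np.fill_diagonal(z, 0.0)
        self.z_matrix = z

    @property
    def n_rois(self) -> int:
        return self.z_matrix.shape[0]

    def to_tsv(self, directory: str | Path, region_names: list[str]) -> Path:
        path = Path(directory) / f"{self.subject_id}_{self.band.name}.tsv"
        pd.DataFrame(self.z_matrix, index=region_names, columns=region_names).to_csv(
            path, sep="\t", float_format="%.12g"
        )
        return path


def pearson_matrix(ts: np.ndarray) -> np.ndarray:
    """Sample Pearson correlation matrix of an ROIs x timepoints array.

    Zero-variance ROIs (degenerate regions, e.g. fully masked-out) get
    correlation 0 with every other ROI and trigger a warning; the diagonal
    is 1 everywhere.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("expected a 2D ROIs x timepoints array")
    if ts.shape[1] < 3:
        raise ValueError("need at least 3 timepoints for a correlation")
    sd = ts.std(axis=1)
    # relative threshold: a constant series has sd ~ 1e-16 * |mean|, not 0
    scale = np.maximum(np.abs(ts).max(axis=1), 1.0)
    degenerate = sd <= 1e-12 * scale
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance ROI(s); correlations set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ts)
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return (r + r.T) / 2.0


def fisher_z(r_matrix: np.ndarray) -> np.ndarray:
    """Elementwise Fisher transform ``z = arctanh(r) = 0.5 ln((1+r)/(1-r))``.

    ``r`` is clipped to ``+/-(1 - 1e-7)`` first so perfect correlations map
    to a large finite weight; the diagonal is set to 0.  Strictly monotone
    and antisymmetric in r.
    """
    r = np.asarray(r_matrix, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-9):
        raise ValueError("correlations outside [-1, 1]")
    z = np.arctanh(np.clip(r, -(1 - FISHER_CLIP), 1 - FISHER_CLIP))
    if z.ndim == 2 and z.shape[0] == z.shape[1]:
        np.fill_diagonal(z, 0.0)
    return z


def build_networks(
    subject_ts: np.ndarray,
    bands: list[BandSpec],
    tr_seconds: float,
    mode: str = "multi",
    subject_id: str = "",
) -> list[ConnectivityNetwork]:
    """Build a subject's connectivity network(s).

    ``mode="multi"`` decomposes the series into the given bands and returns
    one network per band; ``mode="full"`` band-passes over the union
    interval and returns a single network.
    """
    subject_ts = np.asarray(subject_ts, dtype=float)
    n_t = subject_ts.shape[-1]
    if mode == "multi":
        components = decompose_bands(subject_ts, bands, tr_seconds)
        used_bands = bands
    elif mode == "full":
        lo, hi = bands[0].f_lo, bands[-1].f_hi
        components = [bandpass_filter(subject_ts, lo, hi, tr_seconds)]
        used_bands = [BandSpec(FULL_BAND_NAME, lo, hi)]
    else:
        raise ValueError(f"mode must be 'multi' or 'full', got {mode!r}")
    return [
        ConnectivityNetwork(
            z_matrix=fisher_z(pearson_matrix(comp)),
            band=band,
            subject_id=subject_id,
            n_timepoints_used=n_t,
        )
        for comp, band in zip(components, used_bands)
    ]
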
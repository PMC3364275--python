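"""Weighted clustering coefficients and feature-table assembly.

Each connectivity network is summarized by one number per node: the
weighted local clustering coefficient, a segregation measure quantifying
how strongly a node's neighbours are themselves interconnected.  The
geometric-mean (Onnela-style) weighted form is used:

    C_i = ( sum_{j != h, both != i} (w'_ij w'_ih w'_jh)^(1/3) ) / (k_i (k_i - 1))

where w' are the positive z-weights rescaled by the network's global
maximum (so w' in [0, 1]) and k_i is the number of positive-weight
neighbours of i.  Negative weights are treated as absent edges and do not
contribute to degree; nodes with fewer than two neighbours get C_i = 0.
Rescaling by the per-network maximum makes C invariant to a global scaling
of the weights.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityNetwork

__all__ = ["FeatureTable", "clustering_coefficients", "assemble_features"]


@dataclass
class FeatureTable:
    """Subjects x (band, ROI) clustering-coefficient matrix with labels."""

    matrix: np.ndarray
    feature_names: list[tuple[str, str]]
    labels: np.ndarray
    subject_ids: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2D (subjects x features)")
        if self.matrix.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")
        if self.matrix.shape[0] != len(self.labels) or len(self.subject_ids) != len(self.labels):
            raise ValueError("labels/subject_ids length mismatch")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("features must be finite")
        if np.any(self.matrix < 0):
            raise ValueError("clustering coefficients cannot be negative")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        cols = [f"{band}:{roi}" for band, roi in self.feature_names]
        df = pd.DataFrame(self.matrix, index=self.subject_ids, columns=cols)
        df.insert(0, "label", self.labels)
        df.index.name = "subject_id"
        df.to_csv(path, sep="\t", float_format="%.12g")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        labels = df.pop("label").to_numpy(dtype=int)
        names = [tuple(c.split(":", 1)) for c in df.columns]
        return cls(
            matrix=df.to_numpy(dtype=float),
            feature_names=names,
            labels=labels,
            subject_ids=[str(s) for s in df.index],
        )


def clustering_coefficients(network: ConnectivityNetwork | np.ndarray) -> np.ndarray:
    """Per-node weighted local clustering coefficients of one network.

    Accepts a :class:`ConnectivityNetwork` or a bare symmetric weight
    matrix.  Negative weights and the diagonal are zeroed, the remaining
    weights are rescaled by the global maximum, and the geometric-mean
    triangle intensity around each node is normalized by ``k_i (k_i - 1)``.
    Values lie in [0, 1]; an all-nonpositive network yields all zeros.
    """
    w = network.z_matrix if isinstance(network, ConnectivityNetwork) else np.asarray(network, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(w, w.T, atol=1e-12):
        raise ValueError("weight matrix must be symmetric")
    w = np.where(w > 0, w, 0.0)
    np.fill_diagonal(w, 0.0)
    w_max = w.max()
    n = w.shape[0]
    if w_max == 0:
        return np.zeros(n)
    w_hat = w / w_max
    cube = np.cbrt(w_hat)
    # (cube^3)_ii counts ordered neighbour pairs (j, h); diagonal of cube is
    # zero so j, h != i, and the j == h term vanishes with it
    triangles = np.einsum("ij,jh,hi->i", cube, cube, cube)
    degree = (w_hat > 0).sum(axis=1)
    denom = degree * (degree - 1)
    c = np.zeros(n)
    valid = denom > 0
    c[valid] = triangles[valid] / denom[valid]
    return c


def assemble_features(
    networks_per_subject: list[list[ConnectivityNetwork]],
    labels: np.ndarray,
    region_names: list[str],
    subject_ids: list[str] | None = None,
) -> FeatureTable:
    """Concatenate per-band clustering coefficients into a feature table.

    Features are ordered band-major, ROI-minor: all ROIs of the first band,
    then all ROIs of the second, and so on.  All subjects must carry the
    same bands in the same order.
    """
    if not networks_per_subject:
        raise ValueError("no subjects")
    ref_bands = [net.band for net in networks_per_subject[0]]
    rows = []
    for nets in networks_per_subject:
        if [n.band for n in nets] != ref_bands:
            raise ValueError("subjects carry different band sets")
        rows.append(np.concatenate([clustering_coefficients(n) for n in nets]))
    names = [(band.name, roi) for band in ref_bands for roi in region_names]
    if subject_ids is None:
        subject_ids = [nets[0].subject_id or f"S{i}" for i, nets in enumerate(networks_per_subject)]
    prov = hashlib.sha256(
        repr(([b.name for b in ref_bands], region_names, len(rows))).encode()
    ).hexdigest()[:12]
    return FeatureTable(
        matrix=np.vstack(rows),
        feature_names=names,
        labels=np.asarray(labels),
        subject_ids=list(subject_ids),
        provenance=prov,
    )
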
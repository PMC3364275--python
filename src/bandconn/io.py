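"""Reading and writing cohort time-series files.

On-disk layout of a cohort directory::

    manifest.tsv          subject_id / file / label  (one row per subject)
    cohort.json           {"tr_seconds": ..., "region_names": [...]}
    <subject_id>.tsv      rows = ROIs, first column = region name,
                          remaining columns = timepoints

Values are written with 12 significant digits so a write/read round trip is
lossless at that precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .signal import RegionalTimeSeriesSet

__all__ = ["write_cohort", "read_cohort", "load_nifti"]

MANIFEST_NAME = "manifest.tsv"
SIDECAR_NAME = "cohort.json"
_FLOAT_FMT = "%.12g"


def write_cohort(
    cohort: RegionalTimeSeriesSet, directory: str | Path, overwrite: bool = False
) -> Path:
    """Write a cohort as per-subject TSVs plus a manifest and JSON sidecar.

    Returns the manifest path.  Refuses to clobber an existing manifest
    unless ``overwrite`` is set.
    """
    if cohort.n_subjects == 0:
        raise ValueError("refusing to write an empty cohort")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / MANIFEST_NAME
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace")

    rows = []
    for i, sid in enumerate(cohort.subject_ids):
        fname = f"{sid}.tsv"
        df = pd.DataFrame(cohort.data[i], index=cohort.region_names)
        df.index.name = "region"
        df.to_csv(directory / fname, sep="\t", float_format=_FLOAT_FMT)
        rows.append({"subject_id": sid, "file": fname, "label": int(cohort.labels[i])})
    pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)
    sidecar = {"tr_seconds": cohort.tr_seconds, "region_names": list(cohort.region_names)}
    (directory / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=1))
    return manifest_path


def read_cohort(manifest_path: str | Path) -> RegionalTimeSeriesSet:
    """Read a cohort written by :func:`write_cohort` (or hand-built likewise)."""
    manifest_path = Path(manifest_path)
    directory = manifest_path.parent
    manifest = pd.read_csv(manifest_path, sep="\t")
    sidecar = json.loads((directory / SIDECAR_NAME).read_text())
    data, ids, labels = [], [], []
    region_names: list[str] | None = sidecar.get("region_names")
    for row in manifest.itertuples(index=False):
        df = pd.read_csv(directory / row.file, sep="\t", index_col=0)
        if region_names is None:
            region_names = list(df.index)
        elif list(df.index) != list(region_names):
            raise ValueError(f"subject {row.subject_id}: region names disagree with cohort")
        data.append(df.to_numpy(dtype=float))
        ids.append(str(row.subject_id))
        labels.append(int(row.label))
    if not data:
        raise ValueError(f"manifest {manifest_path} lists no subjects")
    return RegionalTimeSeriesSet(
        subject_ids=ids,
        data=np.stack(data),
        labels=np.asarray(labels),
        region_names=list(region_names or []),
        tr_seconds=float(sidecar["tr_seconds"]),
    )


def load_nifti(path: str | Path) -> np.ndarray:
    """Load a NIfTI volume as a float array (thin nibabel wrapper)."""
    import nibabel as nib

    return np.asanyarray(nib.load(str(path)).dataobj)
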
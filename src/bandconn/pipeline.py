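"""End-to-end orchestration: cohort in, cross-validated classification out.

A :class:`PipelineConfig` captures every analysis choice (band mode, edges,
discard count, feature-pool size, SVM grid, contamination toggle) so a run
is fully reproducible from its config; every output file records the config
hash that produced it.

Band modes
----------
``multi``   five sub-band networks, concatenated features (bands x ROIs);
``full``    one network over the union interval (ROIs features);
``band<k>`` a single sub-band's network (k = 1-based band index).

For tabular cohorts the tissue-masking factor of voxel pipelines cannot be
realized; an additive common-noise contamination toggle stands in for the
"unmasked" condition (a shared nuisance series inflates all correlations).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bands import BandSpec, default_bands, equal_split_bands
from .classify import CVResult, default_grid, fast_grid, nested_loocv
from .cohort import add_common_contamination
from .connectivity import build_networks
from .features import FeatureTable, assemble_features
from .io import read_cohort
from .signal import RegionalTimeSeriesSet, discard_initial_volumes

__all__ = ["PipelineConfig", "run_pipeline", "compare_conditions", "cohort_to_features"]


@dataclass
class PipelineConfig:
    """Declarative description of one classification run."""

    manifest: str = ""
    tr_seconds: float | None = None  # None: take from the cohort sidecar
    n_discard: int = 0
    mode: str = "multi"  # multi | full | band1..bandN
    band_edges: str = "printed"  # printed | equal-split | custom
    custom_bands: list[tuple[str, float, float]] = field(default_factory=list)
    contamination_sd: float = 0.0  # stand-in for the unmasked condition
    top_m: int = 100
    grid: str = "default"  # default | fast
    class_weight: str = "none"  # none | balanced (inverse-frequency SVM weights)
    out_dir: str = "bandconn_out"
    seed: int = 0

    def bands(self) -> list[BandSpec]:
        if self.band_edges == "printed":
            return default_bands()
        if self.band_edges == "equal-split":
            return equal_split_bands()
        if self.band_edges == "custom":
            if not self.custom_bands:
                raise ValueError("band_edges='custom' requires custom_bands")
            return [BandSpec(n, lo, hi) for n, lo, hi in self.custom_bands]
        raise ValueError(f"unknown band_edges {self.band_edges!r}")

    def grid_points(self) -> list[tuple[float, float]]:
        if self.grid == "default":
            return default_grid()
        if self.grid == "fast":
            return fast_grid()
        raise ValueError(f"unknown grid {self.grid!r}")

    def band_index(self) -> int | None:
        """1-based single-band index, or None for multi/full."""
        if self.mode in ("multi", "full"):
            return None
        if self.mode.startswith("band"):
            k = int(self.mode[4:])
            if not 1 <= k <= len(self.bands()):
                raise ValueError(f"band index {k} out of range")
            return k
        raise ValueError(f"unknown mode {self.mode!r}")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self)))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "custom_bands" in raw:
            raw["custom_bands"] = [tuple(b) for b in raw["custom_bands"]]
        return cls(**raw)


def cohort_to_features(
    cohort: RegionalTimeSeriesSet, config: PipelineConfig
) -> tuple[FeatureTable, list[list]]:
    """Discard, (contaminate,) decompose, correlate and featurize a cohort."""
    data = cohort.data
    if config.n_discard:
        data = discard_initial_volumes(data, config.n_discard)
    work = RegionalTimeSeriesSet(
        subject_ids=list(cohort.subject_ids),
        data=data,
        labels=cohort.labels.copy(),
        region_names=list(cohort.region_names),
        tr_seconds=config.tr_seconds or cohort.tr_seconds,
    )
    if config.contamination_sd > 0:
        work = add_common_contamination(work, config.contamination_sd, config.seed)
    bands = config.bands()
    k = config.band_index()
    net_mode = "full" if config.mode == "full" else "multi"
    networks = []
    for i, sid in enumerate(work.subject_ids):
        nets = build_networks(
            work.data[i], bands, work.tr_seconds, mode=net_mode, subject_id=sid
        )
        if k is not None:
            nets = [nets[k - 1]]
        networks.append(nets)
    table = assemble_features(
        networks, work.labels, work.region_names, subject_ids=work.subject_ids
    )
    return table, networks


def run_pipeline(
    config: PipelineConfig,
    cohort: RegionalTimeSeriesSet | None = None,
    write_networks: bool = False,
) -> CVResult:
    """Execute the full pipeline and write report files to ``config.out_dir``.

    ``cohort`` may be passed directly (e.g. a synthetic one); otherwise it
    is read from ``config.manifest``.  Outputs: ``features.tsv``,
    ``cv_result.json``, ``selection_frequency.tsv`` (Band / Region /
    Selected Frequency), ``roc.tsv``, ``run_log.json`` and optionally the
    per-subject network matrices.
    """
    if cohort is None:
        if not config.manifest:
            raise ValueError("config.manifest is empty and no cohort was passed")
        cohort = read_cohort(config.manifest)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    table, networks = cohort_to_features(cohort, config)
    table.to_tsv(out / "features.tsv")
    if write_networks:
        net_dir = out / "networks"
        net_dir.mkdir(exist_ok=True)
        for nets in networks:
            for net in nets:
                net.to_tsv(net_dir, cohort.region_names)

    result = nested_loocv(
        table, grid=config.grid_points(), top_m=config.top_m,
        class_weight=None if config.class_weight == "none" else config.class_weight,
    )

    pd.DataFrame(
        result.selection_frequency, columns=["Band", "Region", "Selected Frequency"]
    ).to_csv(out / "selection_frequency.tsv", sep="\t", index=False)
    pd.DataFrame(result.roc_points, columns=["fpr", "tpr"]).to_csv(
        out / "roc.tsv", sep="\t", index=False, float_format="%.12g"
    )
    (out / "cv_result.json").write_text(
        json.dumps(
            {
                "config_hash": chash,
                "accuracy_percent": result.accuracy,
                "auc": result.auc,
                "per_subject": [
                    {
                        "subject_id": sid,
                        "true_label": int(t),
                        "mean_score": float(sc),
                        "predicted_label": int(p),
                    }
                    for sid, t, sc, p in zip(
                        result.subject_ids,
                        result.true_labels,
                        result.mean_scores,
                        result.predicted_labels,
                    )
                ],
            },
            indent=1,
        )
    )
    (out / "run_log.json").write_text(
        json.dumps(
            {
                "config_hash": chash,
                "config": dataclasses.asdict(config),
                "bandconn_version": __version__,
                "python": platform.python_version(),
                "numpy": np.__version__,
            },
            indent=1,
        )
    )
    return result


def compare_conditions(
    configs: list[PipelineConfig],
    cohort: RegionalTimeSeriesSet | None = None,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Run several configs on the same cohort and tabulate Accuracy / AUC.

    Configs must target the same cohort (identical manifest unless one is
    passed in memory).  Returns a table with columns
    ``Approach / Accuracy / AUC``, one row per config.
    """
    if not configs:
        raise ValueError("no configs")
    if cohort is None and len({c.manifest for c in configs}) != 1:
        raise ValueError("configs target different cohorts")
    if names is None:
        names = [c.mode for c in configs]
    rows = []
    for name, cfg in zip(names, configs):
        res = run_pipeline(cfg, cohort=cohort)
        rows.append({"Approach": name, "Accuracy": res.accuracy, "AUC": res.auc})
    return pd.DataFrame(rows, columns=["Approach", "Accuracy", "AUC"])
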
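"""Cohort manifests, ROI time-series files, feature tables, metrics, config.

File conventions
----------------
* Time series: delimited numeric text, rows = timepoints, columns = regions,
  no header by default (``header=True`` skips one header line).
* Manifest: CSV with header ``subject_id,site_id,label,path``; paths are
  resolved relative to the manifest's directory.
* Features: CSV, one row per subject: ``subject_id,site_id,label,f1..fP``.
* Metrics: JSON keyed by site id.
* Config: YAML (or JSON, a YAML subset) mirroring :class:`RunConfig`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

NC = "NC"
ASD = "ASD"
UNKNOWN = "UNKNOWN"
LABELS = (NC, ASD, UNKNOWN)


def normalize_label(raw: str) -> str:
    """Map a raw label string to NC/ASD (case-insensitive); anything else errors."""
    label = str(raw).strip().upper()
    if label not in (NC, ASD):
        raise ValueError(f"unknown label {raw!r}: expected NC or ASD")
    return label


@dataclass(frozen=True)
class ROITimeSeries:
    """One subject's ROI-averaged BOLD matrix (T timepoints x R regions)."""

    subject_id: str
    site_id: str
    label: str
    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError(
                f"time series must be T x R with T >= 2, R >= 2; got {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("time series contains non-finite values")
        if self.label not in LABELS:
            raise ValueError(f"invalid label {self.label!r}")
        object.__setattr__(self, "data", arr)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class ManifestRecord:
    subject_id: str
    site_id: str
    label: str
    path: Path


@dataclass(frozen=True)
class CohortManifest:
    records: tuple[ManifestRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("no records in manifest")
        ids = [r.subject_id for r in self.records]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValueError(f"duplicate subject_id(s): {', '.join(dupes)}")

    @property
    def site_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.site_id, None)
        return tuple(seen)

    def by_site(self, site_id: str) -> tuple[ManifestRecord, ...]:
        return tuple(r for r in self.records if r.site_id == site_id)


@dataclass
class RunConfig:
    """End-to-end run parameters; all randomness flows from ``rng_seed``."""

    window_length: int = 30
    window_stride: int = 1
    n_regions: int = 116
    encoder_widths: tuple[int, ...] = (512, 128)
    head_widths: tuple[int, ...] = (64,)
    embedding_dim: int = 64
    activation: str = "relu"
    learning_rate: float = 1e-3
    n_iterations: int = 500
    optimizer: str = "adam"
    meta_train_fraction: float = 0.7
    fine_tune_shots_per_class: int = 5
    fine_tune_steps: int = 50
    rng_seed: int = 0
    baseline_site: str = ""
    training_sites: tuple[str, ...] = ()
    affine_head: bool = False
    loss_on_raw_distance: bool = False
    reconstruction_weight: float = 0.0
    fisher_z: bool = False

    def __post_init__(self) -> None:
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")
        if self.window_stride < 1:
            raise ValueError("window_stride must be >= 1")
        if not 0.0 < self.meta_train_fraction < 1.0:
            raise ValueError("meta_train_fraction must be in (0, 1)")
        self.encoder_widths = tuple(int(w) for w in self.encoder_widths)
        self.head_widths = tuple(int(w) for w in self.head_widths)
        self.training_sites = tuple(self.training_sites)


def read_timeseries(
    path: str | Path,
    expected_regions: int,
    *,
    subject_id: str = "",
    site_id: str = "",
    label: str = UNKNOWN,
    header: bool = False,
) -> ROITimeSeries:
    """Load a delimited timepoints-by-regions matrix and validate its shape."""
    path = Path(path)
    try:
        frame = pd.read_csv(
            path,
            header=0 if header else None,
            sep=None,
            engine="python",
            dtype=str,
        )
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"cannot parse time series {path}: {exc}") from exc
    raw = frame.to_numpy()
    data = np.empty(raw.shape, dtype=float)
    for idx, cell in np.ndenumerate(raw):
        try:
            value = float(cell)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: non-numeric cell at row {idx[0] + 1}, column {idx[1] + 1}: {cell!r}"
            ) from None
        if not np.isfinite(value):
            raise ValueError(
                f"{path}: non-finite value at row {idx[0] + 1}, column {idx[1] + 1}"
            )
        data[idx] = value
    if data.shape[1] != expected_regions:
        raise ValueError(
            f"{path}: expected {expected_regions} regions, found {data.shape[1]}"
        )
    return ROITimeSeries(
        subject_id=subject_id or path.stem,
        site_id=site_id,
        label=label,
        data=data,
    )


def write_timeseries(ts: ROITimeSeries, path: str | Path) -> None:
    np.savetxt(path, ts.data, delimiter=",", fmt="%.10g")


def read_manifest(path: str | Path) -> CohortManifest:
    """Read and validate a cohort manifest CSV.

    Referenced time-series paths must exist; labels are normalized and
    anything outside NC/ASD is a hard error naming the offending row.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    required = ["subject_id", "site_id", "label", "path"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"manifest {path} missing column(s): {', '.join(missing)}")
    if len(frame) == 0:
        raise ValueError(f"manifest {path}: no records")
    records = []
    for row_num, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            label = normalize_label(row.label)
        except ValueError as exc:
            raise ValueError(f"manifest {path} row {row_num}: {exc}") from None
        ts_path = Path(row.path)
        if not ts_path.is_absolute():
            ts_path = path.parent / ts_path
        if not ts_path.exists():
            raise ValueError(
                f"manifest {path} row {row_num}: time-series file not found: {ts_path}"
            )
        records.append(
            ManifestRecord(
                subject_id=str(row.subject_id),
                site_id=str(row.site_id),
                label=label,
                path=ts_path,
            )
        )
    return CohortManifest(records=tuple(records))


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    """Write a manifest CSV; time-series paths are stored relative to the
    manifest's own directory so the cohort directory stays relocatable."""
    path = Path(path)
    base = path.parent.resolve()

    def _portable(p: Path) -> str:
        try:
            return str(p.resolve().relative_to(base))
        except ValueError:
            return str(p.resolve())

    frame = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in manifest.records],
            "site_id": [r.site_id for r in manifest.records],
            "label": [r.label for r in manifest.records],
            "path": [_portable(r.path) for r in manifest.records],
        }
    )
    frame.to_csv(path, index=False)


def load_cohort(manifest: CohortManifest, expected_regions: int) -> list[ROITimeSeries]:
    return [
        read_timeseries(
            r.path,
            expected_regions,
            subject_id=r.subject_id,
            site_id=r.site_id,
            label=r.label,
        )
        for r in manifest.records
    ]


def write_features(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-subject feature table (subject_id,site_id,label,f1..fP)."""
    table.to_csv(path, index=False, float_format="%.12g")


def read_features(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    for col in ("subject_id", "site_id", "label"):
        if col not in frame.columns:
            raise ValueError(f"feature table {path} missing column {col!r}")
        frame[col] = frame[col].astype(str)
    frame["label"] = frame["label"].map(normalize_label)
    return frame


def write_metrics(metrics: dict, path: str | Path) -> None:
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")
    with open(path, "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_metrics(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def config_to_dict(config: RunConfig) -> dict:
    out = dataclasses.asdict(config)
    for key in ("encoder_widths", "head_widths", "training_sites"):
        out[key] = list(out[key])
    return out


def write_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def read_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"config {path}: unknown field(s) {sorted(unknown)}")
    return RunConfig(**raw)
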
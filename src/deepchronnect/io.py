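"""Readers, writers and configuration for chronnectome analyses.

Canonical on-disk formats are plain text where possible:

* region time series — TSV with T rows and N columns, header row = node ids,
  or an HDF5 container with one ``T x N`` dataset per run (attrs:
  ``tr_seconds``, ``subject_id``, ``node_ids``);
* node-to-network partition — two-column TSV (node_id, network_label);
* cohort metadata — TSV/CSV with one row per subject.

Time-major orientation (rows = samples) is canonical everywhere.  Inputs are
never transposed heuristically; a column-major file must be transposed by the
caller via the explicit ``transpose=True`` flag.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RoiTimeSeries",
    "NetworkPartition",
    "CohortTable",
    "read_timeseries",
    "write_timeseries",
    "read_runs_hdf5",
    "write_runs_hdf5",
    "read_partition",
    "write_partition",
    "read_cohort",
    "write_cohort",
    "RunConfig",
    "load_config",
    "dump_config",
    "provenance_record",
]


@dataclass
class RoiTimeSeries:
    """One run's region-averaged signals: ``values`` is T samples x N regions."""

    values: np.ndarray
    tr_seconds: float
    node_ids: list[str]
    run_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D matrix (T x N)")
        t, n = self.values.shape
        if t < 2:
            raise ValueError(f"need at least 2 samples, got {t}")
        if n < 2:
            raise ValueError(f"need at least 2 regions, got {n}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"run {self.run_id!r}: time series contains NaN/inf")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        self.node_ids = [str(x) for x in self.node_ids]
        if len(self.node_ids) != n:
            raise ValueError(f"{len(self.node_ids)} node ids for {n} columns")
        if len(set(self.node_ids)) != n:
            raise ValueError("node_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class NetworkPartition:
    """Assignment of every node to exactly one functional network."""

    node_to_network: dict[str, str]
    network_labels: list[str]

    def __post_init__(self) -> None:
        if not self.network_labels:
            raise ValueError("partition needs at least one network")
        used = set(self.node_to_network.values())
        missing = used - set(self.network_labels)
        if missing:
            raise ValueError(f"labels used but not listed: {sorted(missing)}")

    def labels_for(self, node_ids: list[str]) -> list[str]:
        missing = [n for n in node_ids if n not in self.node_to_network]
        if missing:
            raise KeyError(f"nodes missing from partition: {missing}")
        return [self.node_to_network[n] for n in node_ids]

    @property
    def n_networks(self) -> int:
        return len(self.network_labels)


class CohortTable:
    """Per-subject metadata table (sex label, trait scores, age, motion, runs).

    Thin wrapper over a DataFrame indexed by ``subject_id`` with a
    ``run_ids`` column holding comma-separated run identifiers.
    """

    REQUIRED = ("subject_id", "sex", "age", "mean_fd", "run_ids")

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        for col in self.REQUIRED:
            if col not in frame.columns:
                raise ValueError(f"cohort table missing column {col!r}")
        frame["subject_id"] = frame["subject_id"].astype(str)
        if frame["subject_id"].duplicated().any():
            dupes = frame.loc[frame["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValueError(f"duplicate subject ids: {dupes}")
        if not set(frame["sex"].unique()) <= {0, 1}:
            raise ValueError("sex column must be coded 0/1")
        self.frame = frame.reset_index(drop=True)
        run_owner: dict[str, str] = {}
        for _, row in self.frame.iterrows():
            for rid in self.runs_of(row["subject_id"]):
                if rid in run_owner:
                    raise ValueError(
                        f"run {rid!r} assigned to both {run_owner[rid]!r} "
                        f"and {row['subject_id']!r}"
                    )
                run_owner[rid] = row["subject_id"]
        self.run_to_subject = run_owner

    @property
    def subject_ids(self) -> list[str]:
        return self.frame["subject_id"].tolist()

    @property
    def trait_columns(self) -> list[str]:
        reserved = set(self.REQUIRED)
        return [c for c in self.frame.columns if c not in reserved]

    def runs_of(self, subject_id: str) -> list[str]:
        row = self.frame.loc[self.frame["subject_id"] == subject_id]
        if row.empty:
            raise KeyError(subject_id)
        raw = str(row["run_ids"].iloc[0])
        return [r for r in raw.split(",") if r]

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# time series I/O


def read_timeseries(
    path: str | Path,
    tr_seconds: float,
    run_id: str = "",
    subject_id: str = "",
    transpose: bool = False,
) -> RoiTimeSeries:
    """Read a TSV time-series file (T rows x N columns, header = node ids)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:  # malformed structure
        raise ValueError(f"{path}: cannot parse as TSV: {exc}") from exc
    values = frame.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        for ridx in range(len(frame)):
            row = pd.to_numeric(frame.iloc[ridx], errors="coerce")
            if row.isna().any() and not frame.iloc[ridx].isna().any():
                raise ValueError(f"{path}: non-numeric cell in data row {ridx}")
        raise ValueError(f"{path}: non-numeric data")
    if np.isnan(values).any():
        bad = int(np.argwhere(np.isnan(values))[0][0])
        raise ValueError(f"{path}: missing value in data row {bad}")
    if transpose:
        values = values.T
        node_ids = [f"n{k}" for k in range(values.shape[1])]
    else:
        node_ids = [str(c) for c in frame.columns]
    return RoiTimeSeries(values, tr_seconds, node_ids, run_id or path.stem, subject_id)


def write_timeseries(ts: RoiTimeSeries, path: str | Path) -> None:
    """Write a run as TSV, full float precision, header = node ids."""
    frame = pd.DataFrame(ts.values, columns=ts.node_ids)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_runs_hdf5(runs: list[RoiTimeSeries], path: str | Path) -> None:
    """Write runs to an HDF5 container, one dataset per run keyed by run id."""
    with h5py.File(path, "w") as h5:
        for ts in runs:
            ds = h5.create_dataset(ts.run_id, data=ts.values)
            ds.attrs["tr_seconds"] = ts.tr_seconds
            ds.attrs["subject_id"] = ts.subject_id
            ds.attrs["node_ids"] = np.array(ts.node_ids, dtype="S")


def read_runs_hdf5(path: str | Path) -> list[RoiTimeSeries]:
    """Read every run from an HDF5 container written by :func:`write_runs_hdf5`."""
    out = []
    with h5py.File(path, "r") as h5:
        for run_id in h5:
            ds = h5[run_id]
            node_ids = [s.decode() for s in ds.attrs["node_ids"]]
            out.append(
                RoiTimeSeries(
                    values=ds[()],
                    tr_seconds=float(ds.attrs["tr_seconds"]),
                    node_ids=node_ids,
                    run_id=run_id,
                    subject_id=str(ds.attrs["subject_id"]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# partition and cohort I/O


def read_partition(path: str | Path, node_ids: list[str] | None = None) -> NetworkPartition:
    """Read a two-column TSV (node_id, network_label).

    Labels are ordered by first appearance.  If ``node_ids`` is given, every
    listed node must be present; missing nodes raise with their ids.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (node_id, network_label)")
    node_col, label_col = frame.columns[:2]
    if frame[node_col].duplicated().any():
        dupes = frame.loc[frame[node_col].duplicated(), node_col].tolist()
        raise ValueError(f"{path}: duplicate node rows: {dupes}")
    mapping = dict(zip(frame[node_col], frame[label_col]))
    if node_ids is not None:
        missing = [n for n in node_ids if n not in mapping]
        if missing:
            raise ValueError(f"{path}: nodes missing from partition: {missing}")
    labels = list(dict.fromkeys(frame[label_col]))
    return NetworkPartition(mapping, labels)


def write_partition(partition: NetworkPartition, path: str | Path) -> None:
    rows = [(n, l) for n, l in partition.node_to_network.items()]
    pd.DataFrame(rows, columns=["node_id", "network_label"]).to_csv(
        path, sep="\t", index=False
    )


def read_cohort(path: str | Path) -> CohortTable:
    sep = "," if str(path).endswith(".csv") else "\t"
    return CohortTable(pd.read_csv(path, sep=sep))


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    cohort.frame.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Fully resolved analysis configuration with validated defaults.

    Window defaults follow the reference pipeline: 55-sample windows
    (39.6 s at TR = 0.72 s) advanced by 5 samples, multi-scale kernels
    (4, 8, 16), 32 channels per scale, pool 5, two 32-unit LSTM layers.
    """

    # dFC
    window_samples: int = 55
    stride_samples: int = 5
    tr_seconds: float = 0.72
    # model
    conv_kernels: tuple[int, ...] = (4, 8, 16)
    conv_channels: int = 32
    pool_kernel: int = 5
    lstm_hidden: int = 32
    lstm_layers: int = 2
    dropout: float = 0.5
    # training
    batch_size: int = 64
    learning_rate: float = 1e-4
    lr_decay: float = 0.1
    weight_decay: float = 0.0
    max_epochs: int = 10
    patience: int = 3
    n_folds: int = 10
    seed: int = 0
    # surrogate
    n_copies: int = 100

    def __post_init__(self) -> None:
        if self.window_samples < 2:
            raise ValueError(f"window_samples must be >= 2, got {self.window_samples}")
        if self.stride_samples < 1:
            raise ValueError("stride_samples must be >= 1")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        self.conv_kernels = tuple(int(k) for k in self.conv_kernels)
        if any(k < 1 for k in self.conv_kernels) or not self.conv_kernels:
            raise ValueError("conv_kernels must be positive integers")
        for name in ("conv_channels", "pool_kernel", "lstm_hidden", "lstm_layers",
                     "batch_size", "max_epochs", "patience", "n_folds", "n_copies"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 < self.lr_decay <= 1.0:
            raise ValueError("lr_decay must be in (0, 1]")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config; missing keys take defaults, bad values raise."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)


def dump_config(config: RunConfig, path: str | Path) -> None:
    data = asdict(config)
    data["conv_kernels"] = list(config.conv_kernels)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def provenance_record(config: RunConfig, seed: int) -> dict:
    """Reproducibility stamp written next to every CLI output."""
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": int(seed),
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
    }
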
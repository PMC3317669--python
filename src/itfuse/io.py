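"""File I/O: HDF5 epoch containers, CSV trial/feature tables, flat configs.

Epoch files carry datasets ``data`` (trials x channels x samples),
``time_ms`` (or ``time_s``), ``channel_names`` and ``trial_ids``.  Trial
tables and feature tables round-trip through CSV with the column
conventions documented in :mod:`itfuse.containers`.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import EpochArray
from .synthetic import ExperimentConfig

__all__ = [
    "write_epochs",
    "read_epochs",
    "write_trial_table",
    "read_trial_table",
    "save_experiment_config",
    "load_experiment_config",
]


def write_epochs(path, epochs: EpochArray) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("time_ms" if epochs.time_unit == "ms" else "time_s",
                         data=epochs.times)
        f.create_dataset(
            "channel_names",
            data=np.array(epochs.channels, dtype=h5py.string_dtype()),
        )
        f.create_dataset("trial_ids", data=np.asarray(epochs.trial_ids))
        f.attrs["time_unit"] = epochs.time_unit


def read_epochs(path) -> EpochArray:
    with h5py.File(path, "r") as f:
        unit = f.attrs.get("time_unit", "ms")
        times = f["time_ms" if "time_ms" in f else "time_s"][...]
        return EpochArray(
            data=f["data"][...],
            times=times,
            channels=[c.decode() if isinstance(c, bytes) else str(c)
                      for c in f["channel_names"][...]],
            trial_ids=f["trial_ids"][...],
            time_unit=str(unit),
        )


def write_trial_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_experiment_config(path, config: ExperimentConfig) -> None:
    """Flat key=value file; tuples are comma-joined."""
    lines = []
    for f in fields(config):
        v = getattr(config, f.name)
        if f.name in ("electrode_pairs",):
            v = ";".join("/".join(p) for p in v)
        elif isinstance(v, (tuple, list)):
            v = ",".join(str(x) for x in v)
        lines.append(f"{f.name}={v}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_experiment_config(path) -> ExperimentConfig:
    kw = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, raw = line.partition("=")
        key = key.strip()
        raw = raw.strip()
        if key in ("n_subjects", "trials_per_condition", "seed"):
            kw[key] = int(raw)
        elif key in ("sampling_rate_eeg", "tr"):
            kw[key] = float(raw)
        elif key == "session_kind":
            kw[key] = raw
        elif key in ("epoch_window", "iti_choices"):
            kw[key] = tuple(float(x) for x in raw.split(","))
        elif key == "rois":
            kw[key] = tuple(raw.split(","))
        elif key == "electrode_pairs":
            kw[key] = tuple(tuple(p.split("/")) for p in raw.split(";"))
        else:
            raise ValueError(f"unknown config key {key!r}")
    return ExperimentConfig(**kw)
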
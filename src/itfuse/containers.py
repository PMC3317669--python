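"""In-memory containers shared across the pipeline.

``EpochArray`` holds trial-locked multichannel time series (EEG epochs in
microvolts on a millisecond axis, or per-ROI BOLD segments in raw scanner
units on a seconds axis).  Feature tables and trial tables are plain
:class:`pandas.DataFrame` objects with documented column conventions:

Trial table columns
    ``subject, trial, informativeness, prioritization, category, hemifield``
    and, after behaviour simulation, ``rt, decision, responded_within_1s``.

Feature table columns
    ``trial, feature_id, value`` -- one scalar per (trial, feature).
    EEG feature ids are ``"<pair>|w<k>"`` (electrode pair x time-window),
    fMRI feature ids are the ROI label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["EpochArray", "feature_matrix"]


@dataclass
class EpochArray:
    """Trials x channels x samples array with axis metadata."""

    data: np.ndarray
    times: np.ndarray
    channels: list[str]
    trial_ids: np.ndarray = field(default=None)
    time_unit: str = "ms"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"epoch data must be 3-d (trials, channels, samples), got {self.data.shape}"
            )
        n_tr, n_ch, n_t = self.data.shape
        if len(self.channels) != n_ch:
            raise ValueError(f"{len(self.channels)} channel names for {n_ch} channels")
        if self.times.shape != (n_t,):
            raise ValueError(f"time axis length {self.times.shape} != {n_t} samples")
        if self.trial_ids is None:
            self.trial_ids = np.arange(n_tr)
        self.trial_ids = np.asarray(self.trial_ids)
        if self.trial_ids.shape != (n_tr,):
            raise ValueError("trial_ids must have one entry per trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select_trials(self, mask) -> "EpochArray":
        """Subset trials by boolean mask or integer positions."""
        mask = np.asarray(mask)
        return replace(self, data=self.data[mask], trial_ids=self.trial_ids[mask])

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present") from None


def feature_matrix(features: pd.DataFrame, feature_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Pivot a long feature table to (trial_ids, values[n_trials, n_features]).

    Raises if a requested feature id is absent or a (trial, feature) pair is
    duplicated or missing.
    """
    missing = set(feature_ids) - set(features["feature_id"].unique())
    if missing:
        raise KeyError(f"feature ids not present: {sorted(missing)}")
    sub = features[features["feature_id"].isin(feature_ids)]
    wide = sub.pivot(index="trial", columns="feature_id", values="value")
    wide = wide[list(feature_ids)]
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(f"missing feature values for trials {bad[:5]}...")
    return wide.index.to_numpy(), wide.to_numpy(dtype=float)
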
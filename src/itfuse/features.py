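"""Single-trial feature extraction.

EEG epochs are screened for amplitude artifacts, collapsed over hemispheres
onto virtual contralateral channels, and reduced to one scalar per
(electrode pair x time window): the window maximum, except the third window
which spans the negative N140 deflection and contributes the minimum.
BOLD segments are reduced to the maximum percent signal change over the
10 s post-stimulus period relative to a two-volume pre-stimulus baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import EpochArray
from .synthetic import ELECTRODE_PAIRS

__all__ = [
    "TimeWindowSet",
    "ElectrodePairMap",
    "EEG_ONLY_WINDOWS",
    "EEG_FMRI_WINDOWS",
    "default_windows",
    "reject_amplitude_artifacts",
    "pool_contralateral",
    "extract_eeg_features",
    "extract_bold_features",
    "compute_erp",
    "eeg_feature_id",
]


@dataclass(frozen=True)
class TimeWindowSet:
    """Ordered non-overlapping (start_ms, end_ms, polarity) windows covering -100..500 ms."""

    windows: tuple[tuple[float, float, str], ...]
    session_kind: str = "eeg_only"

    def __post_init__(self):
        prev_end = None
        n_min = 0
        for i, (lo, hi, pol) in enumerate(self.windows):
            if lo >= hi:
                raise ValueError(f"window {i} is empty: ({lo}, {hi})")
            if pol not in ("max", "min"):
                raise ValueError(f"window {i} polarity must be 'max' or 'min'")
            if prev_end is not None and lo <= prev_end:
                raise ValueError(f"window {i} overlaps or is out of order")
            prev_end = hi
            n_min += pol == "min"
        if n_min != 1 or self.windows[2][2] != "min":
            raise ValueError("exactly the third window must have polarity 'min'")

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)


EEG_ONLY_WINDOWS = TimeWindowSet(
    (
        (-100.0, 58.0, "max"),
        (60.0, 120.0, "max"),
        (122.0, 154.0, "min"),
        (156.0, 370.0, "max"),
        (372.0, 500.0, "max"),
    ),
    "eeg_only",
)

EEG_FMRI_WINDOWS = TimeWindowSet(
    (
        (-100.0, 58.0, "max"),
        (60.0, 140.0, "max"),
        (142.0, 188.0, "min"),
        (190.0, 400.0, "max"),
        (402.0, 500.0, "max"),
    ),
    "eeg_fmri",
)


def default_windows(session_kind: str) -> TimeWindowSet:
    return {"eeg_only": EEG_ONLY_WINDOWS, "eeg_fmri": EEG_FMRI_WINDOWS}[session_kind]


@dataclass(frozen=True)
class ElectrodePairMap:
    """Bijective left <-> right homologue pairing over the parieto-occipital set."""

    pairs: tuple[tuple[str, str], ...] = ELECTRODE_PAIRS

    def __post_init__(self):
        lefts = [l for l, _ in self.pairs]
        rights = [r for _, r in self.pairs]
        if len(set(lefts)) != len(lefts) or len(set(rights)) != len(rights):
            raise ValueError("electrode pairing must be bijective")
        if set(lefts) & set(rights):
            raise ValueError("an electrode appears on both sides of the pairing")

    def virtual_name(self, left: str, right: str) -> str:
        # "O1"/"O2" -> "O1/2"; fall back to "left|right"
        i = 0
        while i < min(len(left), len(right)) and left[i] == right[i]:
            i += 1
        return f"{left}/{right[i:]}" if i else f"{left}|{right}"


def reject_amplitude_artifacts(
    epochs: EpochArray, low: float = -100.0, high: float = 100.0
) -> np.ndarray:
    """Boolean mask, True where a trial contains any sample outside [low, high].

    Boundary values are inclusive (a sample exactly at the limit is kept):
    only amplitudes strictly outside the physiological range are treated as
    artifacts.
    """
    if low >= high:
        raise ValueError("low must be < high")
    return ((epochs.data < low) | (epochs.data > high)).any(axis=(1, 2))


def pool_contralateral(
    epochs: EpochArray,
    schedule: pd.DataFrame,
    pairs: ElectrodePairMap | None = None,
) -> EpochArray:
    """Collapse hemispheres: one virtual channel per pair, taken contralaterally.

    Left-hemifield trials contribute the right-hemisphere electrode of each
    pair and vice versa, so the pooled channels never mix hemispheres
    within a trial.
    """
    pairs = pairs or ElectrodePairMap()
    sched = schedule.set_index("trial").loc[epochs.trial_ids]
    hemi = sched["hemifield"].to_numpy()
    if not np.isin(hemi, ("left", "right")).all():
        bad = sorted(set(hemi) - {"left", "right"})
        raise ValueError(f"unknown hemifield labels: {bad}")
    missing = [
        name
        for pair in pairs.pairs
        for name in pair
        if name not in epochs.channels
    ]
    if missing:
        raise KeyError(f"channels absent from the epoch array: {missing}")

    use_right = hemi == "left"  # contralateral hemisphere
    out = np.empty((epochs.n_trials, len(pairs.pairs), epochs.data.shape[2]))
    names = []
    for j, (left, right) in enumerate(pairs.pairs):
        li, ri = epochs.channel_index(left), epochs.channel_index(right)
        out[:, j, :] = np.where(use_right[:, None], epochs.data[:, ri, :], epochs.data[:, li, :])
        names.append(pairs.virtual_name(left, right))
    return replace(epochs, data=out, channels=names)


def eeg_feature_id(channel: str, window_index: int) -> str:
    return f"{channel}|w{window_index + 1}"


def extract_eeg_features(epochs: EpochArray, windows: TimeWindowSet) -> pd.DataFrame:
    """Window extrema per trial x channel x window, as a long feature table."""
    t = epochs.times
    rows = []
    for k, (lo, hi, pol) in enumerate(windows):
        if lo < t[0] or hi > t[-1]:
            raise ValueError(f"window ({lo}, {hi}) outside the epoch time axis")
        mask = (t >= lo) & (t <= hi)
        if not mask.any():
            raise ValueError(f"window ({lo}, {hi}) contains no samples")
        seg = epochs.data[:, :, mask]
        val = seg.min(axis=2) if pol == "min" else seg.max(axis=2)
        for j, ch in enumerate(epochs.channels):
            rows.append(
                pd.DataFrame(
                    {
                        "trial": epochs.trial_ids,
                        "feature_id": eeg_feature_id(ch, k),
                        "value": val[:, j],
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def extract_bold_features(
    segments: EpochArray, post_window_s: float = 10.0
) -> pd.DataFrame:
    """Max percent signal change over (0, post_window_s] per trial x ROI.

    PSC(t) = 100 * (x(t) - b) / b with b the mean of the two baseline
    volumes closest to stimulus onset (t <= 0).
    """
    t = segments.times
    base_idx = np.where(t <= 0)[0]
    if len(base_idx) < 2:
        raise ValueError("need >= 2 pre-stimulus volumes per trial")
    base_idx = base_idx[-2:]
    post = (t > 0) & (t <= post_window_s)
    if not post.any():
        raise ValueError("post-stimulus window contains no volumes")
    b = segments.data[:, :, base_idx].mean(axis=2)
    if np.any(b == 0):
        raise ValueError("zero baseline: percent signal change undefined")
    psc = 100.0 * (segments.data - b[:, :, None]) / b[:, :, None]
    val = psc[:, :, post].max(axis=2)
    rows = []
    for j, roi in enumerate(segments.channels):
        rows.append(
            pd.DataFrame(
                {"trial": segments.trial_ids, "feature_id": roi, "value": val[:, j]}
            )
        )
    return pd.concat(rows, ignore_index=True)


def compute_erp(
    epochs: EpochArray,
    schedule: pd.DataFrame,
    by: tuple[str, ...] = ("informativeness",),
    baseline_window: tuple[float, float] = (-100.0, 0.0),
    channels: list[str] | None = None,
) -> pd.DataFrame:
    """Baseline-corrected per-condition average waveform over listed channels.

    Returns a long DataFrame with one row per (condition cell, time point).
    """
    t = epochs.times
    base = (t >= baseline_window[0]) & (t <= baseline_window[1])
    if not base.any():
        raise ValueError("baseline window outside the epoch")
    chan_idx = (
        [epochs.channel_index(c) for c in channels]
        if channels is not None
        else list(range(len(epochs.channels)))
    )
    corrected = epochs.data - epochs.data[:, :, base].mean(axis=2, keepdims=True)
    pooled = corrected[:, chan_idx, :].mean(axis=1)  # trials x time

    sched = schedule.set_index("trial").loc[epochs.trial_ids]
    out = []
    for cell, grp in sched.groupby(list(by), observed=False):
        cell = cell if isinstance(cell, tuple) else (cell,)
        rows = np.isin(epochs.trial_ids, grp.index.to_numpy())
        if not rows.any():
            raise ValueError(f"condition cell {cell} has no trials")
        wave = pooled[rows].mean(axis=0)
        df = pd.DataFrame({"time_ms": t, "amplitude": wave, "n_trials": rows.sum()})
        for name, lev in zip(by, cell):
            df[name] = lev
        out.append(df)
    return pd.concat(out, ignore_index=True)
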
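"""Synthetic single-trial EEG / BOLD / behaviour generator.

Emulates a 2x2 within-subject perceptual-decision experiment (factors:
stimulus informativeness high/low and spatial prioritization yes/no, with
orthogonal stimulus category face/car and presentation hemifield left/right).
Every generator is a pure function of its inputs and a seed, and returns the
injected ground truth alongside the signals so that downstream feature
extraction and information estimation can be validated by injection
recovery: with all noise terms at zero, extracted features equal the
injected amplitudes exactly.

Model summary
-------------
EEG epochs
    Baseline-zero voltage plus three event-related components (P100, N140,
    P300) modelled as Gaussian bumps truncated at +/-3 sigma, carried only
    by the electrodes contralateral to the stimulated hemifield.  Per-trial
    component amplitude = condition mean + Gaussian amplitude jitter;
    additive white (optionally 1/f-coloured) sensor noise per sample.
BOLD series
    Per-ROI time course at TR resolution: constant baseline of 100 units
    scaled by a gamma-shaped haemodynamic kernel (peak ~6 s, truncated at
    8 s where the response has returned to baseline) times the trial
    amplitude in percent-signal-change units, plus Gaussian noise.  Events
    are spaced by inter-trial intervals drawn from {10, 12} s.
Behaviour
    Response time = shift + Gamma(shape, scale) with condition-dependent
    mean (faster for high-informative and prioritized trials) and an
    optional coupling to the latent single-trial P300 amplitude; a
    ``nonresponse_rate`` fraction of trials receives RT > 1000 ms.
    Decisions are correct with condition-dependent probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._streams import substream
from .containers import EpochArray

__all__ = [
    "ExperimentConfig",
    "EffectSpec",
    "ERPComponent",
    "BoldRun",
    "ELECTRODE_PAIRS",
    "DEFAULT_ROIS",
    "make_trial_schedule",
    "simulate_eeg_epochs",
    "simulate_bold_series",
    "simulate_behaviour",
    "simulate_subject",
]

#: Left/right parieto-occipital homologue pairs used throughout.
ELECTRODE_PAIRS: tuple[tuple[str, str], ...] = (
    ("O1", "O2"),
    ("PO3", "PO4"),
    ("PO7", "PO8"),
    ("P1", "P2"),
    ("P3", "P4"),
    ("P5", "P6"),
    ("P7", "P8"),
    ("TP7", "TP8"),
)

#: ROI labels ordered along an approximate occipital -> frontal gradient.
DEFAULT_ROIS: tuple[str, ...] = (
    "V1", "V2", "LO", "CU", "FF", "PL", "PR", "PC", "AC", "IN", "FL", "FR", "SF",
)

FACTOR_CELLS = [("high", "yes"), ("high", "no"), ("low", "yes"), ("low", "no")]


@dataclass(frozen=True)
class ExperimentConfig:
    """Acquisition-level parameters of a simulated session."""

    n_subjects: int = 13
    trials_per_condition: int = 90
    session_kind: str = "eeg_fmri"  # or "eeg_only"
    sampling_rate_eeg: float = 500.0  # Hz
    epoch_window: tuple[float, float] = (-100.0, 500.0)  # ms
    tr: float = 2.0  # seconds
    iti_choices: tuple[float, ...] = (10.0, 12.0)  # seconds
    rois: tuple[str, ...] = DEFAULT_ROIS
    electrode_pairs: tuple[tuple[str, str], ...] = ELECTRODE_PAIRS
    seed: int = 0

    def __post_init__(self):
        if self.trials_per_condition <= 0:
            raise ValueError("trials_per_condition must be > 0")
        if self.session_kind not in ("eeg_only", "eeg_fmri"):
            raise ValueError(f"unknown session_kind {self.session_kind!r}")
        if self.epoch_window[0] >= self.epoch_window[1]:
            raise ValueError("epoch_window must be an increasing interval")
        if len(self.iti_choices) == 0:
            raise ValueError("iti_choices must be nonempty")

    @classmethod
    def eeg_only(cls, **kw) -> "ExperimentConfig":
        kw.setdefault("trials_per_condition", 72)
        return cls(session_kind="eeg_only", **kw)

    @property
    def times_ms(self) -> np.ndarray:
        dt = 1000.0 / self.sampling_rate_eeg
        lo, hi = self.epoch_window
        return np.arange(lo, hi + dt / 2, dt)

    @property
    def channels(self) -> list[str]:
        return [name for pair in self.electrode_pairs for name in pair]


@dataclass(frozen=True)
class ERPComponent:
    """A truncated-Gaussian evoked component: amp * exp(-(t-mu)^2/2s^2) within 3 sigma."""

    name: str
    latency_ms: float
    sigma_ms: float
    base_amplitude_uv: float  # signed; negative for the N140

    def waveform(self, times_ms: np.ndarray) -> np.ndarray:
        z = (times_ms - self.latency_ms) / self.sigma_ms
        w = np.exp(-0.5 * z**2)
        w[np.abs(z) > 3.0] = 0.0
        return w


# Component latencies sit on the 2 ms sample grid and their +/-3 sigma support
# lies strictly inside the session's corresponding analysis window, so the
# noise-free window extremum equals the injected amplitude exactly.
_COMPONENTS = {
    "eeg_only": (
        ERPComponent("p100", 100.0, 6.5, 5.0),
        ERPComponent("n140", 140.0, 4.4, -3.0),
        ERPComponent("p300", 270.0, 30.0, 6.0),
    ),
    "eeg_fmri": (
        ERPComponent("p100", 100.0, 6.5, 5.0),
        ERPComponent("n140", 164.0, 7.0, -3.0),
        ERPComponent("p300", 290.0, 30.0, 6.0),
    ),
}


@dataclass(frozen=True)
class EffectSpec:
    """Injected condition effects and noise levels.

    Units: EEG amplitudes in microvolts, BOLD in percent signal change,
    response times in milliseconds.  ``bold_effect_deltas`` maps ROI ->
    factor -> delta, where the delta is added to the trial amplitude when
    informativeness == "low", prioritization == "yes" or category ==
    "face" respectively (matching the directions reported for e.g. insula,
    cuneus and fusiform responses).
    """

    p100_prioritization_delta: float = 1.5
    p300_informativeness_delta: float = 2.5
    bold_effect_deltas: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "CU": {"prioritization": 0.3},
            "IN": {"informativeness": 0.4},
            "FF": {"category": 0.4},
            "SF": {"category": 0.3},
        }
    )
    bold_base_amplitude: float = 0.8  # % signal change
    rt_informativeness_delta: float = 55.0  # ms, low slower
    rt_prioritization_delta: float = 30.0  # ms, non-prioritized slower
    accuracy_by_condition: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("high", "yes"): 0.95,
            ("high", "no"): 0.93,
            ("low", "yes"): 0.87,
            ("low", "no"): 0.85,
        }
    )
    nonresponse_rate: float = 0.108
    noise_sd_eeg: float = 3.0  # microvolt per sample
    noise_sd_bold: float = 0.2  # % signal change per volume
    amplitude_jitter_sd: float = 1.0  # trial-to-trial ERP amplitude SD, uV
    bold_jitter_sd: float = 0.15  # trial-to-trial BOLD amplitude SD, %
    rt_base_ms: float = 400.0
    rt_shift_ms: float = 150.0
    rt_shape: float = 4.0
    rt_amplitude_coupling: float = 25.0  # ms per SD of latent P300 amplitude
    pink_noise: bool = False

    def __post_init__(self):
        for p in (self.nonresponse_rate, *self.accuracy_by_condition.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for sd in (self.noise_sd_eeg, self.noise_sd_bold, self.amplitude_jitter_sd,
                   self.bold_jitter_sd):
            if sd < 0:
                raise ValueError("noise SDs must be >= 0")

    @classmethod
    def null(cls, **kw) -> "EffectSpec":
        """All condition effects zero (noise levels retained unless overridden)."""
        kw.setdefault("p100_prioritization_delta", 0.0)
        kw.setdefault("p300_informativeness_delta", 0.0)
        kw.setdefault("bold_effect_deltas", {})
        kw.setdefault("rt_informativeness_delta", 0.0)
        kw.setdefault("rt_prioritization_delta", 0.0)
        kw.setdefault("rt_amplitude_coupling", 0.0)
        kw.setdefault(
            "accuracy_by_condition",
            {cell: 0.5 for cell in FACTOR_CELLS},
        )
        return cls(**kw)


def make_trial_schedule(config: ExperimentConfig, subject: int = 0) -> pd.DataFrame:
    """Randomized trial table for one subject of the 2x2 factorial design.

    Each (informativeness, prioritization) cell receives
    ``trials_per_condition`` trials, half faces and half cars, with
    hemifields balanced within the cell.  When ``trials_per_condition`` is
    divisible by 4 the category x hemifield sub-cells are fully crossed;
    otherwise (e.g. the 90-trial EEG-fMRI sessions) the odd split alternates
    deterministically so that both margins stay exactly balanced.
    """
    tpc = config.trials_per_condition
    if tpc % 2:
        raise ValueError(
            f"trials_per_condition={tpc} is not divisible by 2 "
            "(cannot balance faces/cars within a condition cell)"
        )
    rows = []
    for ci, (info, prio) in enumerate(FACTOR_CELLS):
        for cat_i, category in enumerate(("face", "car")):
            n_cat = tpc // 2
            if n_cat % 2 == 0:
                n_left = n_cat // 2
            else:
                # alternate the extra left-hemifield trial between categories
                n_left = n_cat // 2 + ((ci + cat_i) % 2)
            hemis = ["left"] * n_left + ["right"] * (n_cat - n_left)
            for hemi in hemis:
                rows.append((subject, info, prio, category, hemi))
    table = pd.DataFrame(
        rows,
        columns=["subject", "informativeness", "prioritization", "category", "hemifield"],
    )
    rng = substream(config.seed, "schedule", subject)
    table = table.iloc[rng.permutation(len(table))].reset_index(drop=True)
    table.insert(1, "trial", np.arange(len(table)))
    return table


def _eeg_noise(rng: np.random.Generator, shape: tuple, sd: float, pink: bool) -> np.ndarray:
    if sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    if not pink:
        return sd * white
    # 1/f colouring via spectral shaping along the time axis
    n_t = shape[-1]
    freqs = np.fft.rfftfreq(n_t, d=1.0)
    gain = np.where(freqs > 0, 1.0 / np.sqrt(freqs), 0.0)
    gain[0] = gain[1] if len(gain) > 1 else 0.0
    coloured = np.fft.irfft(np.fft.rfft(white, axis=-1) * gain, n=n_t, axis=-1)
    coloured /= coloured.std() if coloured.std() > 0 else 1.0
    return sd * coloured


def simulate_eeg_epochs(
    schedule: pd.DataFrame,
    effects: EffectSpec,
    config: ExperimentConfig,
    subject: int | None = None,
) -> tuple[EpochArray, pd.DataFrame]:
    """Simulate EEG epochs; returns (epochs, ground-truth amplitude table).

    The evoked components are carried only by electrodes contralateral to
    the trial's hemifield (even-numbered electrodes for left-hemifield
    stimuli).  The amplitude table has one row per trial with columns
    ``p100, n140, p300`` holding the signed per-trial component amplitudes.
    """
    if effects.noise_sd_eeg < 0:
        raise ValueError("noise_sd_eeg must be >= 0")
    subject = int(schedule["subject"].iloc[0]) if subject is None else subject
    rng = substream(config.seed, "eeg", subject)
    times = config.times_ms
    channels = config.channels
    comps = _COMPONENTS[config.session_kind]
    n_trials = len(schedule)

    deltas = {
        "p100": ("prioritization", "yes", effects.p100_prioritization_delta),
        "n140": (None, None, 0.0),
        "p300": ("informativeness", "low", effects.p300_informativeness_delta),
    }
    amp = {}
    for comp in comps:
        factor, level, delta = deltas[comp.name]
        mean = np.full(n_trials, comp.base_amplitude_uv)
        if factor is not None and delta:
            sign = np.sign(comp.base_amplitude_uv) or 1.0
            mean = mean + sign * delta * (schedule[factor] == level).to_numpy()
        jitter = effects.amplitude_jitter_sd * rng.standard_normal(n_trials)
        amp[comp.name] = mean + np.sign(comp.base_amplitude_uv) * jitter

    right_chans = np.array([i % 2 == 1 for i in range(len(channels))])
    contra_right = (schedule["hemifield"] == "left").to_numpy()  # left stim -> right hemisphere

    data = _eeg_noise(rng, (n_trials, len(channels), len(times)), effects.noise_sd_eeg,
                      effects.pink_noise)
    evoked = np.zeros((n_trials, len(times)))
    for comp in comps:
        evoked += amp[comp.name][:, None] * comp.waveform(times)[None, :]
    carrier = np.where(contra_right[:, None], right_chans[None, :], ~right_chans[None, :])
    data += carrier[:, :, None] * evoked[:, None, :]

    epochs = EpochArray(data, times, channels, trial_ids=schedule["trial"].to_numpy())
    truth = pd.DataFrame({"trial": schedule["trial"].to_numpy(), **amp})
    return epochs, truth


def hrf_kernel(tr: float, support_s: float = 8.0, shape: float = 6.0) -> np.ndarray:
    """Gamma-density haemodynamic kernel sampled at TR, peak-normalized on the grid.

    The kernel is truncated at ``support_s`` (the simulated response has
    returned to baseline by 8 s post-stimulus) and scaled so its maximum on
    the TR grid is exactly 1, making noise-free peak amplitudes recoverable
    without interpolation.
    """
    if tr <= 0:
        raise ValueError("tr must be > 0")
    t = np.arange(0.0, support_s, tr)
    k = sps.gamma.pdf(t, a=shape, scale=1.0)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate HRF kernel")
    return k / peak


@dataclass
class BoldRun:
    """Continuous per-ROI series plus trial-locked segments and ground truth."""

    series: np.ndarray  # (n_rois, n_volumes), raw units (baseline 100)
    vol_times: np.ndarray  # seconds
    onsets: np.ndarray  # stimulus onset per trial, seconds
    itis: np.ndarray  # inter-trial intervals actually drawn, seconds
    segments: EpochArray  # trials x ROIs x segment volumes, times in s rel. onset
    amplitudes: pd.DataFrame  # trial x ROI ground-truth % signal change


def simulate_bold_series(
    schedule: pd.DataFrame,
    effects: EffectSpec,
    config: ExperimentConfig,
    subject: int | None = None,
) -> BoldRun:
    """Simulate per-ROI BOLD time courses for the trial schedule."""
    if config.tr <= 0:
        raise ValueError("tr must be > 0")
    if len(config.iti_choices) == 0:
        raise ValueError("iti_choices must be nonempty")
    subject = int(schedule["subject"].iloc[0]) if subject is None else subject
    rng = substream(config.seed, "bold", subject)
    tr = config.tr
    rois = list(config.rois)
    n_trials = len(schedule)

    itis = rng.choice(np.asarray(config.iti_choices, dtype=float), size=n_trials - 1)
    onsets = np.empty(n_trials)
    onsets[0] = 20.0
    if n_trials > 1:
        onsets[1:] = onsets[0] + np.cumsum(itis)
    total = onsets[-1] + 20.0
    vol_times = np.arange(0.0, total, tr)
    kernel = hrf_kernel(tr)

    effect_levels = {"informativeness": "low", "prioritization": "yes", "category": "face"}
    amps = np.empty((n_trials, len(rois)))
    for j, roi in enumerate(rois):
        mean = np.full(n_trials, effects.bold_base_amplitude)
        for factor, delta in effects.bold_effect_deltas.get(roi, {}).items():
            mean = mean + delta * (schedule[factor] == effect_levels[factor]).to_numpy()
        amps[:, j] = mean + effects.bold_jitter_sd * rng.standard_normal(n_trials)

    baseline = 100.0
    series = np.full((len(rois), len(vol_times)), baseline)
    onset_vols = np.rint(onsets / tr).astype(int)
    for i in range(n_trials):
        sl = slice(onset_vols[i], min(onset_vols[i] + len(kernel), len(vol_times)))
        n_k = sl.stop - sl.start
        series[:, sl] += baseline * (amps[i][:, None] / 100.0) * kernel[None, :n_k]
    if effects.noise_sd_bold > 0:
        series = series + effects.noise_sd_bold * rng.standard_normal(series.shape)

    seg_offsets = np.arange(-2, 6)  # volumes relative to onset: -4 ... +10 s at TR 2
    seg_times = seg_offsets * tr
    seg = np.empty((n_trials, len(rois), len(seg_offsets)))
    for i in range(n_trials):
        idx = onset_vols[i] + seg_offsets
        if idx[0] < 0 or idx[-1] >= len(vol_times):
            raise ValueError(f"trial {i} segment exceeds the simulated run")
        seg[i] = series[:, idx]
    segments = EpochArray(seg, seg_times, rois, trial_ids=schedule["trial"].to_numpy(),
                          time_unit="s")
    amplitudes = pd.DataFrame(amps, columns=rois)
    amplitudes.insert(0, "trial", schedule["trial"].to_numpy())
    return BoldRun(series, vol_times, onsets, itis, segments, amplitudes)


def simulate_behaviour(
    schedule: pd.DataFrame,
    effects: EffectSpec,
    latent_amplitudes: pd.DataFrame | None = None,
    config: ExperimentConfig | None = None,
    subject: int | None = None,
) -> pd.DataFrame:
    """Append rt / decision / responded_within_1s columns to the schedule.

    RT ~ shift + Gamma(shape, scale) with mean ``rt_base + deltas`` per
    condition, optionally shifted by the standardized latent single-trial
    P300 amplitude (``rt_amplitude_coupling`` ms per SD, larger P300 ->
    slower, mirroring the difficulty covariation).  A ``nonresponse_rate``
    fraction of trials receives RT > 1000 ms and is flagged accordingly.
    """
    seed = config.seed if config is not None else 0
    subject = int(schedule["subject"].iloc[0]) if subject is None else subject
    rng = substream(seed, "behaviour", subject)
    n = len(schedule)
    if latent_amplitudes is not None and len(latent_amplitudes) != n:
        raise ValueError("latent amplitude rows do not align with the schedule")

    mu = np.full(n, effects.rt_base_ms)
    mu += effects.rt_informativeness_delta * (schedule["informativeness"] == "low").to_numpy()
    mu += effects.rt_prioritization_delta * (schedule["prioritization"] == "no").to_numpy()
    if latent_amplitudes is not None and effects.rt_amplitude_coupling:
        a = latent_amplitudes["p300"].to_numpy(dtype=float)
        sd = a.std()
        if sd > 0:
            mu = mu + effects.rt_amplitude_coupling * (a - a.mean()) / sd
    scale = np.maximum(mu - effects.rt_shift_ms, 1.0) / effects.rt_shape
    rt = effects.rt_shift_ms + rng.gamma(effects.rt_shape, scale)
    # responding trials follow the Gamma truncated at the 1 s deadline, so the
    # non-response fraction is exactly nonresponse_rate in the long run
    for _ in range(1000):
        over = rt > 1000.0
        if not over.any():
            break
        rt[over] = effects.rt_shift_ms + rng.gamma(effects.rt_shape, scale[over])

    nonresp = rng.random(n) < effects.nonresponse_rate
    rt = np.where(nonresp, 1000.0 + rng.exponential(250.0, size=n), rt)

    acc = np.empty(n)
    for (info, prio), p in effects.accuracy_by_condition.items():
        cell = (schedule["informativeness"] == info) & (schedule["prioritization"] == prio)
        acc[cell.to_numpy()] = p
    correct = rng.random(n) < acc
    other = np.where(schedule["category"] == "face", "car", "face")
    decision = np.where(correct, schedule["category"], other)

    out = schedule.copy()
    out["rt"] = rt
    out["decision"] = decision
    out["responded_within_1s"] = rt <= 1000.0
    return out


def simulate_subject(
    config: ExperimentConfig,
    effects: EffectSpec,
    subject: int = 0,
) -> dict:
    """Full single-subject simulation bundle used by the pipeline."""
    schedule = make_trial_schedule(config, subject)
    epochs, truth = simulate_eeg_epochs(schedule, effects, config, subject)
    out = {"schedule": schedule, "epochs": epochs, "erp_truth": truth}
    if config.session_kind == "eeg_fmri":
        out["bold"] = simulate_bold_series(schedule, effects, config, subject)
    out["schedule"] = simulate_behaviour(schedule, effects, truth, config, subject)
    return out
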
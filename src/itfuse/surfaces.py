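"""Aggregation into temporal / spatial profiles and spatiotemporal surfaces.

Per-subject bias-corrected MI estimates (one per electrode pair x time
window for EEG, per ROI for fMRI, per window x ROI for the joint features)
are averaged over the electrode pairs *after* bias correction, then
averaged over subjects with the standard error of the mean, and finally
arranged on a time-window x ROI grid ordered along an early -> late and
occipital -> frontal gradient.  ``run_pipeline`` orchestrates the whole
chain on simulated data: simulate -> extract -> estimate -> correct ->
aggregate -> surfaces for the five variables of interest (informativeness,
category, prioritization, response time, decision).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._streams import subseed
from .bias import NullModelSpec, corrected_mi
from .features import (
    default_windows,
    eeg_feature_id,
    extract_bold_features,
    extract_eeg_features,
    pool_contralateral,
    reject_amplitude_artifacts,
    ElectrodePairMap,
)
from .histmi import BinningSpec, mi_about_behaviour, mi_about_stimulus, STIMULUS_VARIABLES
from .synthetic import (
    DEFAULT_ROIS,
    ELECTRODE_PAIRS,
    EffectSpec,
    ExperimentConfig,
    simulate_subject,
)

__all__ = [
    "InfoSurface",
    "PipelineConfig",
    "PipelineResult",
    "aggregate_electrodes",
    "group_average",
    "build_information_surface",
    "run_pipeline",
]

ALL_VARIABLES = ("informativeness", "category", "prioritization", "rt", "decision")


@dataclass
class InfoSurface:
    """Group-mean corrected information (bits) on a window x ROI grid with SEM."""

    values: np.ndarray  # (n_windows, n_rois)
    sem: np.ndarray
    windows: list[int]  # early -> late window indices (1-based)
    rois: list[str]  # occipital -> frontal
    n_subjects: int
    variable: str = ""

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.rois)
        df.insert(0, "window", self.windows)
        return df

    def argmax_cell(self) -> tuple[int, str]:
        """(window index (1-based), ROI label) of the grid maximum."""
        w, r = np.unravel_index(np.argmax(self.values), self.values.shape)
        return self.windows[w], self.rois[r]


def aggregate_electrodes(estimates: pd.DataFrame) -> pd.DataFrame:
    """Average estimates over electrode pairs, after bias correction.

    Input rows carry an ``electrode`` column; all other identifying columns
    are kept as grouping keys.  Electrode sets must agree across subjects
    for each remaining cell.
    """
    if "electrode" not in estimates.columns:
        raise ValueError("estimates have no 'electrode' column")
    value_cols = [c for c in ("naive", "pt_bias", "shuffle_mean", "null_mean", "corrected")
                  if c in estimates.columns]
    keys = [c for c in estimates.columns if c not in value_cols + ["electrode", "n_bins"]]

    cell_keys = [k for k in keys if k != "subject"]
    if cell_keys:
        for _, grp in estimates.groupby(cell_keys, dropna=False, observed=True):
            per_subj = grp.groupby("subject")["electrode"].agg(frozenset)
            if per_subj.nunique() > 1:
                raise ValueError("electrode sets are inconsistent across subjects")
    return estimates.groupby(keys, dropna=False, observed=True, as_index=False)[value_cols].mean()


def group_average(estimates: pd.DataFrame, value: str = "corrected") -> pd.DataFrame:
    """Across-subject mean and SEM (SD/sqrt(n)) per cell."""
    keys = [
        c
        for c in estimates.columns
        if c not in ("subject", "naive", "pt_bias", "shuffle_mean", "null_mean",
                     "corrected", "n_bins")
    ]
    grouped = estimates.groupby(keys, dropna=False, observed=True)[value]
    out = grouped.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count").reset_index()
    if (out["n"] < 2).any():
        raise ValueError("group SEM undefined: fewer than 2 subjects in a cell")
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out.drop(columns="sd")


def build_information_surface(
    group: pd.DataFrame,
    variable: str,
    windows: list[int] | None = None,
    rois: list[str] | None = None,
) -> InfoSurface:
    """Arrange group-mean joint estimates on the window x ROI grid."""
    sub = group[(group.get("variable") == variable) & (group["roi"].notna())
                & (group["window"].notna())]
    windows = windows or sorted(sub["window"].unique())
    rois = rois or [r for r in DEFAULT_ROIS if r in set(sub["roi"])]
    values = np.full((len(windows), len(rois)), np.nan)
    sem = np.full_like(values, np.nan)
    n_subjects = 0
    lookup = sub.set_index(["window", "roi"])
    missing = []
    for i, w in enumerate(windows):
        for j, r in enumerate(rois):
            if (w, r) not in lookup.index:
                missing.append((w, r))
                continue
            row = lookup.loc[(w, r)]
            values[i, j] = row["mean"]
            sem[i, j] = row["sem"]
            n_subjects = int(row["n"])
    if missing:
        raise ValueError(f"missing surface cells: {missing}")
    return InfoSurface(values, sem, list(windows), list(rois), n_subjects, variable)


@dataclass
class PipelineConfig:
    """End-to-end run settings (simulation + estimation + aggregation)."""

    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    effects: EffectSpec = field(default_factory=EffectSpec)
    variables: tuple[str, ...] = ALL_VARIABLES
    include_marginals: bool = True
    include_joint: bool = True
    n_sim: int = 1000
    n_perm: int = 1000
    correction_mode: str = "parametric"
    artifact_limits: tuple[float, float] = (-100.0, 100.0)

    @property
    def seed(self) -> int:
        return self.experiment.seed


@dataclass
class PipelineResult:
    estimates: pd.DataFrame  # per subject x electrode x window x roi
    aggregated: pd.DataFrame  # electrode-averaged, per subject
    group: pd.DataFrame  # group mean +- SEM per cell
    surfaces: dict  # variable -> InfoSurface (joint features only)
    manifest: dict

    def write(self, outdir, plots: bool = False) -> None:
        """Write CSV/JSON outputs (and optional PNG heatmaps) under ``outdir``."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.estimates.to_csv(outdir / "estimates.csv", index=False)
        self.aggregated.to_csv(outdir / "estimates_electrode_averaged.csv", index=False)
        self.group.to_csv(outdir / "group_estimates.csv", index=False)
        for var, surf in self.surfaces.items():
            surf.to_frame().to_csv(outdir / f"surface_{var}.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        if plots:
            for var, surf in self.surfaces.items():
                _plot_surface(surf, outdir / f"surface_{var}.png")


def _plot_surface(surf: InfoSurface, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.2))
    im = ax.imshow(surf.values, aspect="auto", origin="lower", cmap="viridis")
    ax.set_xticks(range(len(surf.rois)), surf.rois, rotation=90)
    ax.set_yticks(range(len(surf.windows)), [f"w{w}" for w in surf.windows])
    ax.set_xlabel("ROI (occipital → frontal)")
    ax.set_ylabel("time window (early → late)")
    ax.set_title(f"I(bits): {surf.variable}")
    fig.colorbar(im, ax=ax, label="corrected MI (bits)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _estimate(problem, cfg: PipelineConfig, *keys) -> dict:
    spec = NullModelSpec(
        n_sim=cfg.n_sim,
        n_perm=cfg.n_perm,
        seed=subseed(cfg.seed, "estimate", *keys),
        mode=cfg.correction_mode,
    )
    return corrected_mi(problem, spec).as_row()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Simulate, extract, estimate, correct and aggregate for all variables.

    Fully reproducible from (config, seed).  Stage failures propagate with
    a stage-named message.
    """
    cfg = config
    exp = cfg.experiment
    pairs = ElectrodePairMap(exp.electrode_pairs)
    windows = default_windows(exp.session_kind)
    has_fmri = exp.session_kind == "eeg_fmri"
    rows = []

    for s in range(exp.n_subjects):
        try:
            sim = simulate_subject(exp, cfg.effects, subject=s)
            schedule = sim["schedule"]
            rejected = reject_amplitude_artifacts(sim["epochs"], *cfg.artifact_limits)
            kept = sim["epochs"].select_trials(~rejected)
            pooled = pool_contralateral(kept, schedule, pairs)
            eeg_feats = extract_eeg_features(pooled, windows)
            bold_feats = (
                extract_bold_features(sim["bold"].segments.select_trials(~rejected))
                if has_fmri
                else None
            )
        except Exception as err:
            raise RuntimeError(f"[simulate/extract] subject {s}: {err}") from err

        feats = (
            pd.concat([eeg_feats, bold_feats], ignore_index=True)
            if bold_feats is not None
            else eeg_feats
        )
        sched = schedule[np.isin(schedule["trial"].to_numpy(), kept.trial_ids)]

        def estimate_for(variable: str, feature_ids, electrode, window, roi):
            make = mi_about_stimulus if variable in STIMULUS_VARIABLES else mi_about_behaviour
            try:
                problem = make(feats, sched, variable, feature_ids)
                row = _estimate(problem, cfg, s, variable, *feature_ids)
            except Exception as err:
                raise RuntimeError(f"[estimate] subject {s}, {variable}, {feature_ids}: {err}") from err
            row.update(subject=s, variable=variable, electrode=electrode, window=window, roi=roi)
            rows.append(row)

        for variable in cfg.variables:
            for e, (left, right) in enumerate(pairs.pairs):
                name = pairs.virtual_name(left, right)
                for w in range(len(windows)):
                    fid = eeg_feature_id(name, w)
                    if cfg.include_marginals:
                        estimate_for(variable, [fid], name, w + 1, None)
                    if cfg.include_joint and has_fmri:
                        for roi in exp.rois:
                            estimate_for(variable, [fid, roi], name, w + 1, roi)
            if cfg.include_marginals and has_fmri:
                for roi in exp.rois:
                    estimate_for(variable, [roi], None, None, roi)

    estimates = pd.DataFrame(rows)
    with_elec = estimates[estimates["electrode"].notna()]
    without = estimates[estimates["electrode"].isna()].drop(columns="electrode")
    aggregated = aggregate_electrodes(with_elec)
    if len(without):
        aggregated = pd.concat([aggregated, without], ignore_index=True)
    group = group_average(aggregated)

    surfaces = {}
    if cfg.include_joint and has_fmri:
        joint = group[group["roi"].notna() & group["window"].notna()]
        for variable in cfg.variables:
            if variable in set(joint["variable"]):
                surfaces[variable] = build_information_surface(
                    group, variable, rois=list(exp.rois)
                )

    manifest = {
        "seed": cfg.seed,
        "n_subjects": exp.n_subjects,
        "session_kind": exp.session_kind,
        "trials_per_condition": exp.trials_per_condition,
        "variables": list(cfg.variables),
        "n_sim": cfg.n_sim,
        "n_perm": cfg.n_perm,
        "correction_mode": cfg.correction_mode,
        "rois": list(exp.rois),
        "electrode_pairs": ["/".join(p) for p in exp.electrode_pairs],
    }
    return PipelineResult(estimates, aggregated, group, surfaces, manifest)
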
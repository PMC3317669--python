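"""Histogram estimation of joint probability mass functions and plug-in MI.

The response space of each feature is partitioned into equal-width bins
spanning the observed minimum to maximum (the grid always includes the most
extreme values, so single outliers widen every bin).  Bins are half-open
[lo, hi) with a closed top bin, conserving counts.  The default bin count
follows a square-root-of-total-cells heuristic: bins_per_dim =
floor(N^(1/(2d))), so the number of cells in the d-dimensional response
grid is about sqrt(N).  Mutual information is the plug-in estimate

    I = sum_{v,cell} p(v,cell) log2[ p(v,cell) / (p(v) p(cell)) ]

in bits, with 0 log 0 = 0.  The estimator is positively biased at finite N;
see :mod:`itfuse.bias` for the correction machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import feature_matrix

__all__ = [
    "BinningSpec",
    "JointPMF",
    "MIProblem",
    "default_bin_count",
    "build_histogram_grid",
    "digitize",
    "estimate_joint_pmf",
    "plugin_mutual_information",
    "mi_bits_from_counts",
    "mi_about_stimulus",
    "mi_about_behaviour",
    "STIMULUS_VARIABLES",
    "BEHAVIOUR_VARIABLES",
]

STIMULUS_VARIABLES = ("informativeness", "category", "prioritization")
BEHAVIOUR_VARIABLES = ("rt", "decision")

#: Response-time cutoff: trials slower than this are treated as non-responses
#: and excluded from the RT information analysis.
RT_LIMIT_MS = 1000.0


def default_bin_count(N: int, d: int) -> int:
    """Default bins per response dimension: floor(N^(1/(2d))).

    ``d`` is the dimensionality of the histogrammed response space (the
    behavioural variable, when binned, counts as a dimension).  Raises when
    fewer than two bins per dimension would result.
    """
    if d not in (1, 2, 3):
        raise ValueError(f"response dimension must be 1, 2 or 3, got {d}")
    if N < 4:
        raise ValueError(f"N={N}: cannot form >= 2 bins per dimension")
    b = math.floor(N ** (1.0 / (2 * d)))
    if b < 2:
        raise ValueError(f"N={N} too small for {d}-dimensional binning (would give {b} bin)")
    return b


@dataclass
class BinningSpec:
    """How to bin the response dimensions.

    ``rule="sqrt_total_cells"`` applies :func:`default_bin_count` with
    ``N_c`` (trials per condition, or total trials for behavioural
    analyses); ``rule="fixed"`` uses ``n_bins_per_dim``.  Explicit
    ``edges`` override both.
    """

    rule: str = "sqrt_total_cells"
    n_bins_per_dim: int | None = None
    edges: list[np.ndarray] | None = None
    n_condition_trials: int | None = None  # N_c driving the default rule

    def resolve_bins(self, N: int, d: int) -> int:
        if self.rule == "fixed":
            if self.n_bins_per_dim is None:
                raise ValueError("fixed rule requires n_bins_per_dim")
            return int(self.n_bins_per_dim)
        if self.rule == "sqrt_total_cells":
            return default_bin_count(self.n_condition_trials or N, d)
        raise ValueError(f"unknown binning rule {self.rule!r}")


def build_histogram_grid(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width bin edges from observed min to observed max."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if lo == hi:
        raise ValueError("constant dimension: zero-width histogram grid")
    return np.linspace(lo, hi, n_bins + 1)


def digitize(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin indices for half-open bins [lo, hi) with a closed top bin."""
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


@dataclass
class JointPMF:
    """Joint counts over (variable level, response cell) with the grid metadata."""

    counts: np.ndarray  # (n_levels, *bins_per_dim), integer counts
    levels: np.ndarray  # level labels, aligned with axis 0
    edges: list[np.ndarray]  # per response dimension

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def probs(self) -> np.ndarray:
        return self.counts / self.N

    @property
    def level_counts(self) -> np.ndarray:
        """N_s: trials per variable level."""
        return self.counts.reshape(self.counts.shape[0], -1).sum(axis=1)

    @property
    def occupied_per_level(self) -> np.ndarray:
        """Occupied response cells within each level (B~_s)."""
        flat = self.counts.reshape(self.counts.shape[0], -1)
        return (flat > 0).sum(axis=1)

    @property
    def occupied_overall(self) -> int:
        """Occupied response cells pooled over levels (B~)."""
        flat = self.counts.reshape(self.counts.shape[0], -1)
        return int((flat.sum(axis=0) > 0).sum())


def estimate_joint_pmf(
    levels: np.ndarray,
    responses: np.ndarray,
    spec: BinningSpec | None = None,
    expected_levels: list | None = None,
) -> JointPMF:
    """Histogram the (level, response) sample into a JointPMF.

    ``levels`` are discrete labels; ``responses`` is (N,) or (N, d)
    continuous features.  Raises when a level listed in
    ``expected_levels`` (or observed to have zero trials after alignment)
    is empty.
    """
    levels = np.asarray(levels)
    responses = np.asarray(responses, dtype=float)
    if responses.ndim == 1:
        responses = responses[:, None]
    if len(levels) != len(responses):
        raise ValueError("levels and responses are not aligned")
    spec = spec or BinningSpec()

    uniq, codes = np.unique(levels, return_inverse=True)
    if expected_levels is not None:
        missing = [lv for lv in expected_levels if lv not in uniq]
        if missing:
            raise ValueError(f"levels with zero trials: {missing}")
    if len(uniq) < 2:
        raise ValueError("need >= 2 variable levels")

    N, d = responses.shape
    if spec.edges is not None:
        edges = [np.asarray(e, dtype=float) for e in spec.edges]
        if len(edges) != d:
            raise ValueError(f"{len(edges)} edge vectors for {d} dimensions")
        for e in edges:
            if not np.all(np.diff(e) > 0):
                raise ValueError("bin edges must be strictly increasing")
    else:
        nb = spec.resolve_bins(N, d)
        edges = [build_histogram_grid(responses[:, j], nb) for j in range(d)]

    shape = tuple(len(e) - 1 for e in edges)
    cell = np.zeros(N, dtype=np.int64)
    for j in range(d):
        cell = cell * shape[j] + digitize(responses[:, j], edges[j])
    n_cells = int(np.prod(shape))
    flat = codes * n_cells + cell
    counts = np.bincount(flat, minlength=len(uniq) * n_cells)
    counts = counts.reshape(len(uniq), *shape)
    return JointPMF(counts, uniq, edges)


def mi_bits_from_counts(counts: np.ndarray) -> np.ndarray:
    """Plug-in MI in bits from count tensors.

    ``counts`` has shape (..., L, C): leading axes are batch dimensions,
    the last two are variable level x (flattened) response cell.
    """
    counts = np.asarray(counts, dtype=float)
    N = counts.sum(axis=(-2, -1), keepdims=True)
    p = counts / N
    pl = p.sum(axis=-1, keepdims=True)
    pc = p.sum(axis=-2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * np.log2(p / (pl * pc))
    term = np.where(p > 0, term, 0.0)
    return term.sum(axis=(-2, -1))


def plugin_mutual_information(pmf: JointPMF) -> float:
    """Plug-in mutual information of the estimated joint pmf, in bits."""
    flat = pmf.counts.reshape(pmf.counts.shape[0], -1)
    return float(mi_bits_from_counts(flat))


@dataclass
class MIProblem:
    """A prepared MI estimation problem: data, pmf and naive estimate.

    ``kind`` selects the matching parametric null model downstream:
    "stimulus" (Gaussian responses, design labels fixed), "rt" (Gamma
    behavioural null) or "decision" (Bernoulli behavioural null).
    """

    kind: str
    variable: str
    feature_ids: list[str]
    levels: np.ndarray  # discrete labels (for rt: the raw RT values, binned below)
    responses: np.ndarray  # (N, d)
    pmf: JointPMF
    naive_bits: float
    n_bins_per_dim: int
    spec: BinningSpec = field(default_factory=BinningSpec)
    behaviour_values: np.ndarray | None = None  # raw RT / decision codes


def _gather(features: pd.DataFrame, schedule: pd.DataFrame, feature_ids):
    trial_ids, resp = feature_matrix(features, list(feature_ids))
    sched = schedule.set_index("trial").loc[trial_ids]
    return trial_ids, resp, sched


def _condition_cell_count(sched: pd.DataFrame) -> int:
    """N_c: smallest 2x2 design-cell count among the trials in use."""
    return int(sched.groupby(["informativeness", "prioritization"], observed=True).size().min())


def mi_about_stimulus(
    features: pd.DataFrame,
    schedule: pd.DataFrame,
    variable: str,
    feature_ids,
    spec: BinningSpec | None = None,
) -> MIProblem:
    """Naive MI of the features about a binary stimulus/state variable.

    Trials are pooled over all non-target factors; the variable's design
    marginal is (near-)uniform.  ``feature_ids`` holds one feature for the
    univariate quantity or an (EEG, fMRI) pair for the bivariate one.
    """
    if variable not in STIMULUS_VARIABLES:
        raise ValueError(
            f"unknown stimulus variable {variable!r}; expected one of {STIMULUS_VARIABLES}"
        )
    feature_ids = list(feature_ids)
    if not 1 <= len(feature_ids) <= 2:
        raise ValueError("stimulus MI takes 1 (univariate) or 2 (EEG+fMRI) features")
    _, resp, sched = _gather(features, schedule, feature_ids)
    levels = sched[variable].to_numpy()
    spec = spec or BinningSpec(n_condition_trials=_condition_cell_count(sched))
    d = resp.shape[1]
    pmf = estimate_joint_pmf(levels, resp, spec, expected_levels=sorted(set(levels)))
    nb = len(pmf.edges[0]) - 1
    return MIProblem(
        kind="stimulus",
        variable=variable,
        feature_ids=feature_ids,
        levels=levels,
        responses=resp,
        pmf=pmf,
        naive_bits=plugin_mutual_information(pmf),
        n_bins_per_dim=nb,
        spec=spec,
    )


def mi_about_behaviour(
    features: pd.DataFrame,
    schedule: pd.DataFrame,
    variable: str,
    feature_ids,
    spec: BinningSpec | None = None,
) -> MIProblem:
    """Naive MI of the features about behaviour (response time or decision).

    rt:
        all conditions pooled; trials with RT > 1 s (non-responses)
        excluded; RT binned on its own equal-width grid, giving a
        (d+1)-dimensional histogram.
    decision:
        low-informativeness trials only (decoupling the decision from the
        physical category as far as possible); binary levels.

    The bin-count rule uses the total number of trials evaluated with
    d = response dims + 1 (the behavioural variable counts as a dimension).
    """
    if variable not in BEHAVIOUR_VARIABLES:
        raise ValueError(
            f"unknown behavioural variable {variable!r}; expected one of {BEHAVIOUR_VARIABLES}"
        )
    feature_ids = list(feature_ids)
    _, resp, sched = _gather(features, schedule, feature_ids)
    d = resp.shape[1]

    if variable == "rt":
        rt = sched["rt"].to_numpy(dtype=float)
        keep = np.isfinite(rt) & (rt <= RT_LIMIT_MS)
        if keep.sum() < 4:
            raise ValueError("too few responded trials for the RT analysis")
        rt, resp = rt[keep], resp[keep]
        N = len(rt)
        spec = spec or BinningSpec(n_condition_trials=N)
        nb = spec.edges and (len(spec.edges[0]) - 1) or spec.resolve_bins(N, d + 1)
        b_edges = build_histogram_grid(rt, nb)
        b_codes = digitize(rt, b_edges)
        inner = BinningSpec(rule="fixed", n_bins_per_dim=nb, edges=spec.edges)
        pmf = estimate_joint_pmf(b_codes, resp, inner)
        return MIProblem(
            kind="rt",
            variable="rt",
            feature_ids=feature_ids,
            levels=b_codes,
            responses=resp,
            pmf=pmf,
            naive_bits=plugin_mutual_information(pmf),
            n_bins_per_dim=nb,
            spec=spec,
            behaviour_values=rt,
        )

    # decision
    low = (sched["informativeness"] == "low").to_numpy()
    dec = sched["decision"].to_numpy()
    keep = low & pd.notna(dec)
    if keep.sum() < 4:
        raise ValueError("too few low-informativeness decision trials")
    dec, resp = dec[keep], resp[keep]
    N = len(dec)
    spec = spec or BinningSpec(n_condition_trials=N)
    nb = spec.edges and (len(spec.edges[0]) - 1) or spec.resolve_bins(N, d + 1)
    inner = BinningSpec(rule="fixed", n_bins_per_dim=nb, edges=spec.edges)
    pmf = estimate_joint_pmf(dec, resp, inner, expected_levels=["car", "face"])
    return MIProblem(
        kind="decision",
        variable="decision",
        feature_ids=feature_ids,
        levels=dec,
        responses=resp,
        pmf=pmf,
        naive_bits=plugin_mutual_information(pmf),
        n_bins_per_dim=nb,
        spec=spec,
        behaviour_values=(dec == "face").astype(int),
    )
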
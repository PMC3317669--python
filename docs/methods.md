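# Methods

This note documents the generative model behind the synthetic data, the
estimator and its bias correction, the aggregation into information
surfaces, the numerical choices, and what the package's tests do and do
not establish about real recordings.

## Estimation model

For a discrete variable of interest `V` (a binary stimulus/state factor,
a binary decision, or a binned response time) and a response feature
vector `R` of dimension d ∈ {1, 2}, the joint probability mass function
is estimated by an equal-width histogram and the mutual information is
the plug-in sum `I = Σ p(v, cell) log₂[p(v, cell)/(p(v) p(cell))]` in
bits, with `0·log 0 = 0`.

**Binning.**  Each response dimension is partitioned into equal-width
bins spanning exactly the observed minimum to maximum, so the grid always
contains every data point; a single outlier therefore widens all bins,
which is why response-time outliers are excluded before estimation (see
below).  Bins are half-open `[lo, hi)` with a closed top bin, conserving
counts.  The default bin count per dimension is `floor(N^(1/(2d)))` —
about √N cells in the full response grid — driven by `N_c`, the number of
trials per condition for stimulus analyses, and by the total number of
evaluated trials for behavioural analyses, where the behavioural variable
itself counts as a dimension (d = response dims + 1).  This heuristic is
deliberately configurable (`BinningSpec`): it is a documented stand-in, on
the permissive/non-conservative side, and the bias-correction machinery is
what keeps the false-positive risk in check.  Absolute information values
should not be over-interpreted; between-feature comparisons are the
intended use.

**Exclusions.**  Response-time analyses pool all conditions and drop
trials slower than 1 s (non-responses).  Decision analyses use only
low-informativeness trials, where the decision is least determined by the
physical category; this halves the trial count and makes those estimates
noisier by design.

**Bias correction.**  The plug-in estimator is positively biased at
finite N.  Three corrections are computed:

1. *Panzeri–Treves (PT):* `[Σₛ(B̃ₛ − 1) − (B̃ − 1)] / (2N ln 2)` bits,
   with `B̃ₛ`, `B̃` the occupied response cells per level and overall.
2. *Parametric null:* `n_sim` (default 1000) replicates of mutually
   independent surrogates with matched marginal moments — Gaussian
   responses (pooled mean/SD per feature); a Gamma with the observed
   response-time mean/variance, or a Bernoulli with the observed decision
   rate, for the behavioural variable — each replicate passed through the
   *full* pipeline including its own min–max grid construction.
3. *Shuffle null:* `n_perm` (default 1000) label permutations with the
   responses and their binning fixed.

The default combination is

    corrected = naive − PT − mean(null naive − null PT)

i.e. the PT term is removed once from the data estimate and once inside
each null replicate, so the analytic first-order bias is not subtracted
twice; the parametric-null residual mops up what the first-order formula
misses.  The shuffle distribution is kept as a diagnostic (and available
as an alternative correction mode) because whether the published analyses
subtracted it in addition to the parametric null cannot be determined;
subtracting both would double-count the same finite-sampling bias.
Negative corrected values are possible and are not clamped — clamping
would bias between-feature comparisons upward.

Calibration is verified by simulation: on data generated under full
independence the corrected estimator's mean over 200 replicates is within
Monte-Carlo error of zero for all three null kinds
(`tests/test_acceptance.py`).

## Synthetic data generator

The generator emulates the study design so that every downstream stage is
testable without any recordings: a 2×2 within-subject factorial
(informativeness high/low × spatial prioritization yes/no) with stimulus
category (face/car) and hemifield (left/right) balanced within cells;
72 trials per condition for EEG-only sessions and 90 for EEG-fMRI
sessions (when the per-condition count is not divisible by 4 the
category × hemifield sub-cells use a deterministic near-balanced split so
both margins stay exactly half/half).

**EEG.**  Epochs span −100…500 ms at 500 Hz (301 samples).  Three evoked
components — P100 (100 ms), N140 (140 ms EEG-only / 164 ms EEG-fMRI,
negative) and P300 (270 / 290 ms) — are Gaussian bumps truncated at ±3σ,
carried only by the electrodes contralateral to the stimulated hemifield
over the eight parieto-occipital pairs (O1/2, PO3/4, PO7/8, P1/2, P3/4,
P5/6, P7/8, TP7/8).  Latencies sit on the sample grid and each
component's support lies strictly inside its analysis window, so with all
noise terms at zero the window extremum equals the injected amplitude
*exactly* — the injection-recovery tests rely on this.  Per-trial
amplitude = condition mean (base + effect delta) + Gaussian amplitude
jitter; sensor noise is white Gaussian per sample (optional 1/f
colouring), as no noise model is prescribed by the design.

Default effect sizes (free parameters, documented rather than estimated):
P100 prioritization delta 1.5 µV on a 5 µV base, P300 informativeness
delta 2.5 µV on a 6 µV base, amplitude jitter 1 µV, sensor noise 3 µV.
These are optimistic relative to raw single-trial EEG; they are chosen so
that recovery properties can be demonstrated at desk-scale trial counts,
and they can be dialled down for harder regimes.

**BOLD.**  Per-ROI series at TR = 2 s, baseline 100 units, events spaced
by inter-trial intervals drawn from {10, 12} s.  The haemodynamic kernel
is a gamma-density bump (shape 6, scale 1 s) truncated at 8 s — the
simulated response has returned to baseline by 8 s and has no
post-stimulus undershoot — normalized so its maximum *on the TR grid*
is exactly 1.  Percent signal change uses the two volumes at −2 s and 0 s
relative to onset as baseline (the response lag exceeds one TR), and the
single-trial feature is the PSC maximum over (0, 10] s without any
deconvolution or interpolation.  With these choices the noise-free
extracted peak equals the injected amplitude exactly even from the
continuous, overlapping series.  Defaults: base amplitude 0.8 % signal
change, per-factor ROI deltas ~0.3–0.4 %, trial jitter 0.15 %, volume
noise 0.2 %.

**Behaviour.**  Response time = 150 ms shift + Gamma(shape 4) with
condition-dependent mean (base 400 ms; +55 ms for low informativeness,
+30 ms without prioritization — high-informative and prioritized trials
are faster), optionally coupled to the latent single-trial P300 amplitude
(25 ms per SD) so that genuine `I(B; R) > 0` exists for recovery tests.
Responding trials follow the Gamma truncated at the 1 s deadline; a
`nonresponse_rate` fraction (default 10.8 %) receives RT > 1 s, so the
downstream exclusion rule is exercised and the long-run non-response
fraction equals the configured rate exactly.  Decisions are correct with
condition-dependent probability (defaults 0.95/0.93/0.87/0.85 across the
four cells, ~90 % overall).

**What the generator does not emulate:** scanner and physiological EEG
artifacts (gradient/BCG residuals, eye movements), spatially correlated
sensor noise, HRF shape variability across ROIs and subjects,
trial-history effects, and realistic (lower) single-trial SNR.  Passing
tests therefore demonstrate correctness of the estimation machinery under
a known generative model, not expected effect sizes or detection power on
real recordings.

## Feature extraction

Trials with any sample outside ±100 µV are discarded before pooling
(boundary values inclusive — equality is not "outside").  Rejection is
evaluated on all retained scalp channels before contralateral pooling.
Pooling maps each electrode pair to one virtual channel taking the
hemisphere contralateral to the trial's hemifield; it never mixes
hemispheres within a trial.  Window features are the maximum per window,
except the third window (N140) which contributes the minimum.  Window
presets: EEG-only −100–58 / 60–120 / 122–154 / 156–370 / 372–500 ms;
EEG-fMRI −100–58 / 60–140 / 142–188 / 190–400 / 402–500 ms (responses are
delayed in the scanner); both are config-driven.

## Aggregation and surfaces

Corrected estimates are averaged over electrode pairs *after* bias
correction (per-electrode joint estimates, then the unweighted mean —
the same order is used for the joint features), then across subjects
(mean ± SD/√n).  Surfaces are pure rearrangements of those values onto
the 5-window × 13-ROI grid (V1, V2, LO, CU, FF, PL, PR, PC, AC, IN, FL,
FR, SF — an approximate occipital → frontal gradient); no further
transform is applied, so the sum of surface cells equals the sum of the
aggregated estimates.

## Statistics

Between-feature comparisons use one- or two-way repeated-measures ANOVA
(fitting delegated to pingouin) with Greenhouse–Geisser correction of the
degrees of freedom when Mauchly's test is significant at α = 0.05 (the
trigger level is assumed; GG ε is clipped to [1/(k−1), 1]), followed by
uncorrected pairwise paired-t comparisons of the marginal means (LSD —
by construction no multiplicity adjustment; caveat emptor).  Effects with
zero sum of squares report F = 0 rather than 0/0.  Sphericity is
undefined for two levels and the Mauchly test refuses k < 3.

## Stimulus generation

Image informativeness is manipulated by mixing the Fourier phase spectrum
with that of a Gaussian noise image at weight w while keeping the
amplitude spectrum: the mixed phase is the circular (vector-resultant)
weighted mean `arg(w·e^{iφ_orig} + (1−w)·e^{iφ_noise})` — naive linear
interpolation of raw angles misbehaves at the ±π wrap-around and is not
used.  The noise phase comes from the FFT of a real noise image, so it is
Hermitian and the mixed spectrum corresponds to a real image; the DC
phase is pinned to the original's, preserving mean luminance exactly.
The weights used for "high" and "low" informativeness in the original
experiments are not legible in the available text; w is therefore an
explicit parameter with no claimed default.

## Numerical and testing choices

* Randomness: every component draws from a `numpy` Generator keyed by a
  master seed plus a tuple of identifiers (subject, stage, variable,
  feature), hashed with BLAKE2 — estimates are bit-reproducible and
  independent of evaluation order.
* Ties at bin edges go to the upper bin (half-open bins, closed top).
* The bivariate-vs-univariate monotonicity check (`I(S;R₁,R₂) ≥ I(S;R₁)`)
  holds on shared grids and is tested that way; with independently chosen
  grids it can fail by discretisation.
* Test problem sizes: the null-calibration check uses 240 trials × 200
  replicates × 1000 null simulations per kind; the surface-recovery check
  uses 50 replicate pipelines of 5 subjects × 72 trials/condition on a
  5-window × 4-ROI grid with 2 electrode pairs and 200 null simulations
  (the shuffle diagnostic off, as it does not enter the default
  correction).  These sizes are the package's chosen demonstration scale;
  all of them are configuration, not limits.
* The zero-effect surface check asks that each cell's mean corrected MI
  over replicate pipelines stays within twice the run-level SEM the
  surface itself reports.  A simultaneous per-cell 2·SEM z-test over
  dozens of cells would fail with probability ≈ 1 − 0.954^k under perfect
  calibration; averaging replicates against the run-level error bar keeps
  the check sensitive to real bias (> 2 σ of a single run's group mean)
  without being a multiplicity coin-flip.

## Known limitations

* Histogram MI with √N-cell grids is crude for small N; kernel or
  nearest-neighbour estimators are out of scope by design.
* Synergy/redundancy decomposition of the joint EEG-fMRI information is
  not computed — with histogram estimation at these trial counts it is
  too unreliable.
* The parametric null assumes independent Gaussian response marginals;
  heavy-tailed features would make the residual-bias estimate slightly
  off (the shuffle diagnostic is the cross-check).
* The RM-ANOVA layer supports one- and two-way complete within-subject
  designs only; GG correction for interactions of factors with more than
  two levels is not attempted.
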
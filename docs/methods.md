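# Methods

This note documents the models, algorithms and design choices behind
`sersdx`: what is computed, under which assumptions, and where the open
choices were resolved.

## The synthetic cohort generator

The generator (`sersdx.synth`) emulates a two-group serum SERS
case–control study so that every downstream stage can be exercised and
validated without patient data. A spectrum is built as

```
I(ν) = b·B(ν) + s·Σ_k g_k A_k L_k(ν) + ε(ν)
```

* `L_k` — vibrational line shapes (Lorentzian by default, Gaussian
  available) at common serum SERS positions; 19 peaks between 495 and
  1655 cm⁻¹ with FWHM 12–22 cm⁻¹ and relative amplitudes 0.2–0.6 a.u.
* `B(ν)` — a fixed smooth autofluorescence shape (low-order polynomial
  plus one wide Gaussian bump) scaled by `baseline_scale` (default 1.5
  a.u., comparable to the peaks, as in real serum SERS after the
  instrument's own background subtraction).
* `s = exp(N(0, subject_sd))` and `b = exp(N(0, subject_sd))` — one
  overall amplitude factor and one baseline factor per **subject**
  (default sd 0.15), shared by all of that subject's replicates.
* `g_k = exp(N(0, peak_jitter_sd))` — per-subject, per-peak amplitude
  jitter (default sd 0.35). This is the between-subject biochemical
  variability that survives per-spectrum normalisation; without it
  replicate spectra would be separable by noise alone and any single
  band would classify perfectly, which no serum study shows. Its
  default makes a single effect band discriminate at roughly 0.7–0.8
  accuracy while the multivariate model pools all three bands — the
  qualitative regime reported for serum discrimination tasks.
* **Group effect** — peaks whose centers fall inside a configured
  effect band (defaults: 632, 728, 1062 cm⁻¹) have their amplitudes
  multiplied by `effect_ratio` (default 2.0) in Target subjects only.
  The effect peaks carry a deliberately modest share (~15%) of the
  total peak intensity: per-spectrum SNV rescaling couples all
  channels, and if the effect bands dominated the spectrum's variance
  the rescaling would smear the group difference over every large band.
* `ε` — i.i.d. additive Gaussian channel noise (default sd 0.02 a.u.).
  Shot-noise (intensity-dependent) scaling is deliberately omitted; it
  is not identifiable from summary descriptions of such experiments.
  The signal peak-to-peak (~2 a.u.) over the noise sd is ≈100, i.e. the
  "SNR not less than 50" regime.

Default cohort: 48 Target and 30 Control subjects, 3 replicates each,
axis 400–1800 cm⁻¹ at 2 cm⁻¹ (701 channels). Three replicates of 30
Control subjects give 90 spectra; studies sometimes report slightly
fewer after quality control, so `drop_spectra` removes one replicate
from each of the last *n* Control subjects (default 0). All randomness
flows from a single `seed` through `numpy.random.SeedSequence`
spawning, so identical configs give bit-identical datasets.

What the generator does **not** emulate: wavenumber calibration drift,
cosmic-ray spikes, detector nonlinearity, peak-position shifts between
subjects, and correlated (pink) noise. Passing tests on this generator
therefore demonstrate the statistical machinery — leakage-free
validation, chance-level behaviour under the null, band localisation —
not performance on any real cohort.

## Preprocessing

Fixed order: smoothing → baseline removal → SNV. Sample standard
deviation (n−1) is used everywhere.

* **Savitzky–Golay** (window 15 channels, polyorder 1, no derivative)
  via the standard convolution implementation. Edges are handled by
  evaluating the edge-window polynomial fit at the boundary channels,
  which keeps the output length equal to the input and passes
  polynomials of degree ≤ polyorder (in particular affine signals)
  through unchanged everywhere — reflective padding would break that
  exactness at the edges.
* **Baseline**: degree-15 polynomial fitted in a Chebyshev basis on the
  channel index rescaled to [−1, 1] (a raw-wavenumber monomial
  Vandermonde at degree 15 is numerically singular). The default
  scheme is the iterative clipped ("modified polyfit") variant: after
  each fit, signal above the fit is clipped to it and the polynomial is
  refitted; iteration stops when the relative change of the residual sd
  falls below `tol = 1e-3` or after `max_iter = 100` rounds. On
  peak-free input the first fit is already exact and the scheme reduces
  to a plain least-squares fit (also available via
  `baseline_iterative=False`). `corrected = spectrum − baseline`
  exactly, so the decomposition reconstructs the input to float
  round-off. Lorentzian wings are partially absorbed into the baseline
  — an intrinsic ambiguity of polynomial background removal — giving
  peak-height recovery within a few percent for well-separated bands.
* **SNV**: per-spectrum centering and scaling to unit sd. A constant
  spectrum is a degenerate-input error.
* **SNR estimate**: `ptp(smoothed) / sd(raw − smoothed)`, with +inf for
  a zero residual. Note that for peaks only a few channels wide the
  residual contains smoothing distortion as well as noise, so this
  estimator reads below the pure signal-to-noise ratio on sharply
  peaked spectra; on smooth signals it recovers amplitude/σ within
  Monte-Carlo error (validated in the tests).

## PLS-DA

Univariate-response NIPALS (PLS1) with X-deflation, implemented
directly: two classes need one dummy response column (Target = 1,
Control = 0; the 0.5 decision threshold and ≥-tie-break live in one
place, `sersdx.plsda.DECISION_THRESHOLD`). Weight columns are unit
norm; score vectors are mutually orthogonal; the full-rank fit
reproduces ordinary least squares; coefficients match an independent
reference implementation to 1e-6 — all asserted in the test suite.

**VIP** uses the canonical weight-based formula
`VIP_j² = p · Σ_a SS_a w_{ja}² / Σ_a SS_a`, `SS_a = q_a² t_aᵀt_a`, which
is the standard reading of "weighted sum of squared correlations
between components and the variable"; mean squared VIP is 1 by
construction, so 1.0 is the natural reporting threshold
("above-average importance").

**Model-order selection**: k-fold (default 7) cross-validation with
folds drawn at the subject level (shuffled within class, dealt
round-robin, so folds are group-stratified and never split a subject),
scoring mean held-out spectrum-level accuracy over a component grid
(default 1–15, capped by the rank bound). Ties prefer the smallest A —
a parsimony guard against overfitting. One NIPALS fit at the largest
candidate serves all smaller candidates through truncated
`W (PᵀW)⁻¹ q` coefficients.

## Validation protocol

Per iteration: 80% of the subjects of each group (floor per group:
38 Target + 24 Control of 48/30) are drawn into training; A is selected
by CV on the training sample; the model is fitted on training and
applied to both subsamples; specificity (Control recall), sensitivity
(Target recall), accuracy and Mann–Whitney AUC (midranks; ties count
one half) are computed **per spectrum** — each replicate counts
separately, since no subject-level vote rule is part of the protocol (a
majority-vote variant exists behind `subject_vote=True`). 30 iterations
by default; aggregation is mean/min/max per metric per subsample.

Randomness derives from `(base_seed, iteration, stage)` seed sequences,
so any single iteration is reproducible in isolation and the whole
protocol is deterministic given `base_seed`. Test subjects never touch
fitting or selection.

The single-band comparator mirrors the protocol: the feature is the
mean preprocessed intensity over `center ± halfwidth`, the threshold
(and its direction) is chosen to maximise training accuracy per split,
and mean test accuracy is reported.

The VIP profile is averaged across the 30 per-iteration models before
band extraction; contiguous channels with mean VIP ≥ 1 form the
reported intervals, annotated with their VIP maxima and ordered by peak
height in reports.

## Numerical and degenerate-input choices

* Zero-variance weight vector or score during NIPALS → fit error naming
  the component index.
* A test subsample missing one class aborts the iteration with a clear
  message (cannot occur at the default 48/30 cohort sizes).
* `single_band_accuracy` threshold candidates are midpoints of sorted
  unique feature values plus sentinels beyond both extremes; ties
  resolve to the first candidate scanned (deterministic).
* Model JSON serialisation stores arrays as nested lists at full double
  precision; a round-tripped model predicts bit-identically.

## Problem sizes

The acceptance tests and `scripts/acceptance.py` run the full
study-scale configuration: 234 spectra × 701 channels, 30 iterations,
7-fold CV per iteration, for both the strong-effect and the null
cohort. The unit/property suite uses reduced cohorts (e.g. 24 subjects,
351 channels) that preserve the replicate-within-subject structure.

## Known limitations

* PLS-DA scores are not calibrated probabilities; the 0.5 threshold is
  a convention, and with a 48/30 imbalance it trades specificity
  against sensitivity (visible in the worked example).
* The generator's effects are multiplicative amplitude changes at fixed
  positions; real disease signatures may also shift or broaden bands.
* Polynomial baseline removal absorbs part of broad Lorentzian wings;
  quantitative peak heights are recovered only approximately.
* Aggregated min–max ranges are order statistics over 30 splits and are
  themselves noisy; they characterise split-to-split spread, not
  confidence intervals.
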
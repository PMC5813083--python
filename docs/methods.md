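# Methods

This note records the modelling assumptions, parameter defaults and
numerical choices behind `isocoh`, and what the synthetic benchmarks do
and do not establish.

## Signal model and estimation

ROI time series are modelled, within a short stimulus-locked analysis
window, as a stationary multivariate autoregressive (MVAR) process

y_t = Σ_{k=1..p} A_k y_{t−k} + ε_t,  ε_t ~ N(0, S_ε).

**Fitting.** Ordinary least squares on lagged design rows stacked across
trials.  Each trial contributes rows for samples p..T−1 only, so no
design row ever mixes samples from two trials; this is the natural way
to exploit many short, synchronized trials without pretending they are
one continuous recording.  The innovation covariance is the
degrees-of-freedom-adjusted covariance of the pooled residuals.  Each
trial and ROI is mean-centered before fitting (a flag, on by default;
band-limited signals are already near zero-mean).  OLS is unbiased and
consistent for stable VAR processes and is trivially checkable against
textbook formulas, which is why it is preferred here over Yule-Walker or
state-space estimators.

A fit warns (does not fail) when fewer than 10 regression rows per
design column are available, and raises a singular-fit error naming the
implicated (ROI, lag) block when the design is rank-deficient.
Stability (companion-matrix spectral radius < 1) is a warning on fitted
models — estimation noise can push a near-unit-root fit over 1 — but a
hard error for simulation requests, where an unstable generator would
be meaningless.

**Model order.** Default 8.  With 51-sample windows this spends 32 of
~43 rows per trial per equation on parameters, deliberately trading
variance for the frequency resolution a higher order gives the AR
spectrum; the order is a configuration value, not a constant.  Order
selection criteria (AIC/BIC) are out of scope.

## Connectivity statistics

**Coherency.** Per trial, a single-taper DFT of the (windowed) epoch;
every complex coefficient is normalized to unit modulus before the
outer products are averaged across trials (an optional Hann taper is
off by default — the most literal reading of "normalized Fourier
transforms").  Coefficients with numerically zero modulus (the DC bin
of a centered signal) carry no phase and are dropped.  The frequency
grid is the native DFT grid of the window: ~5 Hz spacing for a 200 ms
window at 256 Hz.

**Lagged phase synchronization.** φ² = Im[f]²/(1 − Re[f]²), applied
entrywise; symmetric by construction.  When Re[f]² ≥ 1 − 10⁻¹² (perfect
instantaneous coherence, including the diagonal) the value is set to 0
and a warning counter is incremented rather than raising — such entries
are exactly the ones the statistic is designed to discount.

**Isolated effective coherence.** For source j → target i, the isolated
model keeps the self-connections (diagonal lag coefficients) of *all*
ROIs — the formula uses |Ā_jj|, so the source's own dynamics must
survive — zeroes every other cross connection, and reduces S_ε to its
diagonal (the full model's diagonal carried over; refitting the
isolated model is a sensitivity option deliberately not taken, since
the isolation is a counterfactual, not a new estimation problem).
κ is evaluated on a 1 Hz grid from the AR spectrum; the two statistics
are allowed different grids on purpose (DFT-limited vs model-based
resolution).  Both ratio evaluations floor the denominator at 10⁻¹²
with logged counters.

**Band averaging.** Arithmetic mean over grid frequencies with
inclusive edges; the default gamma band is 30–100 Hz.

## Group pipeline

Per subject: both report conditions are subsampled to their common
minimum trial count (seeded draw; reproducible), the 500–700 ms
post-stimulus window is extracted by half-open index arithmetic
(`round((t − t0)·fs)`), LPS is computed for the homotopic SAC and PAC
pairs and iCoh for all directed pairs including the heterotopic ones.
Group inference: paired Wilcoxon (LE vs RE) on LPS; per homotopic pair
a 2×2 repeated-measures ANOVA with Condition and Direction as
within-subject factors; four post-hoc Wilcoxon contrasts per pair
(direction within each condition, condition within each direction) as
one Holm family of size 4; a signed-rank test of RE vs LE report counts
alongside the mean laterality index.

Statistical conventions: with two levels per factor sphericity cannot
be violated (Greenhouse–Geisser ε = 1) and every effect F equals the
squared paired t of its subject-level contrast — the test suite holds
the implementation (pingouin's RM-ANOVA) to that identity against an
independent scipy route.  Partial η² is recovered as F·df₁/(F·df₁+df₂).
Wilcoxon p-values use the exact null distribution when ≤ 25 non-zero
differences remain and the tie-corrected normal approximation
otherwise; the reported Z is always the normal-approximation statistic
(signed positive when the first sample is larger) so the effect size
r = |Z|/√n is well defined; n is the number of pairs supplied.  A
zero-variance ANOVA contrast with non-zero mean is reported as F = ∞,
p = 0 rather than an exception, and subjects with missing cells are
dropped listwise with a logged count.

## Synthetic data: what it emulates

Each ROI is a stochastically driven damped AR(2) oscillator: poles at
modulus 0.95 and angle 2π·40/256 (a 40 Hz gamma rhythm at 256 Hz),
unit-variance Gaussian innovations.  Directed couplings are lag-1 cross
coefficients, so the generative model stays inside the MVAR family and
the directed ground truth is exact — parameter recovery and direction
recovery can be asserted against the generating coefficients rather
than a proxy.  Trials are drawn independently with a 10·order·4-sample
burn-in (comfortably past transients at pole modulus ≤ 0.97); epochs
default to 200 ms × 82 trials per condition, the analysis-window regime.

The default two-condition study encodes the callosal-relay hypothesis
as ground truth: homotopic SAC and PAC couplings of 0.08 in both
directions, with the rSAC→lSAC edge boosted by δ = 0.008 during
left-ear reports.  Between-subject variability (SD 0.03) is drawn once
per unordered pair and applied to both directions: a subject's callosal
coupling strength is treated as a subject property, while directional
asymmetry is condition-driven.  (With independent per-direction draws,
baseline asymmetry noise would swamp any plausible within-condition
direction contrast — the group effect would be detectable only in the
cross-condition comparison, which is not how a coupling difference of
this kind should behave.)  δ was calibrated once so that the
Condition × Direction interaction reaches roughly 85–90% power at 33
subjects (measured 0.93 over 30 pilot studies; ≥ 0.80 is asserted over
200 replicates in the suite); it is a configuration value, not a claim
about any real effect size.  Behavioral reports are multinomial draws
with right-ear/left-ear/error probabilities proportional to
134.81 : 80.00 : 25.69 (a strongly right-ear-advantaged group), 240
trials per subject.

What this does **not** emulate: lead fields and realistic source
mixing, non-stationarity within the window, non-Gaussian or
non-linear dynamics, evoked (phase-locked) components, trial-count
heterogeneity, or any coupling between behavioral laterality and
neural coupling strength (the two are generated independently).
Passing the synthetic benchmarks therefore shows that the estimators
and inference recover a known MVAR ground truth at realistic SNR and
sample sizes — not that the pipeline is robust to every pathology of
real source-reconstructed EEG.

## Volume-conduction robustness, honestly stated

Applying an invertible zero-lag mixing to independent ROI signals
leaves the *population* LPS at zero (the coherency becomes purely
real).  The finite-sample estimator is not exactly invariant: mixing
inflates Re[f], shrinks the 1 − Re² denominator, and raises the noise
floor by ~10–15% at zero-lag correlation ≈ 0.8 (≈ 4% at correlation
≈ 0.4; measured over 300 paired replicates).  The robustness tests
therefore assert what the measure actually delivers: the mean and
median of 200 mixed replicates stay inside the Monte-Carlo null band,
and the mixing artifact that uncorrected squared coherence shows
(which jumps two orders of magnitude above the band) is suppressed by
more than 95%.  A strict "no increase at all under paired comparison"
criterion would fail for any estimator of this form at strong mixing.

## Problem sizes used by tests and the acceptance script

Chosen to make the Monte-Carlo assertions statistically meaningful at
interactive runtimes: 1000 random 3-ROI models for the oracle
equivalence (tolerance 10⁻¹⁰), 400 trials × 51 samples for coefficient
recovery (±0.05), 200 replicates each for direction recovery (≥ 95%),
mixing robustness, and interaction power (≥ 0.80), and 500 null
studies of n = 33 for the type-I calibration (0.05 ± 0.02).  The
acceptance script derives independent sub-seeds for each block from a
single `--seed` via `SeedSequence`.

## Known limitations

* OLS MVAR assumes within-window stationarity; the windowing is the
  only defense offered.
* iCoh inherits the MVAR linearity assumption; it quantifies
  Granger-sense directed influence within the fitted model, not
  anatomical connectivity.
* The LPS noise floor scales with 1/n_trials and its null distribution
  depends on the trial count; comparisons should use balanced trials
  (the pipeline enforces this).
* The CLI's `simulate` accepts only scalar overrides of the default
  study recipe; structured coupling configurations are a Python-API
  feature.
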
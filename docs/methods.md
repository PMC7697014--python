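# Methods

`lungsound-dx` classifies mono lung-sound recordings into COPD, pneumonia
and healthy classes.  This note records the models and procedures the
package implements, the choices made where the design was genuinely open,
and what the synthetic test bed does and does not demonstrate.

## Pipeline

A recording passes through five stages in a fixed order:

1. **Region-of-interest extraction by empirical mode decomposition.**
   The signal is sifted into up to 10 intrinsic mode functions (IMFs);
   the region of interest is the sum of IMFs 2–4.  IMF-1 carries the
   fastest oscillations (sensor and quantization noise when the sampling
   rate comfortably exceeds the respiratory band), and modes beyond the
   fourth carry baseline drift and heart-sound remnants.
2. **Wavelet denoising.**  A single-level discrete wavelet transform with
   the Coiflets-5 mother wavelet splits the ROI into an approximation band
   (0 to fs/4) and a detail band (fs/4 to fs/2); detail coefficients are
   hard-thresholded and the signal is reconstructed at the original length.
3. **Feature extraction.**  A 116-dimensional descriptor: 19 time-domain
   statistics, 12 spectral statistics, 13 MFCC + 13 GFCC cepstral
   coefficients, and a 59-bin uniform local-binary-pattern histogram of the
   dB spectrogram.
4. **Class balancing (ADASYN)** in feature space, by default inside
   training folds only.
5. **Quadratic discriminant classification** with stratified k-fold or
   hold-out evaluation, reporting ACC and per-class TPR/FNR/PPV/FDR.

## Empirical mode decomposition

Sifting subtracts the mean of the cubic-spline upper/lower envelopes of the
current mode until the Cauchy criterion `SD = Σ(h_prev − h_cur)² / Σ h_prev²
< 0.2` is met *and* the extrema/zero-crossing counts differ by at most one,
capped at 100 iterations per mode.  Spline knots are the local extrema,
mirror-extended (two extrema about each end) to suppress end swings.
Decomposition stops early when the residue has fewer than three extrema.

Two numerical choices deserve note:

* **Mode acceptance tolerance.**  On oscillation-rich broadband signals
  (a second of audio at 44.1 kHz has ~30 000 extrema in its first mode) the
  extrema/zero-crossing counts converge to within a handful but not always
  to within one inside the iteration cap.  A sifted mode is therefore
  accepted when the counts agree within `max(1, 0.5% of the extrema
  count)`.  A candidate that still fails — in practice a residue-like tail
  with ~3 extrema and one zero crossing — is folded back into the residue
  and decomposition ends.  On short fixtures every accepted IMF satisfies
  the strict within-one condition; the test suite asserts this.
* **Completeness is exact by construction**: the residue is the running
  difference, so IMFs + residue reproduce the input to float round-off
  (observed ≤ 4e-16 relative).

`mean_frequency` (the periodogram centroid) is exposed as the diagnostic
used to describe each mode's band; it returns NaN on an all-zero mode.

## Wavelet denoising

Threshold rule: Donoho–Johnstone universal threshold `T = σ̂ √(2 ln N)` per
detail level, with the MAD noise estimate `σ̂ = median(|d|)/0.6745`; a fixed
threshold is available (`threshold_rule="fixed"`), and `T = 0` reproduces
the input to machine precision.  Hard thresholding (`d·1[|d|>T]`) keeps
kept coefficients untouched, which preserves transient crackle morphology
better than soft shrinkage.  Boundary extension is symmetric and the
reconstruction is trimmed to the input length.

## Features

Conventions (full list in `features.py`):

* Time and spectral moments use population (1/n) normalization; spectral
  kurtosis is excess (Gaussian → 0).  Log energy is `log10 Σx²`.
* Shannon energy is computed on peak-normalized samples so the log argument
  stays in (0, 1].
* "Average frequency" is the zero-crossing rate scaled to Hz (a pure f Hz
  tone crosses zero 2f times per second); "jitter" is the mean absolute
  difference of successive zero-crossing periods over the mean period.
  Both use linearly interpolated crossing instants.
* Spectral roll-off is the lowest frequency below which 95% of the
  cumulative magnitude lies; spectral flux is the mean over consecutive
  short-time frames (20-sample Hann window, 10-sample hop — the same
  geometry as the texture spectrogram) of the summed squared magnitude
  difference.
* MFCC: 55 ms Hann frames (midpoint of the 50–60 ms range usual for
  respiratory sounds) with 50% hop, 26 triangular filters equally spaced in
  Mel (`2595 log10(1+f/700)`), natural log, orthonormal DCT-II, 13
  coefficients averaged over frames.  The log floor is relative to each
  frame's strongest filter so that amplitude scaling moves only the first
  coefficient.
* GFCC: 64 gammatone channels (scipy's IIR design) with center frequencies
  equally spaced on the ERB-rate scale `21.4 log10(1+0.00437 f)` between
  50 Hz and 0.99·fs/2, rectified, averaged into 100 Hz frames, cube-root
  compressed, orthonormal DCT-II across channels, 13 coefficients averaged
  over frames.  Silence maps to the zero vector.
* LBP texture: dB magnitude spectrogram, radius-1 eight-neighbor codes with
  the `neighbor ≥ center` convention, bits counter-clockwise from the east
  neighbor; 58 uniform codes in ascending order plus one pooled
  non-uniform bin, histogram normalized to sum 1.  The implementation is a
  vectorized lookup table; the test suite checks it against a naive
  per-pixel oracle.
* Ratio features with zero denominators (silence) return 0 with a warning
  instead of raising, so batch extraction never aborts.

A compact 25-feature preset (`"table5"`) — std, peak-to-peak, log energy;
spectral std/skewness/kurtosis/flux/roll-off/decrease; MFCC 3–10 and GFCC
3–10 — is the classification default, so the discriminant is runnable
without re-running the wrapper search.  Reducing 116 → 25 features is a
78.44% reduction (truncated to two decimals).

## ADASYN

For each minority class, `G = (n_majority − n_c)·ratio` synthetic rows are
generated.  Seeds are drawn with probability proportional to the fraction
of each point's k = 5 whole-data nearest neighbors belonging to other
classes (uniform fallback when all weights vanish), and each synthetic row
interpolates between the seed and a random same-class neighbor, so
synthetic points stay inside the class's convex hull.  Neighbor search runs
on z-scored features (fitted on original rows) because the descriptor's
dimensions have wildly different units.  Balancing defaults to inside
training folds only; `balance_pre_split` balances the whole table before
splitting, which leaks interpolants into test folds and should be used only
for comparison.

## Classifier and evaluation

The quadratic discriminant assigns x to the class maximizing
`δ_k(x) = −½ ln|Σ_k| − ½ (x−μ_k)ᵀΣ_k⁻¹(x−μ_k) + ln π_k`, with per-class
sample covariances (n−1 denominator) and count priors.  A relative ridge
`reg · trace(Σ)/p` (default `reg = 1e-6`) keeps fits well-posed when a
class has fewer recordings than features.  A shared-covariance linear
discriminant is available as `model_type="lda"`.  Ties go to the first
class in sorted order.  Metrics are one-vs-rest per class; overall accuracy
is the confusion-matrix diagonal over the total; pooled confusion across
folds.  A class absent from the test rows reports its TPR/FNR as missing
rather than zero.

## Backward elimination

Greedy wrapper search: at each step the feature whose removal maximizes the
cross-validated accuracy of the evaluator is dropped (ties to the lowest
column index); the search stops when a removal would fall below the best
score seen so far for more than `patience` consecutive steps (the blocked
removal is not applied) or at `min_features`.  The recorded history
contains only applied removals, so `|retained| + |history|` equals the
starting feature count.

## Synthetic test bed

The generator emulates the acoustic structure that distinguishes the three
classes, not airway physiology: all classes share band-limited Gaussian
breath noise (60–600 Hz, the normal tracheal band) modulated by a two-phase
breath-cycle envelope, plus weak broadband sensor noise and low-frequency
baseline wander.  COPD adds 3 sustained amplitude-enveloped wheeze tones
(200–800 Hz, 0.3–1 s, amplitude 1.0 relative to the unit-RMS breath band)
in expiratory phases; pneumonia adds crackle trains (damped sinusoids,
400–2000 Hz, 5–40 ms decay, amplitude 1.2, ~8 per cycle).  Defaults follow
the recording conventions of public respiratory-sound collections: 21.5 s
at 44.1 kHz, 0.25 Hz breath rate.

`SyntheticSpec.compact()` (3 s at 16 kHz, 0.6 Hz breath rate) is the
profile used by the end-to-end tests and the acceptance script.  Two
constraints fix it: each recording must contain whole breath cycles (or
expiratory wheezes fall outside the excerpt), and the sampling rate must
comfortably exceed the adventitious band (≤ 2 kHz) so that IMF-1 carries
only sensor noise and the IMF 2–4 region of interest retains the class
cues — the same regime as a 44.1 kHz recording with content below 5 kHz.
At 8 kHz the crackle band bleeds into IMF-1 and the ROI destroys it.

What passing the synthetic suite shows: the pipeline preserves and
separates class-conditional spectral/temporal structure end to end, the
decomposition and denoising identities hold, and the classifier implements
the exact Gaussian-Bayes rule.  What it does not show: performance on real
auscultation, which adds heart sounds, friction artifacts, device
heterogeneity, within-class disease variability and label noise that the
generator deliberately omits.

## Problem sizes

End-to-end runs use 60 recordings per class under the compact profile
(180 × 3 s at 16 kHz), 5-fold stratified CV with in-fold ADASYN and the
25-feature preset; smaller configurations appear in unit tests.  The
wrapper search is quadratic in feature count and is exercised on small
tables (5–10 features); running it on all 116 features is supported but
slow (~7 000 CV fits).

## Known limitations

* The sifting envelope uses mirror extension of extrema; signals whose
  first/last samples are extreme points can still show mild end effects in
  low-order modes.
* GFCC channel envelopes are decimated by block averaging (no anti-alias
  filter beyond the gammatone itself), which is standard but makes the
  exact coefficient values implementation-specific.
* ADASYN assumes minority classes have more than k members; smaller classes
  are rejected rather than silently under-sampled.
* The ICBHI-style loader expects a `recording_id,label` sidecar CSV; it
  does not parse the official annotation formats.
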
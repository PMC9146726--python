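# Methods

## Signal model

Chrominance rPPG assumes the camera observes skin whose reflected colour
is a product of (slowly varying) illumination, a static skin tone, and a
small pulsatile component dominated by the green channel.  Dividing each
channel by its temporal mean over a short segment removes the first two
factors; the projections `X_s = 3R_n − 2G_n` and `Y_s = 1.5R_n + G_n −
1.5B_n` are chosen so that specular/illumination flicker appears with
equal strength in both, and the adaptive combination `S_f = X_f − α Y_f`,
`α = σ(X_f)/σ(Y_f)`, cancels it while the pulse survives.  The method
assumes a near-stationary subject, constant frame rate ≥ 20 fps, 8-bit
RGB, and at least standard room lighting.

### Windowing and sub-segments

Video is processed in consecutive non-overlapping windows of 3.3 s (so one
minute yields exactly 18 HR values; a trailing fraction of a window is
discarded with a logged warning).  Inside a window the trace is cut into
33-frame sub-segments at 50% overlap.  Each sub-segment is normalized *by
its own means* — local normalization is what gives the method its
tolerance to illumination drift — transformed, filtered, α-combined,
Hann-weighted and overlap-added; a final sub-segment anchored at the
window end covers any tail the hop pattern misses.  Face detection runs
once per window (first frame) and the cheek ROIs stay fixed within it.

### Band-pass filter

The physiological band is 0.67–3.67 Hz (40–220 bpm).  The filter is a
31-tap (at 30 fps, scaled linearly with fps, always odd) linear-phase FIR
designed by least squares with transition bands 0.3→0.67 Hz and
3.67→4.2 Hz, applied once as a reflection-padded symmetric convolution
after explicit mean subtraction.  Rationale for the choices:

* mean subtraction makes DC rejection exact regardless of filter length;
* a symmetric kernel applied once is zero-phase, and a single pass keeps
  the measured pass-band gain close to unity (1.08 at 1.2 Hz, 0.95 at
  2 Hz) where a double pass of a same-length windowed-sinc design falls
  to ~0.6;
* 31 taps is the longest practical kernel for 33-frame sub-segments; the
  low-edge transition cannot be sharp at this length (gain 0.12 at
  0.2 Hz, 0.5 at the 0.67 Hz edge), which is acceptable because the HR
  estimate is a peak *location*, not an amplitude.

### Spectral peak

A 3.3 s window has a native FFT resolution of ~0.3 Hz (18 bpm), far too
coarse for bpm-level output.  The pulse signal is zero-padded to 1024
points and the in-band magnitude maximum refined by parabolic
interpolation over the three surrounding bins; the result is clipped to
[40, 220] bpm.  A window whose total in-band power falls below 1e-12
(all-zero or degenerate input) returns the sentinel 0, as does a window
with no detected face.  On clean synthetic input the estimator is accurate
to ~0.5 bpm.

### Cheek geometry

With a face box (x, y, w, h), the left cheek is
[x+0.15w, x+0.35w] × [y+0.45h, y+0.70h] and the right cheek its mirror
image — below the eyes, beside the nose — clipped to the frame.  The
fractions are configurable; nothing downstream depends on them beyond the
ROI containing skin.  The default detector is scikit-image's pretrained
LBP frontal-face cascade; any callable returning a face box can replace
it, and tests inject known boxes so detector quality never gates signal
tests.  When several faces are detected the largest box is kept
(single-subject recordings).

## Series cleaning

Cheek series are merged element-wise (mean; if exactly one side is the
0 sentinel the other side is used).  The 5-point moving average uses
centred windows truncated at the series edges, so the trend has the same
length as the input.  Sentinel zeros are treated as missing measurements
throughout: they are excluded from window means and a zero position stays
zero in the trend.  This matters — a recording's first window is always a
warm-up zero, and averaging it into the trend would depress the first
five values enough that the 10% rule would then discard the whole head of
the series.

Cleaning removes all zeros, then repeatedly scans the series: an interior
value is removed when it deviates from the mean of its two current
neighbours by more than 10% of that mean (re-examining the same position
after each removal, since it has new neighbours); boundary values are
checked against their single neighbour.  Scans repeat to a fixpoint, so
cleaning is idempotent and the result is a zero-free subsequence of the
input in which every interior value satisfies the 10% bound.  Values are
removed, never interpolated.  A series with fewer than three usable
intervals (before or after cleaning) is an error rather than a silent
empty result.

## Labels, features, datasets

STAI scales are scored as the sum of twenty 4-point items with the
standard ten state-scale items reverse-keyed (configurable); totals lie
in [20, 80].  The binary label is score > 43.01 (male) or > 43.69
(female); with integer scores the strict/non-strict distinction is
unobservable.  The five dataset variants are built at per-(subject,
interval) granularity — each HR interval becomes an instance carrying its
subject's demographics and label — which is the only construction
consistent with a ~706-instance evaluation from 45 subjects.  A
per-subject granularity (mean HR per subject) is available and is used
for the null-condition check below.

## Classifiers

All four are configured as the reference Weka setup: SVM C=1 with the
Pearson VII kernel (ω=1, σ=1; the kernel itself is implemented here and
fed to scikit-learn's SVC as a precomputed Gram matrix); 1-NN on min-max
normalized features with a distance-derived ranking score
d₀/(d₀+d₁); C4.5-style tree (gain-ratio splits at numeric midpoints
among attributes reaching the average positive gain, ≥2 instances per
leaf, subtree-replacement pruning driven by the confidence factor 0.25
through the exact binomial upper confidence bound); random forest of 100
bagged such trees, unpruned, with a per-node random feature subset of
size ⌊log₂ m⌋+1, seed 1, unlimited depth.  The tree learner is
implemented in this package because no installed library offers
gain-ratio splitting or pessimistic pruning; the split search is
vectorized over sorted feature columns.

Evaluation uses deterministic stratified 10-fold CV (each class must have
at least k members), pools the four confusion counts over folds — the
published matrices sum to a single dataset-sized total, so pooling, not
per-fold averaging, is the comparable quantity — and computes the five
metrics from the pooled counts.  κ uses the standard marginal chance
correction; AUC is the Mann–Whitney rank statistic with ties counted
half, computed from the pooled continuous scores.

## Synthetic data: what it shows and what it does not

The video generator renders a rectangular skin patch (or ellipse) whose
colour oscillates at the planted rate with channel weights
(0.5, 1.0, 0.4)·amplitude — green-dominant, as blood-volume absorption
is — plus multiplicative sinusoidal illumination drift (2% at 1/20 Hz),
per-pixel Gaussian sensor noise, and optional patch jitter, quantized to
8 bits.  Defaults mirror a 30 fps 480×640 webcam; tests use smaller
frames.  Recovery of the planted rate within ±5 bpm therefore shows the
signal chain is correct under realistic noise and drift, but says nothing
about motion artefacts, facial texture, or detector robustness on real
faces (the detector gets a separate smoke test on a real photograph).

The cohort generator plants: stress prevalence 0.5 over 45 subjects;
state-anxiety scores drawn strictly above/below the gender cutoffs to
match the planted label; heart-rate baselines N(72, 10²) bpm shifted
+10 bpm for stressed subjects with within-subject interval noise of
3 bpm (within the <10 bpm resting fluctuation that motivates the 10%
rule), a leading sentinel zero and 8% spike outliers (×1.35) per series;
and Boolean demographics coupled to the label by per-feature log-odds
(defaults between 0.5 and 1.5 in magnitude).  Sixteen intervals per
subject give ~720 raw instances, matching the scale of the real cohort.

On this cohort the benchmark reproduces the qualitative result:
demographics+HR-CLEAN ≫ demographics alone > raw HR alone, for all four
classifiers.  An important caveat the simulation makes explicit: at
per-interval granularity, instances of the same subject appear in both
train and test folds, and since they share demographics and label,
instance-level CV overstates subject-level generalization — the
combined-variant accuracies near 1.0 here (and high accuracies in
comparable real evaluations) partly reflect that leakage.  For the null
condition (no planted HR shift, no demographic coupling) the package
therefore evaluates at per-subject granularity (220 subjects, one
instance each), where all four classifiers sit at chance (0.4–0.6
accuracy), and additionally checks that instance-level label permutation
drives κ to ~0 on the planted cohort.

## Problem sizes and determinism

Tests and the acceptance script use 60×80 to 80×100 pixel frames, 20–60 s
videos, and the default 45-subject cohort; every random draw flows from
an explicit integer seed (generators re-seed per iteration pass, so a
video regenerates bit-identically).  The published-metrics computation
uses the 19 internally consistent confusion matrices shipped as a
fixture; the one matrix whose cells do not sum to the common total is
flagged and excluded.  Known numerical edge cases: κ is defined as 1 when
both observed and chance agreement are exactly 1, and undefined
(an error) when only chance agreement is; metric ratios with empty
denominators report 0; parabolic peak interpolation is clamped to ±half a
bin; sub-segments with degenerate statistics (zero-variance chrominance,
non-positive channel means) contribute silence rather than failing the
window.
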
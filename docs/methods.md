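# Methods

This note records the models, conventions and numerical choices behind
`fatiguekit`, in the order the pipeline runs.

## Event detection

**EMG activations.** The Teager–Kaiser Energy Operator
`y[n] = x[n]² − x[n−1]·x[n+1]` tracks instantaneous signal energy; for a
sinusoid of amplitude A it returns the constant `A² sin²Ω`, which makes
burst onsets sharp even at modest SNR.  Endpoints are zeroed so the
output length equals the input length.  Detection rectifies the TKEO
output, smooths it with a 50 ms moving average, and thresholds at
`baseline mean + k·SD` with `k = 3`.  The baseline is the first 250 ms of
the record; if that span is itself active (mean above three times the
quietest-decile mean) the quietest decile stands in — its SD is
tail-truncated and biased low, which is why it is only a fallback.
Super-threshold runs shorter than twice the smoothing width are discarded
*before* gap-merging (isolated noise exceedances of a correlated envelope
would otherwise chain quiet spans together), runs closer than 100 ms are
merged, and merged runs shorter than 200 ms dropped.  All constants are
keyword arguments.

**R-peaks.** The Pan–Tompkins chain: zero-phase 5–15 Hz band-pass,
derivative, squaring, 150 ms moving-window integration, adaptive
signal/noise peak estimates with the classic 0.125/0.875 update, a 200 ms
refractory period, and a search-back pass triggered at 1.66× the running
RR mean.  Accepted detections are relocated to the raw-signal maximum
within ±50 ms.  On noiseless synthetic ECG every beat is recovered at the
exact sample; at realistic noise sensitivity stays above 0.99.

**RR units** are seconds internally; millisecond lists are converted on
read.  No ectopic-beat correction is applied — synthetic tachograms have
none, and real-data artifact handling is out of scope here.

## EMG descriptors

Each ~1 s activation is analyzed on its own (short enough for the
stationarity the Fourier estimates need).  The spectral estimator is a
linearly detrended one-sided periodogram; Welch averaging is deliberately
not used inside a single activation (too few samples per sub-segment).

**Median frequency** is the smallest grid frequency whose cumulative
power reaches half the total.  When the half level is hit exactly — an
even split such as two equal lines at 50 and 150 Hz — the tie resolves to
the midpoint of the cumulative plateau (100 Hz in that example).  This
convention returns the line frequency itself for a single spectral line
and the band center for a flat spectrum.

**Scalogram.** The continuous wavelet transform uses the complex Morlet
wavelet with bandwidth `b = 2.0` and center frequency `fc = 0.8125 Hz`,
on the pseudofrequency grid 5, 7, …, 499 Hz (2 Hz spacing over the
informative surface-EMG band).  Scales follow `scale = fc·fs/f`, so at
fs = 1000 Hz the array spans 1.628 (499 Hz) to 162.5 (5 Hz).  Descriptor
set per activation:

- *wavelet median frequency*: cumulative-half rule applied to the
  scalogram's marginal power over frequency (row sums over time) — the
  descriptor is named after the quantity, the marginalization is our
  choice;
- *Major Time / Major Frequency*: the scalogram centroid.  Two
  normalizations ship: `intensity` (default; divides the moment sums by
  the total magnitude — a true centroid, invariant to intensity scaling)
  and `literal` (divides by the pixel count T×F, which makes the value
  scale with image intensity and size; retained because some descriptor
  definitions are written that way);
- *mean power*: the average scalogram entry;
- *area, volume, time dispersion, frequency dispersion*: the scalogram is
  segmented by Otsu's method on its magnitudes min-max quantized to 256
  gray levels (the reference convention for Otsu on continuous images;
  the retained region is strictly above the returned threshold, i.e. at
  or above the next gray level).  The convex hull of the retained pixels'
  (time, frequency) coordinates gives the area (s·Hz) and the dispersions
  (hull extents per axis); the volume sums magnitudes over all pixels
  inside the hull.  Fewer than three non-collinear pixels degrade to area
  0, bounding-box dispersions, and the masked-pixel sum.

## HRV descriptors

Time-domain statistics use the population (1/n) variance convention
(`ddof` is exposed); SD1/SD2 come from the lag-1 scatter rotated 45°, so
`SD1² = var(ΔRR)/2` exactly.  The triangular index uses the conventional
1/128 s histogram bin.  RR spectra are computed on the tachogram
cubic-spline resampled at 4 Hz (standard practice; the resampling scheme
is a convention, not a reconstruction), linearly detrended, periodogram
in s²/Hz.  Band powers integrate by trapezoid over half-open bands
[lo, hi) — HF closed on the right — so shared edges are never counted
twice.  A band is *resolvable* only when the window holds a full period
of its lower edge: LF (0.04 Hz) needs 25 s, VLF 333 s, and ULF (lower
edge 0) is never resolvable on windows of minutes; unresolvable bands are
reported as NaN rather than a number.  The HRV median frequency uses the
0.003–0.4 Hz band by default (ULF excluded for the same reason).

## Sliding windows

EMG windows count activations: each activation is analyzed individually
and the per-activation values inside the window are averaged into one
sample.  HRV windows are spans of seconds; descriptors are recomputed on
the RR intervals whose terminating beat falls inside the span.  Window
timestamps are the centers of the spanned range (an unbiased regression
abscissa).  The step is `ts_percent` of the window size — for EMG rounded
half-up to whole activations, minimum one — and a 0 % step denotes
non-overlapping windows (step = window size): a literal zero step never
advances, and the non-overlap reading is the one under which a
25-activation window with "0" step produces a usable series.

## Trend meta-analysis

Per-participant OLS slopes carry the classical sampling variance
`residual variance / Σ(t−t̄)²`.  Pooling is fixed-effect inverse-variance;
no heterogeneity term is estimated.  The 95 % CI uses the *t* quantile
with `n − 2` degrees of freedom where `n` is the number of participants —
with the pooled standard deviation `σ_comb = sqrt(var_comb)` inside the
interval (a variance there would be dimensionally wrong).  The CV is
reported with absolute value, `σ_comb/|m_comb|`, so decreasing trends get
positive CVs.  Best-configuration selection minimizes the CV, ties broken
toward the smaller window, then the smaller step.

A caveat the test suite makes explicit: on strongly *overlapping* windows
the series samples are autocorrelated and the plug-in OLS slope variance
is anticonservative, so pooled CIs become too narrow and the zero-trend
false-positive rate of acceptability criterion 1 rises well above 5 %.
Null-behavior checks therefore run on non-overlapping (0 % step) windows,
where the variance is faithful; trending descriptors are unaffected in
practice because their effects dwarf the CI width.

The bundled reference trend table (`fatiguekit.reference`) records, for
each of the 14 descriptors that pass the acceptability test in the
original 14-subject cycloergometry cohort, the best (window, step), the
CV, the combined slope and its CI half-length.  It provides default GFD
weights and an internal consistency check: every half-length must equal
`t_{0.975, n−2}·CV·|m_comb|` (EMG rows pool 14 subjects, HRV rows 11).

## Global Fatigue Descriptor

`GFD[i] = Σ_k IFD_k[i]/CV_k / Σ_k 1/CV_k` over descriptors normalized by
their calibration maxima and clipped to [0, 1].  Descriptors with an
*increasing* fatigue trend (HRV median frequency) are fused as-is by
default — the fusion tolerates a minority of increasing inputs — with an
`invert_increasing` flag for `1 − x` mapping.  Because the different
descriptors live on different window clocks, series are aligned on a
shared clock (latest common start, smallest step, nearest-previous-window
value per tick); the fusion index is otherwise unconstructed.  Zone
thresholds are the 25 % percentile and median (linear-interpolation
quantiles) of a calibration GFD distribution, per participant; cohort
thresholds average the per-participant ones and report their SD.

## Classifier

Feature vectors hold, per descriptor, the mean of the max-normalized
series segment (`feature1`) and the relative variation rate
`(P_end/P_start − 1)/(t_end − t_start)` (`feature2`): 2·(4+10) = 28
entries.  Normalization maxima come from each participant's own
calibration pass — per-participant calibration is what removes
between-subject baseline differences; cohort-wide maxima leave the
classes entangled.  Class prototypes come from the first/second halves of
each trial (or first/fourth quarters for sharper prototypes, which
excludes the transitional middle).  Features are z-scored (fit on
training folds only — required for comparable |w| ranking), and recursive
feature elimination removes one feature per iteration (smallest
standardized |w|), keeping the subset with the best leave-one-out
accuracy (ties prefer fewer features).  The SVM is a soft-margin linear
machine (C = 1 default).  Evaluation uses 11 folds; with 22 examples from
11 participants each fold holds exactly one participant's pair, which is
simultaneously the stratification (one example per class per fold) and a
guard against within-subject leakage — label-permutation accuracy sits at
chance only under this grouping.  The degree of certainty is a
Platt-style sigmoid fit to the training margins; streamed classification
replaces the segment averages with instantaneous normalized values and a
trailing-window variation rate, reporting the calibrated probability of
the assigned class (≥ 0.5 by construction).

## Synthetic data

The generators emulate an exhausting constant-work-rate cycling trial.
Defaults (one choice, used everywhere): 600 s trials at 1000 Hz; one 1 s
EMG burst every 2 s (a steady cadence with one dominant-leg thrust per
cycle), burst = white noise through a 4th-order Butterworth band-pass of
60 Hz width whose center starts at 90 Hz and drifts at −0.03 Hz/s (the
symmetric band makes the center the expected spectral median), Tukey
tapered, over a quiet baseline of 1 % amplitude; RR starting at 0.8 s
drifting at −2·10⁻⁴ s/s with 30 ms LF (0.1 Hz) and 20 ms HF (0.25 Hz)
sinusoidal modulation and 10 ms white noise, realized as a point process
(each beat placed one instantaneous RR after the previous); ECG from a
stylized PQRST template at those beat times with 0.3 Hz baseline wander.
The recovery phase mirrors the drift signs.  Cohorts jitter starting
values and slopes multiplicatively (relative SD 0.1) and draw each
subject's LF/HF modulation phases uniformly — autonomic oscillations are
not phase-locked across people, and phase-locking them would inject a
spurious common trend into pooled analyses.  Every generator returns its
ground truth, and identical spec + seed gives bit-identical output.

What the generators do *not* model: motor-unit physiology, ECG morphology
beyond what peak detection needs, ectopic beats, movement artifacts,
electrode drift, or nonlinear fatigue trajectories.  Passing tests
demonstrate that the pipeline recovers the statistical structure it
assumes; they do not validate the physiological thresholds on real
recordings.

## Problem sizes in the test suite

Cohort-level checks run 11 subjects, 300 s trials (600 s where slope
precision matters), one burst per 2 s — enough windows for every
reference configuration and tight enough seeds for deterministic
assertions.  Slope-recovery assertions compare the pooled estimate
against the inverse-variance-weighted mean of the programmed per-subject
slopes (the estimand of the pooled statistic); per-burst spectral noise
makes single-subject slopes a few times noisier.

## Known limitations

- Fixed-effect pooling with plug-in variances understates uncertainty on
  overlapping windows (see above) and ignores between-subject
  heterogeneity by design.
- GFD zone thresholds are a statistical convention (quartile/median), not
  a physiologically validated boundary.
- The classifier's headline accuracy on synthetic cohorts reflects the
  programmed class separation; real-data accuracy depends on calibration
  quality and inter-subject transfer, neither of which synthetic data can
  certify.
- Streaming feature extraction approximates `feature2` with a
  trailing-window difference; very short windows make it noisy.
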
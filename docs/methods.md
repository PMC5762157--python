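# Methods

This note documents the models, parameter choices and numerical conventions
behind `songeval`, including the places where the design was genuinely open
and what the synthetic generator does and does not emulate.

## Acoustic features

Spectrograms use a Hann window of 9.27 ms with 7.91 ms overlap (frame step
1.36 ms) and magnitude-squared scaling; the defaults assume 44.1 kHz mono
PCM (16-bit when written to disk), matching the conventions of the song
analysis tools these features emulate.  The sample rate and FFT length are
configuration, not constraints.

Per-frame features (all defined on the power spectrogram *P(f, t)*):

- **Wiener entropy** = mean(log P) − log(mean P) over frequency; exactly 0
  for a flat (noise-like) spectrum, strongly negative for tonal frames,
  floored at −15 log units (silent frames are floored and logged).
- **Amplitude modulation** = d log(total power)/dt (centered differences).
- **Frequency modulation** = arctan2(rms_t, rms_f), where rms_t and rms_f
  are the power-weighted RMS of the temporal and spectral gradients of log
  power, each expressed per grid step so the two axes are dimensionless.
  Power weighting keeps near-silent bins (whose log power fluctuates
  wildly) from dominating; without it a pure stationary tone reads as
  maximally frequency-modulated, which is clearly wrong.
- **Fundamental frequency / pitch goodness**: peak of the real cepstrum in
  the lag band corresponding to 300–8000 Hz; the peak height is the
  goodness.  Frames with goodness below a configurable threshold are
  flagged unvoiced but keep their best-lag F0 value.
- **Center frequency**: power-weighted mean frequency.
- **max FM within frequency / max AM across power**: per-frame maxima of
  bin-wise temporal derivatives — of log-power for the FM variant, and of
  power normalized by total frame power for the AM variant.  These are the
  most literal reading of "maximum modulation within each frequency".

Gain dependence: only total power and its derivative scale with input
gain; every other feature is gain-invariant (tested at ×10 amplitude).

The 101-entry summary vector is 10 statistics × 10 features + duration.
Percent-indexed windows (onset 1–3%, middle 49–51%, offset 97–100%) round
inclusively to the nearest frame with a minimum of one frame, so short
syllables never produce empty windows.  Single-frame tracks set sd and the
trend correlation to 0 (flagged).

## Distances, the dissimilarity index, and clustering

Summary-vector distances are Euclidean after z-scoring each of the 101
dimensions across the syllable set (the dimensions mix Hz, log units and
seconds; unstandardized distance would be dominated by frequency-scaled
entries).  Zero-variance dimensions are dropped.

DTW runs over five tracks (Wiener entropy, FM, AM, F0, pitch goodness),
each divided by its pooled across-frame standard deviation over the whole
collection.  The frame cost is the Euclidean distance in this normalized
space; every non-diagonal step adds the warping penalty.  The default
penalty of 0.6 (in pooled-z cost units) was calibrated once on synthetic
data as the smallest round value that kept within-type DTW distances below
cross-type distances for default repertoires; it is exposed in
configuration.  The DP kernel is numba-compiled; the test suite checks it
against exhaustive enumeration of all monotone alignment paths on short
tracks.

Each channel is converted to percentile ranks over all pairs (mid-rank
ties, values (rank − ½)/n_pairs, so an all-tied channel collapses to 0.5),
and the two channels are fused by the element-wise geometric mean.

The dissimilarity index for a pair (i, j) is 1 − Pearson correlation
between rows i and j of the combined matrix, in [0, 2].  Two conventions
were open:

- *Row-wise vs vectorized correlation*: row-wise is implemented (each
  syllable is characterized by its distance profile to all syllables).
- *Structural entries*: for each pair, the two entries at positions i and j
  (the zero diagonal and the pair's own distance) are excluded from the
  correlation, via a closed-form masked-correlation identity.  Without
  this exclusion a rendition with a profile identical to a tutor syllable
  scores slightly above 0, because the mismatched diagonal zeros
  decorrelate otherwise identical rows; with it, identical profiles give
  exactly 0 and perfectly anticorrelated profiles exactly 2.

Zero-variance profiles leave the correlation undefined; affected pairs are
flagged NaN and logged.

Clustering is complete-linkage agglomerative on the index, cut at a
configured k (4–25 by default; smaller k is allowed explicitly for tests
and two-type demonstrations).  The source procedure's manual curation is
replaced by two declarative mechanisms: a merge list (groups of type
labels to merge) and a quality threshold (clusters whose scatter — mean
member-to-medoid index — exceeds the threshold are rejected, their members
marked UNCLASSIFIED).  Because the index is not embeddable in a vector
space, "cluster center" means the medoid under the index, both for
prototypicality and scatter.

Tutor similarity is computed on a joint matrix over tutors ∪ renditions
(the index needs a common row space) as the minimum index to any tutor
syllable; the closest-to-each-rendition definition is used.  The median
split labels the lower-distance half "high" (similarity); with an odd
count the extra rendition goes to "high".  Recordings with fewer than 40
classified renditions are excluded from similarity analyses.

## Spike metrics

Intervals are half-open [onset, offset) everywhere, times in seconds from
session start.  Episodes split at silent gaps ≥ 300 ms (a gap of exactly
300 ms splits).  Baselines are maximal silent intervals trimmed by a 2 s
guard on both sides with ≥ 2 s remaining.  The local baseline for an
episode is the mean rate over the two baseline periods nearest in time.

Response strength is read as the paired t statistic: the printed-formula
denominator is the standard error of the paired difference,
√[(Var S + Var B − 2 Cov)/n]; the suite fuzz-checks equality with an
independently coded paired t.  The burst-fraction denominator is the
number of ISIs (not spikes), computed only between consecutive spikes
inside the same interval; this convention is configurable.  CV uses the
sample standard deviation (n − 1), which reproduces the worked
convention sd(5, 10, 15)/10 = 0.5; neurons with zero mean rate are
excluded from CV analyses.

## Population statistics

PSTHs use ±200 ms around syllable onsets in 2 ms bins; each neuron's trace
is mean-subtracted (its bin mean is exactly zero before smoothing) and
smoothed with a Gaussian kernel.  "40 ms smoothing" is interpreted as the
kernel FWHM (σ ≈ 17 ms); the width convention is configurable.  Per-bin
significance uses the two-tailed t critical value with (neurons − 1)
degrees of freedom on the population mean ± sem — pointwise and
uncorrected, mirroring the per-bin confidence bars of the source analysis;
smoothing correlates neighbouring bins, so significant bins appear in
contiguous blocks and any family-wise statement needs an explicit
correction.

Regressions reverse the 0–2 distance score to a similarity axis
(2 − score) before correlating, so a positive slope always means higher
firing for more tutor-similar renditions.  The permutation test shuffles
the rate-similarity pairing 1000 times; a neuron is significant when its
actual r falls outside the [.025, .975] percentiles of its own null.  The
population significant fraction averages the per-repeat flagged fraction
over 20 independent repeats (the repeat count is not prescribed by the
source procedure; 20 keeps the Monte-Carlo error of the fraction below a
percentage point at 200 neurons).  The mixed-effects association delegates
to statsmodels MixedLM with a random intercept per neuron and a random +
fixed slope for similarity; on non-convergence it falls back to a
one-sample t on per-neuron r values and says so in its return value.

## Development staging

The exponential is fit by maximum likelihood (rate = 1/mean) and the
statistic is the KS sup-distance against the fitted CDF — the Lilliefors
setting, since the parameter is estimated from the same sample; only the
statistic is used as an index, never a p-value, so no null table is
needed.  "Scaled by the number of syllables" is ambiguous (×n vs ×√n); the
default is ×√n, the conventional n-normalization of the statistic, keeping
sessions of 500–8000 syllables comparable, with ×n available by
configuration.  The unscaled statistic is scale-equivariant: multiplying
all durations by a constant leaves it unchanged.

## The synthetic generator

The source study records real birds and specifies no generative model, so
every distributional choice here is an artifact decision, fixed once:

- **Templates**: k tutor syllables drawn by rejection sampling with a
  minimum pairwise separation (0.45) in normalized (log-F0, sweep,
  duration, noisiness) space; F0 500–2400 Hz, sweeps ±0.6 octaves,
  durations 60–250 ms, noise fractions 0.05–0.55, 2–6 harmonics.
- **Renditions**: distortion level δ ≥ 0 scales smooth multiplicative F0
  and envelope jitter, a log-uniform time-warp factor, a shift of the
  noise fraction, and (waveform tier) additive spectral noise.  δ = 0
  reproduces the template realization bit-exactly for a given seed, and
  measured tutor dissimilarity increases monotonically in δ.
- **Sessions**: syllable durations interpolate between Exp(mean 0.12 s)
  at stage 0 (subsong) and per-type Gaussians with 10% cv at stage 1
  (plastic song); within-bout gaps are lognormal with 60 ms median
  (capped below the 300 ms episode rule), bouts are geometric with mean 8
  syllables, and inter-bout silences of 6–14 s guarantee usable ≥ 2 s
  baselines.
- **Spikes**: inhomogeneous Poisson with within-syllable log-rate
  log(baseline × gain) + β(1 − normalized δ) plus optional rendition-level
  lognormal noise whose sd grows with δ (the variability coupling used in
  the CV analyses), an additive premotor ramp in a ≤ 200 ms lead window,
  and bursts inserted as 4 ms doublets with a configurable probability —
  a deliberately simple mechanism that makes the burst fraction sensitive
  to one parameter.

Two fidelity tiers exist on purpose: the fast tier emits feature tracks
directly (features exactly controllable; used by most tests), the slow
tier synthesizes waveforms so the feature extractor is exercised end to
end.  The generator does **not** emulate realistic zebra-finch vocal-tract
acoustics, calls vs song, cage noise, spike-sorting artifacts, or
non-Poisson history dependence beyond doublet bursts — so passing tests
demonstrate correctness and calibration of the analysis chain under the
stated model, not robustness to every property of real recordings.

## Calibration, recovery and problem sizes

The end-to-end checks run at sizes chosen to keep Monte-Carlo error small
while remaining quick on one CPU: null calibration uses 200 synthetic
neurons per procedure (flagged fraction compared against the exact
binomial 95% interval at α = 0.05); PSTH bin calibration pools 30
independent 12-neuron null populations and uses a pre-chosen conservative
band [0.02, 0.08], because smoothing correlates neighbouring bins and a
naive per-bin binomial interval would be wrong.  Sign recovery of the
rate-similarity coupling uses |β| = 0.8 at 200 renditions — the package's
documented detectability point from a design-time power measurement (at
baseline 6 spikes/s, gain 2 and ~170 ms windows, |β| = 0.5 sits at the
edge of reliable sign recovery; 0.8 is comfortably above it).  The
distortion-similarity monotonicity check uses a 4-point δ grid with 50
renditions per point.

## Known limitations

- The feature definitions are SAP-style, not numerically identical to any
  specific external implementation; cross-tool comparisons should expect
  rank-level, not value-level, agreement.
- The dissimilarity index depends on the syllable set through the
  percentile normalization and row correlations; scores are comparable
  within one joint matrix, not across sessions.
- Automatic choice of the number of types k is out of scope beyond the
  scatter-based quality threshold; k is a configuration decision.
- The mixed-model wrapper exposes only the stated random-intercept +
  random-slope structure (plus an intercept-only option); other covariance
  structures are out of scope.
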
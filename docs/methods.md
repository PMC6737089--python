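# Methods

This note documents the models, estimators, numerical choices and
limitations behind avakit. It covers what each stage assumes, which knobs
matter, what the synthetic generators do and do not emulate, and where the
design was genuinely open.

## Fluorescence processing

**ΔF/F baseline.** F0(t) is computed causally: for each frame, take the
trailing 10-s window (300 frames at 30 Hz, including the current frame),
find its 50th percentile, and average the samples *strictly below* it.
Frames earlier than one full window use the partial available history, so
trace and raster lengths match. If no sample is strictly below the median
(a flat window), F0 falls back to the *window median*: for a constant or
sparsely active trace the median equals the quiescent level exactly, which
keeps ΔF/F ≡ 0 on constant traces and makes the neuropil correction an
exact inverse on noiseless sparse traces (a window mean would be biased
upward by transients). ΔF/F is scale-invariant by construction and *not*
shift-invariant: adding a constant c maps dff → dff·F0/(F0+c), a relation
the tests assert exactly.

**Neuropil correction** subtracts α_NP × (ΔF/F)_neuropil from the soma
ΔF/F, with α_NP = 0.9 by default (configurable).

**Responsiveness.** One-way ANOVA per neuron across one pooled baseline
group (mean ΔF/F over each trial's pre-stimulus window, window length equal
to that trial's stimulus duration) plus one group per frequency × level
condition (mean ΔF/F over the stimulus window, one value per repeat);
responsive iff p < 0.01. The grouping granularity was an open choice; the
per-condition grouping is the finest partition consistent with comparing
baseline against all sound-presentation periods. Zero-variance neurons are
classified not-responsive. Under pure-noise traces the responsive fraction
calibrates to the nominal p (tested at 3 binomial SDs).

**λ threshold.** λ_thr is chosen per experiment to maximize the number of
extracted ensembles over a candidate grid (default: 40 quantiles of the
nonzero λ values, which adapts to any λ scale). Ties break to the smallest
maximizing threshold (retains more activity). The full count-vs-threshold
curve is reported; unimodality is not asserted — too-low and too-high
thresholds both reduce counts but plateaus happen. Whether to optimize
jointly over ongoing + evoked frames or separately was open; the default
optimizes jointly over the whole session.

## Ensembles

A binary raster is segmented into maximal runs of frames with ≥ 1 active
neuron. "Active" is binary per frame (λ ≥ λ_thr counts once); multiple
inferred spikes within a frame are not multiply counted. Size is the sum of
active neuron-frames; duration the frame span. Ensembles touching either
recording boundary are kept but flagged `truncated`. Evoked ensembles are
those *initiated* during a 1-s stimulus window — an ensemble starting on
the last stimulus frame and running 2 s longer is still evoked; one
starting one frame before onset is ongoing. An ensemble spanning two
stimuli is assigned to the trial containing its start frame. The extraction
is verified exactly against a naive frame-walking oracle on 10^3 random
rasters, and sizes partition the total active neuron-frames exactly.

**Shuffle null.** Each neuron's λ trace is permuted independently in time
— per-neuron rates and value multisets are preserved exactly — the raster
is re-thresholded at the original λ_thr, and of 10 repeats the one with the
most ensembles is kept (a conservative choice for the null).

## Heavy-tailed model selection

Sizes and durations are integer counts, so both candidate models are
discrete (the continuous-vs-discrete choice was open): the power law
P(x) = x^α / ζ(−α, x_min) and the geometric law
P(x) = (1−q)·q^(x−x_min). The power-law MLE maximizes the zeta-normalized
likelihood numerically; the geometric MLE is closed-form from the mean.
LLR = log L_PL − log L_exp is stored as exactly the difference of the two
reported log-likelihoods; its significance is a Vuong-style two-sided
normal test on the normalized per-observation log-likelihood differences.
x_min is fixed at 1 (the minimum observable size) rather than estimated —
whole distributions are fitted — but is configurable for sensitivity
analysis.

The KS slope estimator scans α over [−4.00, −1.01] in 0.01 steps (covering
all slopes the analysis targets) and minimizes the sup-distance between
the empirical CDF and the discrete power-law CDF. Both are step functions
jumping at the same integers, so the supremum is evaluated at observed
values only; comparing against empirical left limits (the continuous-case
convention) would inflate D by ≈ P(x_min) and is deliberately avoided.
With n = 10^5 samples from the truncated sampler the KS estimator recovers
generating exponents in [−3, −1.5] to within ±0.005 (mean over seeds), and
the MLE agrees with an independent zipf-likelihood grid search within 0.02.

## Scaling collapse

For each candidate b in [−0.5, 0.5] (step 0.001), every level's log-binned
compensated density (x = s·L^b, y = P(s)·s^|α|) is interpolated in log-x
onto the common overlapping support and scored by the mean over level pairs
of squared log-density differences. Three numerical choices make the
argmin well identified; the error metric itself was open (only "the error
between the three sound level distributions" is specified anywhere) and is
isolated behind one function:

1. **Offset invariance (default).** A pure rescaling s → s·L^b shifts each
   level's compensated curve by a constant log-offset (factor
   L^{b(|α|−1)}), so the default removes each pair's mean log-difference
   before scoring, measuring shape mismatch only. The plain MSE variant is
   available via `offset_invariant=False`.
2. **Minimum bin occupancy.** Bins with fewer than 5 observations are
   excluded; their log-densities fluctuate by factors of 2–3 and otherwise
   dominate the score.
3. **Inverse-variance weighting.** Remaining discrepancies are weighted by
   the harmonic mean of the two bins' counts (the inverse sampling variance
   of a log-density difference, up to a constant).

With these, i.i.d. same-distribution levels give |b̂| ≤ 0.01 and a
constructed s·L^0.2 rescaling is recovered exactly at b̂ = −0.2; without
them the unweighted score wanders by up to ±0.2 under resampling. Ties in
the scan resolve to the b closest to 0; a single level is degenerate and
returns b̂ = 0 with a flag.

## Receptive fields and ensemble tuning

The RF is the mean ΔF/F per frequency × level condition over the 1-s
stimulus window and repeats (negative responses permitted). BF is the RF
center of mass in log2-frequency with negative responses rectified to zero
first — the log axis matches the octave-spaced stimuli, and rectification
prevents suppression from pulling the center of mass (signed mode is
available; both the axis and rectification were open choices). The
ensemble RF is the member RFs averaged with weights equal to frames
active, so it is a convex combination of member fields; IQR_BF is the
interquartile range of member BFs in octaves, unweighted and one entry per
member. Bandwidth — no formula is standard — defaults to the half-maximum
width in octaves of the level row containing the global RF peak, with
linear interpolation at the crossings; a single-frequency response has no
crossing and reports 0 octaves with a point-support flag. The definition
lives behind one configurable function. For identically tuned members the
ensemble bandwidth equals the single-member bandwidth exactly — the
testable core of selectivity scale-invariance.

## Population statistics

Rates and CV_ISI are computed from the *binarized* raster (≤ 1 spike per
frame), consistent with how ensembles count activity; ISIs are consecutive
active-frame differences × Δt with no sub-frame inference, so for
Bernoulli(p)-per-frame spiking CV_ISI → √(1−p) (geometric closed form,
tested). λ magnitudes are deliberately not used for rates. Pairwise
correlation is the zero-lag Pearson correlation of the *continuous* λ
traces over the whole session; constant-λ neurons are excluded and flagged.
Two-sample comparisons use the Wilcoxon rank-sum test (normal approximation
with tie correction; checked against exact enumeration at small n).
Evoked-condition rates are computed within stimulus windows (configurable
via the frame mask; whole-trial windows were the alternative). When a rate
mask is non-contiguous, ISIs are measured on the concatenated masked
frames — a simplification that slightly deflates CV at mask boundaries.

## Synthetic data: what it emulates, what it does not

The generators reproduce the statistical structure the analysis assumes:
~10^2 neurons at 30 Hz; avalanche-structured correlations via a critical
branching process (external drive Poisson(0.02)/frame, each active neuron
spawning Poisson(σ) uniformly chosen targets next frame, σ = 1 default);
9 log-spaced tone frequencies (3–48 kHz, 2/octave) × 3 levels
(40/60/80 dB SPL) × 5 repeats of 1-s stimuli with 4–6 s ISIs; Gaussian
log-frequency tuning with level-dependent gain; and a fluorescence forward
model (exponential kernel, default τ = 0.7 s truncated at 5τ, 0.25 ΔF/F
per spike, multiplicative neuropil contamination, Gaussian noise). The
drive rate 0.02 events/frame keeps active and silent epochs roughly
balanced for a few hundred neurons at criticality (mean avalanche lifetime
O(√N) frames), so avalanches stay separable; it is a modeling choice, not
a fitted quantity.

In the full-session generator, tones act by injecting *extra drive into
the same critical cascade* (default 0.05/0.1/0.2 events/frame for
40/60/80 dB), targeted at neurons with probability proportional to the
tuning kernel around each neuron's BF. Consequently evoked ensembles
inherit cascade (power-law) statistics while their mean size and duration
grow with level, and evoked avalanches preferentially recruit neurons
tuned near the stimulus — the phenomenology the analysis is designed to
detect. An additive tuned-Bernoulli design was tried first and rejected:
independent extra spikes impose a characteristic scale and push evoked
size distributions toward exponentials.

Not emulated: raw 2-photon frames, motion artifacts, ROI segmentation,
spike-deconvolution noise (the λ jitter option is an implementation
convenience for threshold-search tests, not a model of deconvolution
output), pupil-linked state changes, or realistic per-neuron firing-rate
heterogeneity. Passing tests therefore certify the *analysis chain* —
extraction, fitting, nulls, tuning metrics — under controlled ground
truth, not the biology of any particular dataset. Note also that with
binary synthetic λ the printed cortical rates (~1.8 spikes/s over ~10^2
neurons) would leave no silent frames at all; rate calibration is
therefore tested on Bernoulli rasters, while avalanche-structured rasters
run at the lower effective rates the branching process produces.

## Determinism and problem sizes

Every stochastic operation takes one explicit integer seed (numpy
`default_rng`/`SeedSequence`; children spawned per stage), no global state
is touched, and identical config + seed reproduces pipeline reports
byte-for-byte (timestamps are never written). Default analysis scales were
chosen to make sampling error negligible relative to the tolerances they
are checked against: slope recovery uses n = 10^5 samples × 20 seeds
(estimator SD ≈ 0.005 per seed); the shuffle control uses 512 neurons ×
2×10^5 frames × 10 seeds (thousands of avalanches per seed); collapse
scans use n = 10^5 per level; the synthetic demo session uses ~10^2
neurons and a 135-trial protocol (~13 min of session time) and completes
in well under ten minutes on one CPU.

## Known limitations

* x_min is fixed, not estimated; heavy subsampling or non-stationarity can
  bend small-s behavior and bias whole-distribution slopes.
* The Vuong normal approximation for LLR significance is asymptotic;
  p-values at n < ~100 are indicative only (the fitters warn below 50
  observations).
* The branching simulator collapses coincident activations (a neuron
  spikes at most once per frame), so σ is the *offspring* parameter, not
  the realized branching ratio, which dips slightly below σ at high
  activity.
* Ensemble merging: at high drive or during loud stimuli, distinct
  cascades can fuse into one ensemble; this is a property of the
  silence-bounded definition itself, shared with the analysis of real
  data.
* The size–duration scaling exponent (crackling-noise relation) and
  avalanche shape analyses are out of scope.
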
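# Methods

This note records the models, numerical choices, and design decisions
behind `premove`, and what the synthetic benchmark does and does not show.

## Decoding model

The decoder is a linear discriminant on features of a short stimulus-locked
EEG window. Two signal classes carry the hand information:

* **Lateralized oscillatory power.** Preparation of a hand movement
  desynchronizes 10–25 Hz activity over the contralateral sensorimotor
  cortex and (relatively) synchronizes it ipsilaterally. Band power is a
  variance phenomenon, captured by the per-component *variance* features.
* **Slow potential bias.** A small, spatially lateralized DC shift around
  stimulus onset biases the upcoming choice; a mean-level phenomenon,
  captured by the per-component *mean* features.

ICA features (recommended backend): the average training epoch is
subtracted from every trial, residuals are PCA-whitened to M = 30
dimensions, and symmetric fixed-point ICA with the tanh contrast estimates
the demixing W. For trial x and component k the features are
`mean_t (W K x)_k` and `mean_t ((W K (x − evoked))_k²)`. The variance uses
1/N normalization: the template-subtracted component is treated as
zero-mean, so the variance is the mean of squares with no per-trial
recentering. Feature order is [means(1..M), variances(1..M)].

The classifier minimizes `mean_i log(1 + exp(−y_i f(x_i))) + λ·P(w)` with
P the L1 norm (ICA features) or `½‖w‖²` (spatiotemporal-PCA features), the
intercept unpenalized, y ∈ {−1 (left), +1 (right)}. λ is chosen by 5-fold
stratified cross-validation over 30 geometrically spaced values in
`[1e-5/n, 1e5/n]`; ties in CV loss resolve to the **largest** λ
(parsimony). Features are standardized with training statistics before
fitting (required for penalty comparability across mean- and
variance-scaled features; stored in the model, making the pipeline
scale-equivariant). The solver is SAGA via scikit-learn with
`C = 1/(n·λ)`, which optimizes exactly this objective; any convergent
convex solver would reach the same minimizer, and the test suite checks the
coefficients against an independent full-batch proximal-gradient optimizer.

## Windows

Analysis windows are **half-open** `[start, end)` in milliseconds relative
to stimulus onset. This makes the causal contract of the pre-visual mode
exact: a (−150, 0) ms window touches no sample at t ≥ 0, which the test
suite audits by perturbation. At 1 kHz the convention costs one sample
relative to an inclusive reading.

The window grid anchors every size (600, 500, 400, 300, 200, 150, 100,
50 ms) at −550 ms and shifts it in 100 ms steps while the end stays within
+150 ms; a 600 ms window therefore has exactly two positions. The window
search shares its shuffle seeds (balanced 80/20 splits) across windows — a
paired comparison that stabilizes the argmax at no extra cost.

## Feature-ICA operator order

Evoked subtraction happens *before* the compression statistics are
estimated: the PCA whitening is computed from the evoked-subtracted
residuals, then ICA runs on the compressed residuals. All operators are
linear, so compression and template subtraction commute in the transform
chain; estimating the compression from residuals makes the extractor
exactly invariant to any waveform added to every training trial (the
property evoked subtraction exists to provide). The effective component
count is `min(30, n_channels)`, further clipped to the empirical data rank
— average-referenced data (rank C−1) automatically loses one dimension.

## FastICA convergence policy

Symmetric FastICA declares convergence only when *every* component
stabilizes. EEG background is close to Gaussian, and the Gaussian subspace
is rotation-indeterminate, so the global criterion is routinely unreachable
even though the identifiable non-Gaussian components (blinks, planted
sources) stabilize within tens of iterations — and downstream results do
not depend on rotations inside the Gaussian subspace (the classifier
relearns weights in any basis). Defaults are therefore tol 1e-4, max_iter
200, one restart with a fresh seed, and on exhaustion the final estimate is
kept with a warning; `strict=True` raises instead. Fits are deterministic
given the seed. The artifact-cleaning ICA may additionally subsample the
pre-stimulus samples it is fitted on (`fit_decim`, default 4 in the
pipeline config) — neighboring samples are strongly autocorrelated and the
spatial patterns are unaffected; the transform is always applied at full
resolution.

## Preprocessing choices

* Filter orders scale with the sampling rate: ~1 s of taps for the 1 Hz
  high-pass, ~0.1 s for the 45 Hz low-pass, preserving transition-band
  behavior across rates. The high-pass kernel is built as
  delta − low-pass, so its DC gain is exactly zero even when the kernel is
  short relative to 1/cutoff. Filtering is zero-phase: forward application
  of the linear-phase kernel with group-delay compensation,
  zero-padding at the edges (≈ half a kernel of edge transient).
* Rejection replaces interactive visual inspection with a robust-z rule:
  per-channel and per-trial log-variance of the **pre-stimulus segment
  only**, median/MAD z-score, threshold 3.5 (configurable), plus an
  unconditional exclusion list for peripheral electrodes (default empty;
  site-specific).
* Baseline correction subtracts the mean of the entire −2.5…0 s segment
  per channel and trial.
* Ocular components are auto-flagged when a component's channel pattern
  loads maximally on the most anterior channel pair (AFp1/AFp2 when
  present) and its time course has excess kurtosis above 3.
* EMG movement onset: 20 Hz high-pass, rectification, 10 Hz low-pass;
  onset is the first post-stimulus sample where the envelope exceeds 50% of
  its post-stimulus maximum; flat EMG returns a no-movement sentinel.

## Channel selection and ranking

Forward selection scores each candidate set by the cross-validated accuracy
of the ICA-feature classifier on the training trials. Block additions (+1
up to 5 channels, +3 up to 30, +5 afterwards, final block truncated) are
realized as nested single-channel greedy steps — evaluating all triples is
combinatorial, nesting preserves the evaluated set sizes at O(blocks ×
channels) cost — so the selection order is the full greedy permutation with
accuracies recorded at the block checkpoints. Ties break lexicographically
by channel name. Ranks map to points (#1–5 → 5, #6–15 → 3, #16–30 → 2,
#31–50 → 1, >50 → 0); group aggregation sums subject points with mean
imputation for channels a subject lacks and normalizes to 0–100. The
shipped 32-channel montage (`premove/data/montage32.txt`) is a synthetic
stand-in: a sensorimotor-centered 10-5 subset plus the CPz reference,
editable as plain text.

## Interpretation

The topography ν forward-projects the mean-feature discriminant through
the ICA mixing and PCA decompression operators (standardization undone):
ν = D·A·(w_mean/σ). Its scale is arbitrary; the sign is fixed so the
left-hemisphere channel of maximum magnitude is positive for right-hand
evidence. A covariance-based activation pattern (Σ_x̄ · filter) is available
as `mode="covariance"`. Time–frequency maps use Morlet wavelets of 7
cycles, 2–40 Hz; power is the squared magnitude of the analytic
convolution, samples within ±5σ_t of the epoch edge are masked, and the
contrast `(X₁−X₂)/(X₁+X₂)` is bounded in [−1, 1] (a 2:1 power ratio maps
to 1/3). Minimum-norm inversion uses `Gᵀ(GGᵀ + reg·I)⁻¹ν` with free
orientations and default reg 1e-16 — near-unregularized by design, with a
configurable override; per-source amplitude is the norm over the three
orientation coefficients. The default hemisphere channel sets are the
6-channel C1/C2 neighborhoods, with 4-channel variants available.

## Real-time simulation

Calibration uses each class's first `n` trials; every trial after the last
calibration index is classified in chronological order with no reshuffling
or rebalancing — trials of the earlier-completed class interleaved before
that index are not tested. All data-dependent operators (feature model,
standardization, classifier) are frozen at calibration. Streams with fewer
than 25 testable trials are flagged excluded. Both plain and balanced
accuracy are reported because the test stream need not be balanced.

## Synthetic sessions

The generator emulates: uniform 2.5–3.5 s inter-stimulus jitter on top of a
1.2 s post-trial dwell; two-state Markov hand choices (first draw P(R) =
`p_right`, stay probability `p_stay`); 1/f background (10 µV RMS) plus an
ongoing ~10 Hz posterior oscillation (4 µV); hemisphere-specific 10–25 Hz
carriers (6 µV at the topography peak) whose amplitude is modulated
multiplicatively in the effect window — gain 1 ∓ d contralateral/
ipsilateral with depth `d = min(0.9, 0.4·effect_snr)`; a slow shift of
`slow_shift_uV · effect_snr` (default 5 µV at SNR 1) with hand-dependent
sign through the difference of two Gaussian topographies centered on C1 and
C2 (fallback: the most lateral frontocentral pair, with a warning);
Poisson blinks (default 6/min, 80 µV, frontal topography); EMG bursts from
movement onset (lognormal latency, median 300 ms, log-sd 0.35). Everything
injected is returned as ground truth. `effect_snr` is a free simulation
parameter — the real-data effect size is not known in raw-EEG units — so
absolute accuracies on synthetic sessions calibrate nothing; what the
benchmark establishes is *relative* behavior: chance-level decoding at SNR
0 (type-I control), monotone accuracy in SNR, and recovery of planted
structure (channels, windows, topographies).

Not emulated: volume-conduction-realistic mixing (a head model is replaced
by smooth Gaussian topographies and, for source localization, a smooth
random leadfield), non-stationarities such as drowsiness or electrode
drift, realistic EMG physiology, and line noise. Passing tests therefore
demonstrate correctness of the algorithms under the stated statistical
structure, not expected field performance on real recordings.

## Problem sizes in tests and the acceptance script

Sessions of 200 trials at 250 Hz (10–25 Hz content sits far below
Nyquist), with the default 32-channel montage + CPz, stand in for
full-length 1080-trial 1 kHz sessions in the end-to-end checks; structure
recovery uses 100–120-trial constructed epoch sets with 6–20 channels, and
repeat counts of 8–20 per property. The generator's defaults remain the
full study conditions (1080 trials, 1 kHz, 5 kHz optional input to
exercise resampling).

## Known limitations

* The greedy selection's CV-accuracy objective is noisy at small trial
  counts; rankings below the first ~10 channels are not individually
  meaningful (the point bands absorb this).
* With `reg = 1e-16` the minimum-norm inverse is effectively unregularized
  and amplifies noise in ν; the parameter is exposed.
* The SVM (hinge) learner is provided for comparison only and uses the L2
  penalty regardless of the requested one.
* Streaming hardware concerns (amplifier latency, filter-delay
  compensation) are out of scope; the real-time mode is a causal replay.
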
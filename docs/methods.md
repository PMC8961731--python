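# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limitations of the `eegmanifold` pipeline.

## Problem setting

Five visual stimuli (digits 1–5) are decoded from multichannel EEG at the
single-trial level.  Each trial is rest → stimulus → rest.  Physiologically,
the stimulus raises alpha-band (8–15 Hz) power, predominantly over frontal
and occipital electrodes and only during the early part of the stimulus,
and lowers delta-band power.  Decoding therefore proceeds from alpha-band
power features of short epochs cut from the early stimulus window.

## Synthetic sessions

No public recording of this paradigm exists, so the generator is part of
the package's contract rather than a test fixture.  Per trial it synthesizes:

* ongoing rhythms: fixed-amplitude sinusoids at 2.5, 6, 10 and 20 Hz
  (amplitudes 1.5, 0.8, 1.0, 0.5 in arbitrary microvolt-scale units) with
  per-trial, per-channel random phase;
* 1/f^β background noise (β = `noise_exponent`, default 1) by spectral
  shaping of white noise, RMS 0.5·`noise_level`;
* during the stimulus, the delta sinusoid's amplitude is multiplied by
  `delta_attenuation` (default 0.7);
* during the responsive window (the first `response_fraction` of the
  stimulus, default 1/3 — matching an oscillation that persists ~10 s of a
  30-s stimulus), a **class-specific alpha carrier**: a narrowband (±0.5 Hz)
  stochastic oscillation at the class's carrier frequency (evenly spaced
  over 8.5–14.5 Hz), *coherent across channels* and scaled per channel by
  the class's spatial weight vector.

The carrier amplitude is `snr·√(alpha_gain²−1)·a₀·w_c` on top of the
baseline alpha amplitude `a₀`, so in a fully weighted channel the
stimulus/rest alpha power ratio is exactly `alpha_gain²` before noise
dilution; `snr=0` removes every class-specific component while leaving the
background untouched.  Spatial weights are uniform draws per channel with a
fraction `responsive_mass` (default 0.8) of total weight mass on
frontal+occipital channels (`responsive_mass=1` confines the signal
entirely); distinctness across classes is enforced (pairwise cosine
similarity < 0.95).  A narrowband *stochastic* carrier was chosen over a
pure tone for two reasons: real cortical alpha is band-limited noise, not a
sinusoid, and the AR spectrum of a pure tone is a needle whose height a
0.5-Hz evaluation grid samples erratically.  Channel coherence makes the
per-epoch power fluctuation a common factor across channels, preserving the
spatial pattern direction that carries the class information.

What the generator does **not** emulate: volume conduction and realistic
channel covariance, eye-blink/EMG artifacts, inter-subject variability,
non-stationary baseline drift.  Passing tests therefore demonstrate that
the pipeline recovers planted spatial-spectral structure at realistic SNR —
not that it would reach any particular accuracy on real recordings.

Defaults mirror the emulated study conditions (64 channels, 1 kHz, 30-s
stimuli, 30-s flanking rests giving 60 s between stimuli).  Tests, examples
and the acceptance script run scaled sessions — 200 Hz, 4-s stimuli whose
alpha response spans the whole decode window, 2-s rests, 10–20 trials per
class — chosen so a full pipeline run takes seconds while keeping every
structural property (montage, trial structure, epoch counts per trial,
class count) intact.

## Spectral estimation

AR coefficients are estimated by the Burg recursion (forward+backward
prediction error minimization through reflection coefficients), which is
stable by construction; epochs are mean-detrended first.  Default order 16
for 1-s epochs — common EEG practice at this bandwidth; exposed everywhere.
The parametric density uses the convention `P(f) = σ²/(fs·|A(f)|²)` — a
two-sided density evaluated on [0, fs/2], so AR(0) with σ²=1 is flat at
1/fs and the process variance is `2∫₀^{fs/2} P df` (`integrated_power`).
Only band means and ratios are consumed downstream, so the convention is
internal but fixed.  Band power is the mean of `P(f)` on a 0.5-Hz grid over
the band.  **The AR model is always fitted on the broadband (0.1–50 Hz)
epoch**, not on a band-limited copy: a pre-filtered 8–15 Hz signal has a
quasi-line spectrum whose needle peaks the coarse grid hits or misses
erratically, which destroys feature stability.  The subband split exists
for band-power reporting and visualization.

## Latent factors

PCA is mean-centered SVD; explained-variance fractions and the cumulative
curve ride along in the embedding's params.  t-SNE is implemented from
scratch: σᵢ by binary search until each conditional's perplexity matches
the target within 1e−3 (default perplexity 30, capped at (n−1)/3);
symmetrized joint `p_ij = (p_{j|i}+p_{i|j})/(2N)` with degenerate distances
floored at 1e−12 and exact duplicate rows jittered (warned); Student-t
(1 d.f.) low-dimensional kernel; optimization by gradient descent with
momentum 0.5→0.8 at iteration 250, learning rate 200, early exaggeration
×4 for 100 iterations, per-coordinate adaptive gains, and deterministic
PCA initialization (scaled to 1e−4 s.d.) under the seed.  1,000 iterations
by default.  KL(P‖Q) is tracked and returned.

Feature path into t-SNE: per-epoch, per-channel alpha band power, smoothed
within each trial by a Gaussian kernel (σ = 1 epoch) — no leakage across
trials.  The PCA decoding path instead projects the multichannel epoch
signal onto the two leading *spatial* PCs and uses the alpha band power of
the two projected series as a 2-D feature.

Manifold dynamics: cluster similarity is `1/(1+mean pairwise Euclidean
distance)` over the full cross product of two clusters (so two coincident
clusters score exactly their within-cluster value); trajectories are
time-ordered within trials, trials shorter than 3 points are dropped with a
log message, average paths are pointwise means after linear resampling to
100 points, and the closure metric is end-to-start distance divided by path
length.  The bifurcation projection is the partial correlation of each
state with reference A controlling for B (and vice versa), computed as the
correlation of residuals after least-squares removal of the conditioning
reference (with intercept).  The conditioning set is exactly the *other*
reference — a choice, since partial correlation is underdetermined without
one; a state identical to a reference maps to (1, 0), a zero-variance state
to a missing (NaN) point.  Note that an exact noise-free mixture
λA+(1−λ)B has partial correlation 1 with A for every λ>0; monotonicity in
λ is a property of noisy mixtures.

## Decoders

All four are numpy implementations behind `fit(X, y, groups)` /
`predict(X, groups)`.

**TSK fuzzy system.**  Antecedent centers from classical fuzzy c-means
(fuzzifier m=2, relative objective tolerance 1e−6, k-means++-style seeding
under the seed; K=1 degenerates to the data mean).  Widths are the
membership-weighted variances per dimension about each center, scaled by
`l` (default 1).  Normalized firing strengths are computed as a softmax of
log-memberships, which is exact and avoids underflow for far-away inputs.
The global consequent β_g solves a ridge least-squares problem (λ = 1e−6)
from the stacked design ρ(u) = [μ̃₁(u)(1,u), …, μ̃_K(u)(1,u)] onto one-hot
labels — the minimal objective consistent with a linear readout; with K=1
the model is exactly ridge multivariate linear regression.  K defaults to 5
rules for 2-D latent inputs.  Ties in the argmax decision go to the lowest
class index.  Rules export as IF–THEN text with linguistic labels (very
low … very high) assigned by center rank per input dimension.

**Naive Bayes.**  Gaussian class-conditionals per feature, frequencies as
priors, log-space posterior normalization, variance floor 1e−9 instead of
failure on constant features.

**Kalman filter.**  State = one-hot class vector, observation = latent
factors.  A and H by ridge-regularized least squares over training pairs
(A from consecutive within-trial state pairs; H's columns are effectively
the class-mean latent factors), Q and V as residual covariances with
eigenvalue clipping to stay PSD.  Because class labels are constant within
trials, the raw within-trial state residuals are zero and the fitted gain
would vanish, freezing the filter at its initial state — a process-noise
floor (`q_floor` = 0.01 on the diagonal) keeps the filter responsive.  The
gain is iterated to its steady state (fixed point of the Riccati
recursion) before decoding.  Each trial starts from y₀ = pinv(H) · (mean of
the first `n_init`=3 observations) — the state-space image of the
early-observation average, needed because state and observation dimensions
differ — and the trial label is the argmax of the time-averaged filtered
state, broadcast to the trial's epochs.  A class whose latent mean sits at
the origin satisfies H·e_c = 0 and is structurally unobservable; embedded
class clusters are essentially never centered at the origin, but it is a
known degeneracy of the one-hot formulation.

**LSTM.**  One cell (16 hidden units by default) with sigmoid gates and
tanh candidate, softmax readout on the final hidden state, full-batch
gradient descent with global gradient-norm clipping at 5 (learning rate
0.5, 150–200 epochs), deterministic initialization under the seed; forget
bias starts at 1.  The cell equations alone do not define a decoder — the
readout and training loop are this package's addition.  In cross-validation
each epoch is a length-1 sequence; within-trial sequences are supported
through the functional interface.

## Evaluation protocol

The decoding sample is one 1-s epoch (0.5-s overlap) from the early
stimulus window; trial labels broadcast to epochs.  Cross-validation is
stratified 10-fold repeated 10 times (tests and the acceptance script use
1–3 repeats), reporting the mean and s.d. of the repeats' fold averages and
a pooled confusion matrix.  t-SNE has no out-of-sample transform, so the
default protocol embeds all epochs once and splits folds afterwards — a
transductive protocol with a known leakage caveat: overlapping epochs of
one trial share noise, cluster together, and can leak the trial label
across folds even without any stimulus effect.  `groups=trial_ids`
(strict mode) keeps each trial's epochs in one fold and is what the
chance-level checks use; the leakage inflates accuracy only when epochs of
the same trial straddle folds, so planted-effect comparisons (gain sweeps,
lobe rankings) remain interpretable in the default mode.

The lobe analysis recomputes band-power features once (band power is
channel-local, so subsetting commutes with feature extraction), then
re-embeds and re-decodes per channel subset: 4 singles, 6 pairs, 4 triples.

## Known limitations

* The class-signature scheme (distinct carriers + distinct spatial
  patterns) is an assumption; nothing is known about the real
  class-conditional spectral differences between viewed digits.
* Transductive t-SNE evaluation overstates absolute accuracy; strict mode
  understates it for small sessions.  Both are reported deliberately.
* The Kalman decoder inherits the one-hot-state degeneracies noted above.
* ICA-based artifact removal is a pass-through hook; the pipeline has not
  been exercised on artifact-bearing real data.
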
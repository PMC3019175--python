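# Methods

## Encoding model

The package models an auditory neuron's spike train as a point process
whose conditional intensity is a static nonlinearity applied to a linear
functional of the recent stimulus and the cell's own recent spiking:

    λ(t) = f( b + Σ_{f,τ} k[f,τ] · x(t−τ, f) + Σ_{j=1..J} h_j · r(t−j) )

* `x` is the log-compressed stimulus spectrogram on a 3 ms × 20-channel
  grid covering 250–8000 Hz (defaults; configurable).
* `k` is the STRF over 20 lags (0–60 ms at 3 ms).  Stimulus history before
  stimulus onset is taken as silence (zero padding), and spike history
  never crosses trial boundaries.
* `h` has J = 5 coefficients (15 ms), modelling refractoriness and
  recovery as a multiplicative (log-additive) gain on the rate.
* `f` is the exponential by default.  A sub-exponential alternative
  (`exp(u)` for `u ≤ 0`, `1 + u + u²/2` for `u > 0`, C² at 0) is provided;
  both are convex with concave logarithm, which keeps the likelihood
  concave in all parameters, so the fitted optimum is global.

The continuous-time point-process log-likelihood is discretized to the
per-bin Poisson form `Σ n_t log(λ_t Δ) − λ_t Δ` with `Δ` the bin width in
seconds and the convention `0·log 0 = 0`.  At 3 ms bins multi-spike bins
are rare; the count-weighted form handles them when they occur.

### Sparse prior and optimization

The penalized objective is `L(θ) − η‖k‖₁` (the offset and the 5 history
coefficients are not penalized; a flag enables penalizing them).  The
non-differentiable L1 term is handled exactly by the standard positive/
negative split `k = k⁺ − k⁻`, `k⁺,k⁻ ≥ 0`, which turns the problem into a
smooth bound-constrained concave maximization solved by L-BFGS-B (memory
40, `ftol` 1e-13, `gtol` 1e-7).  This yields exact zeros and satisfies the
subgradient optimality condition `|∂L/∂k_i| ≤ η` at zeroed coordinates,
which is verified after every fit (tolerance 1e-4); the `converged` flag
records it.  Stimulus design columns are mean-centered during optimization
(the offset is mapped back afterwards), which decorrelates `b` from `k`
and markedly improves quasi-Newton convergence on naturalistic stimuli.
The linear predictor is capped at +30 before exponentiation; a fit that
ends at the cap raises a warning.

`η` is selected by leave-one-stimulus-out cross-validation inside the
estimation set: for each grid value the model is refitted with the held-out
stimulus removed (warm-started along the descending η path), the held-out
PSTH is predicted from simulated trials, and the mean Pearson correlation
is the score; ties go to the larger (sparser) η.  The default grid is 12
log-spaced values over [1e-3, 1e2] scaled by data length; population runs
in the tests use small explicit grids (3–5 values) and 3-fold grouping of
stimuli to keep runtimes in minutes — the recovery results were not
sensitive to this choice.  With fewer than three estimation stimuli the
inner selection is impossible and the grid midpoint is used with a warning.

### Nonlinearity procedures

Beyond the two closed forms, the empirical nonlinearity is reconstructed
by quantile-binning the fitted filter output (25 equal-count bins by
default) and taking the mean spike count per bin; a cubic spline through
(bin center, log rate) — natural boundary conditions, linear extrapolation
of the log rate — can replace the exponential *for prediction only*; it
never alters fitted filter parameters.  Zero-rate bins are floored at half
a count before the logarithm.

## Normalized reverse correlation

The design matrix lag-embeds the spectrogram (frequency-major, lag-minor
column order, zero-padded onset), concatenates stimuli, and centers
columns.  The autocorrelation `C_XX = XᵀX/D` is eigendecomposed; the
pseudoinverse keeps the leading `m` dimensions whose cumulative eigenvalue
fraction is ≤ τ (minimum 1; roundoff-negative eigenvalues are clipped and
never inverted).  The response is the trial-mean rate; its mean becomes the
prediction offset.  τ is cross-validated over
{0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.99, 1.0} by held-out linear prediction,
ties toward fewer retained dimensions.  NRC operates on the same 3 ms grid
as the GLM by default (a 1 ms mode is available through the preprocessing
configuration).

The ablation grid shares this plumbing: `exp_ln` (GLM without history,
J=0), `spline_glm` (post-hoc spline nonlinearity), and `linear_l1` (the
NRC linear model fitted with the L1 prior instead of subspace truncation,
via the same split solver with a Gaussian objective).

## Synthetic data

The generator emulates the structure of the motivating recordings: two
stimulus classes of ~2 s spectrogram stimuli, 10 trials per stimulus, and
GLM/LNP neurons with 20×20 ground-truth STRFs, 5-bin history filters and
10–20 Hz firing rates.

* **Noiselike** (modulation-limited): Gaussian noise in the log-spectrogram
  domain, low-passed in the modulation plane to 50 Hz temporal and
  2 cyc/kHz spectral modulation, unit variance.  Its band energies are
  near-Gaussian (|excess kurtosis| < 0.5) — the elliptic statistics under
  which reverse correlation is unbiased.
* **Songlike**: sequences of syllables (4-harmonic stacks with spectral
  skirts, frequency sweeps, within-syllable amplitude modulation) at 6/s
  with 80–200 ms durations over a −2 floor carrying low-level texture
  (sd 0.25), peaks +3 above floor.  These settings target zebra-finch-like
  song statistics: near-continuous singing, strong temporal
  autocorrelation (lag-1 > 0.8) and heavy-tailed band energies (excess
  kurtosis > 1) — the higher-order structure that makes subspace-truncated
  reverse correlation stimulus-dependent.
* **White**: the flat-spectrum limit of the noiselike class (cutoffs at
  Nyquist); the probe used for parameter-recovery and estimator-agreement
  checks, where every stimulus dimension is excited.

Spikes are emitted sequentially per bin with probability
`p_t = 1 − exp(−λ_t Δ)`, each trial driving its own history — at 3 ms bins
this Bernoulli emission makes multi-spike bins impossible, matching the
regime the discretized likelihood assumes; a Poisson mode exists behind a
flag.  Ground-truth STRFs come in three archetypes (Gabor patches,
biphasic onset kernels, broadband-inhibition kernels); the STRF is scaled
so its linear drive has unit standard deviation over the stimulus set
(a strongly modulated but non-saturating operating point), and the offset
is calibrated to the target rate by a short deterministic fixed-point
iteration.

What the generator does *not* emulate: real songs' full spectrotemporal
richness, non-Poisson count dispersion, slow nonstationarities
(adaptation, state drift), and across-neuron correlations.  Passing tests
therefore demonstrate correctness and the estimators' statistical behavior
under the model's own assumptions, not performance on recorded data.

## Evaluation

PSTHs are trial-mean rates at the model bin width smoothed with a unit-sum
Hanning window; a window specified in milliseconds is sampled at bin
centers with the tap count rounded to the nearest odd number ≥ 3 (5 ms at
3 ms bins → 3 taps).  Convolution uses symmetric edge padding, which
conserves the total integral exactly.  Prediction accuracy is the Pearson
correlation between predicted and observed smoothed PSTHs; a constant
series yields 0 with a warning.  GLM predictions average 50 simulated
trials by default (seeded), since the history term makes the intensity
trial-dependent; NRC predictions are the linear rate plus the training-set
mean.  Leave-one-stimulus-out validation refits per fold with inner
hyperparameter selection restricted to the fold's training set; the
held-out stimulus never influences centering, η/τ selection or fitting.

The similarity index between two STRFs is their pixel-by-pixel Pearson
correlation (affine-invariant, symmetric).

### Tuning metrics

For each sign (excitatory/inhibitory) the STRF is rectified, averaged over
the other axis, and smoothed with the 5-point symmetric Hanning window
`[0.25, 0.75, 1, 0.75, 0.25]` (unit-normalized, symmetric edge padding).
The best frequency is the global extremum (ties toward the lower
frequency/shorter latency); bandwidths are widths at half the extremum
height, with crossings located by linear interpolation between bins and
the zero level of the rectified curve as baseline.  A flank that reaches
the axis edge before crossing half-height is flagged `edge-truncated`;
metrics of an empty rectified curve are flagged `undefined`, never
reported as zeros.

### Bias analysis

Class-specific fits Kn (noise) and Ks (song) serve as generative models:
spiking through the full conditional intensity for the GLM, the continuous
linear rate for NRC.  Responses to both classes are synthesized and
refitted by the same method, giving second-generation STRFs Knn, Kns, Ksn,
Kss; SI(Kn, Kns) and SI(Ks, Ksn) measure how much the estimate depends on
the probe class.  In the paired population comparison the NRC generative
rate carries Gaussian noise matched to the sampling noise of an n-trial
PSTH at the neuron's mean rate, `sd = sqrt(rate / (n_trials · Δ))`: a
noiseless linear response makes tolerance cross-validation degenerate
(τ = 1 reproduces the generator exactly) so the regularization mechanism
under study never engages, and the matched level makes the two methods'
refits face comparable information.

## Problem sizes and determinism

Recovery checks run 10 neurons at the full 20×20 model size (20 white
stimuli × 10 trials × 2 s each); the paired bias comparison runs 20
neurons at 10×10 with 10 noiselike and 20 songlike stimuli; the
acceptance script uses 6 and 12 neurons for the same two analyses.  These
sizes give stable medians and win fractions while keeping full runs in the
minutes range on one CPU.  Every stochastic step draws from
`numpy.random.default_rng` seeded through `SeedSequence` hierarchies, so
identical inputs and seeds reproduce identical fits, simulations and
summary files byte for byte.

## Known limitations

* The L1 prior operates in the pixel basis.  Under band-limited
  (modulation-limited) probes the likelihood does not constrain STRF
  content outside the stimulus band, and the pixel-sparse optimum retains
  systematic out-of-band structure; recovery then saturates around
  SI ≈ 0.8 regardless of data volume, with the in-band component still
  recovered at SI ≈ 0.97.  A combined smoothness-plus-sparsity prior would
  address this but is out of scope.
* Cross-validated η maximizes prediction, not STRF fidelity; on strongly
  autocorrelated stimuli prediction is insensitive to fine STRF structure,
  so the selected η can under-regularize relative to what recovery alone
  would prefer.
* Tuning bandwidths on heavily truncated (over-sparse) STRFs are fragile;
  flags propagate so population summaries can exclude them pairwise.
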
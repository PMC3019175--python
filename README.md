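# strfglm

Spectrotemporal receptive field (STRF) estimation from auditory spike
trains, built around two estimators:

* a **point-process generalized linear model (GLM) with a sparse (L1)
  prior** — the neuron's spike rate is
  `λ(t) = exp(b + Σ_{f,τ} k[f,τ] x(t−τ,f) + Σ_j h_j r(t−j))`, where `k` is
  the STRF acting on the log-spectrogram `x`, `h` is a post-spike history
  filter capturing refractoriness and recovery, and `b` sets the baseline
  rate.  All parameters are fitted jointly by maximizing the penalized
  point-process log-likelihood
  `Σ_t [n_t log(λ_t Δ) − λ_t Δ] − η‖k‖₁`, with the penalty weight `η`
  chosen by leave-one-stimulus-out cross-validation;
* **normalized reverse correlation (NRC)** — the classical regularized
  least-squares STRF `k = C⁻¹_app (Xᵀr/D)`, where the stimulus
  autocorrelation `C_XX` is inverted only inside the leading eigenspace
  holding a fraction `τ` of the stimulus variance, `τ` again set by
  cross-validation.

Around the estimators the package provides the full evaluation stack used
to compare them: spectrogram preprocessing from WAV audio (125 Hz
filterbank, log compression, rebinning to the 20×20, 3 ms model grid),
a synthetic-data generator (songlike and modulation-limited noise
ensembles, LNP/GLM neurons with known ground truth), leave-one-stimulus-out
PSTH prediction scored by Pearson correlation, STRF similarity indices,
spectral/temporal tuning metrics, and the generative bias analysis that
asks whether an estimator's STRF depends on the stimulus class it was
estimated from.  It is aimed at auditory systems neuroscientists who want
a transparent, testable reference implementation of the sparse-GLM
approach next to the reverse-correlation baseline.

## Worked example

```sh
python examples/fit_sparse_glm.py
```

builds a synthetic neuron (20×20 Gabor STRF, 5-bin refractory history,
~15 Hz), simulates 10 trials on 8 white-noise stimuli, and fits the GLM
with cross-validated η:

```
simulated mean rate: 16.1 spikes/s
selected eta = 8 (cross-validated)
similarity index vs ground truth: 0.924
nonzero STRF coefficients: 363 of 400
history filter (log-rate gain per 3 ms bin): [-4.95 -1.98 -1.   -0.16  0.26]
```

The similarity index (pixel-by-pixel Pearson correlation) of 0.92 means the
400-coefficient STRF was recovered from roughly five thousand spikes; the
history filter reproduces the simulated refractory period (strong negative
weights at short lags) and the slight rebound at 15 ms.

The other scripts in `examples/` each demonstrate one capability: audio
preprocessing, reverse correlation with tolerance selection, held-out PSTH
prediction, tuning metrics, and the stimulus-class bias comparison.  A thin
command-line layer (`strfglm preprocess|fit-glm|fit-nrc|make-stimuli|
tuning|run`) wraps the same functions for shell pipelines, and
`strfglm run --config experiment.yaml --out DIR` executes the whole loop
(simulate → fit both models per stimulus class → validate → tuning → bias
tables) reproducibly from one seed.

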
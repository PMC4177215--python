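# Methods

## Scope

`visenc` implements the full voxelwise encoding/identification workflow:
Gabor-pyramid image featurization, per-voxel linear encoding models fit by
early-stopped gradient descent (from stimulus features or from another
region's voxel patterns), prediction averaging, and correlation-matrix
identification, together with a synthetic generator of coupled two-region
responses.  Upstream fMRI concerns — acquisition, BOLD preprocessing,
retinotopic ROI delineation — are out of scope; responses enter as
stimuli × voxels amplitude matrices and ROIs as voxel-id lists.

## Gabor pyramid

Wavelets at frequency *n* cycles/FOV sit on an *n*×*n* grid with cell
centers at ((i+0.5)/n, (j+0.5)/n) of the image extent (row-major, 0-based);
orientations are measured counterclockwise from horizontal.  Defaults:
128×128 images, frequencies 1, 2, 4, 8, 16, 32 cycles/FOV, eight
orientations (0°–157.5° in 22.5° steps), one luminance wavelet — 10,921
channels.

Choices the pyramid definition leaves open were fixed as follows:

* **Envelope width.** The Gaussian envelope s.d. follows the standard
  bandwidth parameterization σ = (λ/π)·√(ln2/2)·(2^b+1)/(2^b−1) with
  wavelength λ = image_size/frequency and b = 1 octave by default
  (`PyramidConfig.bandwidth_octaves`).  σ therefore scales with the carrier
  period (σ at 32 cycles/FOV is exactly 1/32 of σ at 1 cycle/FOV).
* **Quadrature magnitude.** The "magnitude" of a filtered image is the
  complex quadrature magnitude √((I·even)² + (I·odd)²), which is invariant
  to the phase of the underlying pattern; a single-phase |response| was
  rejected as phase-dependent.
* **Compressive nonlinearity.** Features are log(1 + magnitude): monotone,
  zero at zero, defined everywhere (`log_offset` configurable).
* **Zero-DC, orthogonal pairs.** Filters are rendered on the full canvas
  (no cropping).  A multiple of the Gaussian envelope is subtracted from
  each phase so every band-pass filter sums to zero exactly, and the odd
  phase is orthogonalized against the even phase by one Gram–Schmidt step.
  Without this, envelope truncation at the canvas edge leaves off-center
  low-frequency wavelets with a DC residual and a non-orthogonal pair.
* **Image normalization.** Pixel values are interpreted on a [0, 1] scale
  (8-bit inputs are divided by 255).  Each image is mean-subtracted before
  the band-pass inner products, removing DC leakage; the luminance channel
  sees the raw image through a uniform unit-sum filter and passes through
  the same log transform.

## Encoding model estimation

Each voxel is modelled as y = X·h + c + noise and fit independently.  The
estimator is deliberately *not* a closed-form solve: coefficients are shrunk
by early-stopped full-batch gradient descent, which regularizes like ridge
along the descent path.

* **Standardization.** Input channels are z-scored using the mean and s.d.
  of all training rows (one set of statistics per model, stored with it and
  reapplied at prediction time); this makes a single learning rate workable
  across thousands of heterogeneous channels.  Constant channels pass
  through centered.
* **Stopping set.** 20% of the training rows (`stopping_fraction`) are
  drawn once per voxel — deterministically from (seed, voxel index) — and
  excluded from every gradient computation.  Descent is evaluated on this
  set every `eval_every` = 10 iterations; the kernel snapshot with the
  lowest stopping-set summed squared error is kept.  Descent halts after
  `patience` = 20 evaluations without a relative improvement of at least
  `min_rel_improvement` = 1e-4 (without a minimum margin, asymptotically
  slow improvements would postpone the halt indefinitely), or at
  `max_iters` = 5000.
* **Step size.** The configured `learning_rate` (default 1e-4) applies to
  the summed-squared-error gradient of the standardized design.  It is
  capped at 0.9/λ_max of the fit-sample Gram matrix (estimated by
  deterministic power iteration) because strongly correlated designs —
  Gabor features of naturalistic images — otherwise make the fixed step
  divergent.  On well-conditioned problems the cap is inactive and the
  configured rate is used literally.
* **Intercept.** The intercept is unpenalized and unshrunk: the design and
  response are centered on the fit rows, descent runs on the kernel alone,
  and c = mean(y) − mean(X)·h is recovered in closed form at each snapshot.
  Descending on an explicit all-ones channel is mathematically equivalent
  at convergence but *not* along the early-stopped path — the intercept
  transient leaks into every correlated channel and measurably degrades
  held-out predictions — so the centered parameterization is used.
* **Bootstrap.** `n_bootstrap` = 10 rounds resample the estimation rows
  with replacement (seeded from seed, voxel, round); kernels and intercepts
  are averaged across rounds.  `n_bootstrap=1` means a single fit on the
  estimation rows as-is.  The stopping set is fixed across rounds so the
  stopping criterion is stable.
* **Degenerate targets.** A constant response vector short-circuits to a
  zero kernel with the mean as intercept, flagged in the diagnostics.
* **Region-to-region models.** Nothing in the estimator distinguishes
  feature channels from voxel channels: `ResponseMatrix.as_design()` turns
  a source region's patterns into the design matrix and the identical code
  path runs.

Gradient descent uses a precomputed Gram matrix when the channel count is
at most 3000 (iterations then cost O(q²) instead of O(pq)); above that it
falls back to direct design-matrix products.  Both compute the same
gradient.

## Identification

The correlation matrix holds, at row *n*, column *m*, the Pearson
correlation across voxels between the *predicted* pattern of test image *n*
and the *observed* pattern of image *m*.  Column *m* counts as correct when
its diagonal entry is the strict maximum of the column; ties count as
incorrect (conservative and deterministic).  Accuracy is stored as an exact
fraction and formatted to one decimal percent in reports.  Zero-variance
patterns correlate 0 with everything and are logged, never raised, so a
degenerate voxel subset cannot abort a pipeline run; a single-voxel ROI has
no defined pattern correlation and reports accuracy as NaN.

## Prediction combination

The combined model averages the stimulus-model and region-model predictions
voxel by voxel (weight 0.5).  Raw averaging is the default for fidelity to
the analysis it implements; an optional per-voxel z-scoring switch
(`standardize=True`) is available when the two prediction scales differ,
and general weights are exposed as plumbing.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
the physiology that produces it.

* **Stimuli.** `pink_noise` images have 1/f amplitude spectra (the
  hallmark of natural-image statistics; measured radial log-log slope ≈ −1)
  rescaled to [0, 1]; `gabor_composite` images sum 3–10 randomly drawn
  wavelets plus weak pink noise.
* **Target region ("ERC").** Voxel v responds y = X·h_v + c_v + a_v·z + ε.
  Kernels are sparse (default 1% of channels) and localized: support
  confined to one spatial neighborhood × 1–2 adjacent orientations × 2
  adjacent frequencies.  ROI labels follow the kernel's frequency band —
  high-frequency kernels are "V1", low "V3" — mirroring the coarse-to-fine
  progression of retinotopic areas.  The optional latent components z are
  per-stimulus signals *not* expressible through the features (a stand-in
  for top-down input); `latent_share` sets their fraction of signal
  variance, per ROI if desired.
* **Noise and repeats.** ε is i.i.d. normal per stimulus (the released
  form of such data is per-stimulus amplitude estimates, so no temporal
  autocorrelation is simulated), scaled so per-voxel signal s.d./noise s.d.
  equals the requested SNR.  Test responses average `test_repeats` = 13
  independent draws, emulating repeated test-stimulus presentation.
* **Source region ("LOC").** Each source voxel is a sparse random mixture
  of the target region's *noise-free* signal components plus independent
  noise — shared stimulus-driven variance, never shared measurement noise,
  underlies the region-to-region model's success.  `low_freq_bias` b
  rescales mixing weights by (1+b) for V3 voxels and 1/(1+b) for V1
  voxels, biasing the source toward low-frequency signal.
* **Seeding.** Every generator takes an explicit integer seed; identical
  seeds give bit-identical output, and there is no global random state.

What passing tests on this generator do **not** show: robustness to hemodynamic
nonlinearity, temporally correlated physiological noise, voxel-size/receptive-
field scaling, or real natural-image statistics beyond the 1/f spectrum.
Results on real recordings depend on those factors; the synthetic studies
validate the machinery, not the neuroscience.

## Study configurations and problem sizes

Two desk-scale study configurations are fixed package-wide (`VBEM_STUDY`,
`SHARED_SIGNAL_STUDY`): 800 training / 60 test stimuli, the reduced
four-frequency pyramid (681 channels), 60 target voxels at SNR 2.  These
sizes scale the full design (1750/120 stimuli, 10,921 channels, hundreds of
voxels) down to a few minutes of CPU while keeping every qualitative
regime: chance ≪ accuracy ≪ ceiling.  The shared-signal study adds latent
shares {V1: 0.2, V2: 0.45, V3: 0.7}, a 40-voxel source region at SNR 0.5
with mixing density 0.2 and low-frequency bias 2.0 — calibrated once so
that all three models land strictly between chance and ceiling (measured
means ≈ 0.78 stimulus model, 0.66 region model, 0.88 combined) and the two
models' sub-ROI gradients run in opposite directions.  Full-scale settings
remain valid configurations.

## Numerical choices and degenerate inputs

* Channel s.d. of zero → that channel passes through centered, not divided.
* Correlations are clipped to [−1, 1] after the matrix product.
* Identification requires ≥ 2 test images and ≥ 2 voxels; violations raise
  shape errors rather than returning vacuous results.
* Pipeline results (`result.json`) contain no timing data; wall times,
  versions, seed and config hash live in `run_log.json`, so a rerun with
  the same configuration and seed reproduces `result.json` byte-for-byte
  and every numeric artifact bit-for-bit.
* File interchange is HDF5 for matrices and JSON for metadata; CSV is kept
  for human inspection (round-trips to 1e-12 via `%.17g` formatting).

## Known limitations

* The estimator's shrinkage profile (early-stopped descent) is sharper
  than ridge regression's; on strongly correlated designs it recovers
  slightly less low-eigenvalue signal than an optimally tuned ridge.
  Ridge is intentionally not the estimator here.
* Per-ROI identification uses few voxels at desk scale (20 per ROI), so
  sub-ROI accuracies are noisy; the packaged tests assert orderings of
  means across seeds, not per-seed orderings.
* The CLI loads whole matrices into memory; at the full 10,921-channel,
  1750-stimulus scale a fit needs a few GB and hours of CPU, which is the
  expected cost of the original design rather than a target of this
  implementation.
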
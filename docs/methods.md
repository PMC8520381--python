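# Methods

## Signal model and simulator

The simulator realizes the narrowband far-field model of an M-element
uniform linear array: each snapshot is `x(t) = A s(t) + n(t)` with
steering matrix columns `a(θ)ₙ = exp(−j2πd·n·sinθ)` (pitch `d` in
wavelengths, default 0.5 to exclude grating lobes), circular complex
Gaussian source amplitudes `s(t)` and spatially white circular Gaussian
noise with covariance `σ²I`. Distributional choices are the package's
own; nothing in the model constrains them beyond second-order
statistics. A `coherent=True` switch reuses a single Gaussian draw for
all sources, producing the fully coherent, rank-one covariance case
that motivates spatial smoothing.

What the simulator does **not** emulate: pulse-echo propagation,
time-of-flight focusing, frequency-dependent attenuation, speckle
statistics of real tissue. Passing tests therefore demonstrate the
algebraic and statistical behaviour of the reconstruction chain on the
narrowband model, not clinical image quality.

Defaults: M = 32 elements, q = 12 sub-arrays, T = 256 snapshots, noise
variance 0.01 relative to unit source power, sources at ±0.15 rad.
These are configuration, not physics; no clinically used values exist
to adopt, so they were chosen once as representative of a small linear
probe and a snapshot count comfortably above the sub-array dimension.

## Smoothing and adaptive weights

Sub-arrays are the q overlapping unit-shift windows of length
`l = M − q + 1` (the standard spatial-smoothing convention). Forward
smoothing averages the corresponding principal blocks of the sample
covariance; backward smoothing applies the same average to the
exchange-conjugated matrix `J R* J`; forward–backward (FB) averaging is
their arithmetic mean and is persymmetric by construction
(`J R_s* J = R_s`), which the covariance container asserts to 1e−10
relative tolerance along with Hermitian symmetry and positive
semidefiniteness (smallest eigenvalue ≥ −1e−10·trace).

Adaptive weights are Capon/MVDR with diagonal loading
`ε = δ·tr(R_s)/l`, default δ = 0.01 — a percent of the mean eigenvalue,
the common rule of thumb that stabilizes the solve without visibly
biasing the beam at the SNRs simulated here. The linear system is
solved with a Hermitian factorization (`scipy.linalg.solve`,
`assume_a="her"`), never an explicit inverse; a numerically singular
loaded matrix raises with instructions to increase the loading rather
than being regularized silently. Smoothing is applied once per frame
and the same smoothed covariance is scanned over the angular grid
(per-direction application); per-pixel re-estimation was rejected as it
changes nothing on the narrowband model while multiplying cost.

Per-direction output power is `wᴴR_s w` for the adaptive method and
`wᴴR w` with fixed weights `a/M` for delay-and-sum. Stored pixels are
the envelope (square-root power); display-side log compression (60 dB
default) is available but metrics compare linear intensity.

Coherent-source handling is delegated entirely to the smoothing stage:
no eigen-subspace projection or other decorrelation is layered on top,
so the rank-restoration tests isolate the property smoothing itself
provides.

The Wiener (`gain = S/(S+N)`, S taken as pixel power) and SNR
(`gain = snr/(1+snr)`) post-filters are deliberately generic,
single-line comparators used to exercise the comparison harness; they
are not reconstructions of any published feature-space-fusion method.

## Reconstruction metrics

The three indices are the classical tomography definitions: normalized
root-mean-square distance `l` (normalizer: variance of the original
about its mean), normalized mean absolute distance `f` (normalizer:
Σ|t|), and PSNR via MSE with a `+inf` sentinel for identical images.
`max_value` defaults to the integer dtype ceiling (255 for 8-bit) or
the original's peak for float rasters. Degenerate normalizers
(constant or all-zero original) raise instead of returning NaN. The
algebraic identity `l²·Σ(t−t̄)² = M·N·MSE` ties the indices together
and is enforced in the tests.

## Lung ultrasound score and cohort model

Twelve thoracic zones (six per lung) each receive a continuous grade in
[0, 3]; the total score maps the zone sum linearly onto a 0–100 index.
A 0–100 continuous index was chosen because the modeled group means
(up to 42.57) exceed the classical integer 0–36 twelve-zone range, so
the score is treated as a rescaled severity index rather than the
integer sum; zone grades are generated consistently with each total by
Dirichlet(5) splitting with resampling of the rare draws that exceed a
zone ceiling.

Group scores are truncated normals on [0, 100]. Truncation is by
rejection sampling, and the parent parameters are **moment-matched**:
when the nominal mean sits within about two SDs of a scale bound (the
W3 group: mean 14.33, SD 7.03, ≈2 % mass below zero) naive truncation
would inflate the sample mean by ≈0.5, so the parent mean/SD are solved
numerically such that the truncated distribution has exactly the
nominal moments. Far from the bounds the parent parameters are used
unchanged. Target moments unattainable under truncation (mean/SD ratio
below the exponential-tail limit) raise an error.

Default cohort: 132 subjects. S-stratum sizes 74/58; W-stratum sizes
are not externally fixed and default to 44 per group; P-stratum sizes
83/49 are back-computed from a 62.88 %/37.12 % split of 132.
Demographics (sex, delivery mode, cord abnormality rates; age, weight,
maternal age, gestational age ranges) are drawn from documented
plausible neonatal distributions and carry no effect on scores — they
are realism plumbing, not covariates.

Two-group comparisons use Welch's unequal-variance t-test (robustness
over the pooled-variance form); three groups get one-way ANOVA as the
omnibus test followed by all pairwise Welch tests with Bonferroni
adjustment. Proportions and summary tables round half-up to two
decimals, matching hand arithmetic on integer counts.

## Pipeline and numerical choices

`run_comparison` reconstructs one shared two-point scene with every
method, scores each normalized envelope against an angular ground truth
(unit impulses at the grid points nearest the true source angles) and
measures the −3 dB mainlobe width by linear interpolation of the level
crossings around the global peak. Envelopes are peak-normalized before
scoring so the metrics compare beam shape, not arbitrary gain. Every
run writes a manifest (config hash, seed, package and numpy versions)
sufficient to reproduce it; identical config + seed gives bit-identical
CSV outputs.

The acceptance script runs 100 replicate cohorts per stratification
with seeds drawn from the user seed and reports the 99th-smallest
p-value — the significance level the comparison beats in at least 99 of
100 replicates. At the default group separations (Cohen's d ≈ 1.8 and
larger) these levels are many orders of magnitude below 0.05.

## Known limitations

- The narrowband single-frequency model cannot exhibit broadband or
  near-field effects; conclusions about real probes require a full
  pulse-echo simulator.
- The phantom rasters (points, cyst, pleura + B-lines) are reflectivity
  maps for the metrics module, not scenes rendered through the beam
  former; the beamforming tests operate in angle space.
- The cohort is synthetic by construction: group distributions are
  normal by assumption and demographics are independent of scores, so
  the statistics module validates the testing machinery, not any
  clinical claim.
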
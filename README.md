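# sdss

Adaptive ultrasound image reconstruction by **sub-array decomposition
with forward–backward spatial smoothing (SDSS)**, plus the harness
needed to study it end to end: a synthetic linear-array echo simulator,
classical reconstruction-quality indices, and a twelve-zone lung
ultrasound score (LUS) cohort module with group statistics.

## The problem

Lung ultrasound of neonates with infectious pneumonia is dominated by
coherent reverberation artifacts (B-lines / comet tails). Coherent
echoes make the spatial covariance matrix of an M-element linear array
rank-deficient, which breaks adaptive (minimum-variance) beamformers.
The fix implemented here: divide the array into `q` overlapping
sub-arrays of length `l = M − q + 1`, average their covariance blocks
(forward smoothing), average again with the exchange-conjugated
counterpart (backward smoothing),

```
R_f = (1/q) Σᵢ R[i:i+l, i:i+l]        R_b = forward(J R* J)
R_s = (R_f + R_b) / 2                 (persymmetric, rank-restored)
```

and steer Capon/MVDR weights with diagonal loading on the smoothed
sub-array covariance:

```
w = (R_s + εI)⁻¹ a(θ) / (aᴴ(θ) (R_s + εI)⁻¹ a(θ)),   ε = δ·tr(R_s)/l.
```

Reconstructions are scored against ground truth with the normalized
mean square distance `l = √(Σ(t−r)²/Σ(t−t̄)²)`, normalized mean
absolute distance `f = Σ|t−r|/Σ|t|`, and `PSNR = 10·log₁₀(max²/MSE)`.

The cohort module models the semi-quantitative twelve-zone LUS
(continuous 0–100 index) for a synthetic 132-neonate cohort stratified
by respiratory status (S1/S2), critical-illness severity (W1–W3) and
neurobehavioral development (P1/P2), and runs Welch / ANOVA group
comparisons at α = 0.05.

## Worked example

```python
import sdss

table = sdss.run_comparison(sdss.RunConfig(seed=0))
print(table.to_string(index=False))
```

```
     method        l         f      mse   psnr_db  mainlobe_width_rad
        das 4.084241 33.385342 0.091904 10.366671            0.055992
  mvdr_sdss 0.714715  5.801607 0.002814 25.506237            0.003097
wiener_post 4.053913 31.706622 0.090544 10.431411            0.055918
   snr_post 4.053913 31.706622 0.090544 10.431411            0.055918
```

On a shared two-point scene (32 elements, 12 sub-arrays, 256 snapshots)
the smoothed minimum-variance method (`mvdr_sdss`) cuts the deviation
index `l` from 4.08 to 0.71, raises PSNR by ~15 dB and narrows the
−3 dB mainlobe eighteen-fold relative to delay-and-sum; the generic
Wiener/SNR post-filters barely move the needle because they reweight
the same wide DAS beam.

```python
cohort = sdss.simulate_cohort(stratum="s", seed=0)
print(sdss.group_proportions(cohort, "s"))   # {'S1': 56.06, 'S2': 43.94}
res = sdss.compare_groups(cohort, "s")
print(res.test_name, round(res.statistic, 2), res.p_value)
# welch_t 11.93 1.65e-22
```

The simulated respiratory-status groups (74 vs 58 subjects, score means
40.62 vs 28.47) reproduce the 56.06 % / 43.94 % split exactly and the
between-group difference is overwhelmingly significant — the ~1.8-SD
separation of the group means makes the Welch test essentially certain
to reject at any realistic cohort size.

A CLI mirrors the library: `sdss simulate`, `sdss beamform`,
`sdss metrics`, `sdss cohort simulate/analyze`, and the umbrella
`sdss compare --config run.yaml`.

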
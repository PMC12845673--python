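# Methods

This note documents the model behind `bracekin`, the assumptions it makes,
the default parameter values and why they were chosen, and what the
synthetic-study generator does and does not emulate. It describes what the
code computes; no claims are made beyond that.

## 1. Measurement model

Each of the two brace sensors (thigh and shank) is an MPU-6050 logging raw
ADC counts. Counts are converted to physical units with the fixed
sensitivities of the configured ranges:

- accelerometer, ±2 g: 16 384 LSB/g, values clamped to ±32 768 counts;
- gyroscope, ±250 °/s: 131 LSB/(°/s), values clamped to ±32 750 counts.

Segment tilt in the sagittal plane is read from the accelerometer under the
quasi-static assumption that the measured specific force is dominated by
gravity:

```
φ = atan2(Ax, Ay)   (degrees, 0° = upright, range (−180°, 180°])
```

Tilt series are unwrapped (period 360°) before any subtraction so that
crossings of ±180° do not produce spurious jumps. Knee flexion angle and
angular velocity are segment differences:

```
θ(t) = φ_thigh(t) − φ_shank(t)
ω(t) = ωz_thigh(t) − ωz_shank(t)
```

with ωz the gyroscope z-axis rate (the hinge axis). A static standing window
at the start of each recording (default 1 s) defines the zero of θ; the
window is rejected (`CalibrationError`) if gyroscope activity exceeds
10 °/s, since a moving "static" window would corrupt the reference.

The criterion (optical motion capture at 200 Hz) provides the knee angle
directly; its angular velocity is obtained by differentiating the filtered
angle (`np.gradient`).

## 2. Synthetic study generator

The simulator produces the full validation experiment — by default 13
participants × 5 tasks × 5 trials — at the sensor level: it writes the same
raw-count brace logs and criterion TSVs that real hardware would, so the
entire chain from file parsing onward is exercised.

### Task profiles

Each task is a smooth flexion profile built from analytic bumps:

| task | shape | peak (deg) | duration (s) | reps | thigh share |
|---|---|---|---|---|---|
| walk | sin² periodic | 60 | 3 | 3 strides | 0.30 |
| slope | sin² periodic | 65 | 4 | 3 strides | 0.35 |
| stair | u²(1−u)³ bout | 95 | 5 | 1 | 0.45 |
| sit | u²(1−u)² bout | 90 | 4 | 1 | 0.55 |
| shoelace | u³(1−u)³ bout | 110 | 6 | 1 | 0.30 |

The "thigh share" splits the joint angle between segment tilts
(φ_thigh = share·θ, φ_shank = −(1−share)·θ), reflecting that different
movements are thigh- or shank-dominant. Peak angles vary per participant
(SD 10°) and per trial (SD 3°), clipped to [10°, 160°]. Every trial has a
2 s static lead-in and a 1 s tail.

### What is emulated

- **Quantisation** to integer counts at the sensitivities above.
- **Accelerometer noise**: band-limited (Gaussian-filtered, σ = 1 sample,
  rescaled to the target SD of 0.05 g per axis) rather than white, since
  real motion artefact is correlated.
- **Gyroscope noise and bias**: white noise (0.5 °/s) plus a constant
  per-sensor bias (magnitude 1 °/s).
- **Mounting misalignment**: a per-trial constant tilt offset per sensor
  (SD 3°). It cancels in the static-reference step, as it would in practice.
- **Strap slippage / soft tissue**: a slow 0.1 Hz sinusoidal tilt artefact
  (amplitude 3°) added to each segment, with its analytic derivative added
  to the gyroscope rate for consistency.
- **Clock desynchronisation**: the criterion recording starts a uniform
  0–1 s before the brace, so the two streams must be aligned by
  cross-correlation, as with real unsynchronised loggers.
- **Criterion noise**: white, SD 0.25° — small, as marker-based capture is
  the reference.

### What is not emulated

- Out-of-sagittal-plane motion, cross-axis sensitivity, and magnetometer
  fusion (the device has none).
- Gyroscope drift from integration — the pipeline never integrates the
  gyroscope, so drift does not enter the angle estimate.
- Marker occlusion or soft-tissue artefact on the criterion side.
- Gait-event detection: movement start/end times are carried explicitly in
  the dataset manifest rather than detected from the signals.
- Physiological variation in curve *shape* (only peak amplitude varies).

With all noise terms set to zero (`SimulationConfig.noise_free()`), the
chain recovers the truth to the quantisation floor: worst-case RMSE
≈ 0.002° for angle and ≈ 0.004 °/s for velocity across 325 trials.

## 3. Processing pipeline

1. **Static reference** from the lead-in window; tilt offsets subtracted.
2. **Criterion filtering**: 4th-order zero-lag Butterworth (`sosfiltfilt`),
   cutoff 6 Hz — a standard choice for lower-limb kinematics that keeps
   voluntary-movement frequency content (< 6 Hz) while removing marker
   jitter. The cutoff must lie below Nyquist (`ParameterError` otherwise);
   the 20 Hz brace stream is left unfiltered by default because its Nyquist
   is only 10 Hz.
3. **Alignment**: normalized cross-correlation over integer 20 Hz lags
   (max ±2 s, covering the simulated 0–1 s desync with margin); the match is
   rejected below correlation 0.5 (`AlignmentError`). On the default study
   the median offset-recovery error is one sample (0.019 s at the 50th
   percentile, 0.082 s at the 95th).
4. **Outlier screening** on per-trial peak angles within each
   participant × task cell (needs ≥ 3 trials): a trial is removed when its
   peak deviates from the cell median by more than 3× the scaled MAD **and**
   by more than 5° absolute. The absolute floor prevents the MAD rule from
   discarding legitimate trials when the natural trial-to-trial spread is
   small (a near-zero MAD makes the relative rule hypersensitive). If the
   rule would remove more than 40 % of a cell, nothing is removed and the
   cell is flagged instead.
5. **Time normalisation** of the event window to 101 points (0–100 % of
   cycle) by linear interpolation.
6. **Hierarchical averaging**: trials → participant mean curves → group
   mean ± SD. Statistics are computed on participant means (n = 13) so
   participants, not trials, are the unit of analysis.

## 4. Statistical Parametric Mapping

`spm_paired_test` compares the brace and criterion participant-mean curve
stacks (n pairs × 101 nodes):

- **t trajectory**: paired t at each node, df = n − 1. Nodes with exactly
  zero difference variance are flagged; they get t = 0 when the mean
  difference is zero and a signed cap at the largest finite |t| otherwise.
- **Smoothness**: residuals (differences minus their mean) are normalized
  per node; FWHM = √(4 ln 2 / mean squared forward-difference gradient).
  For white noise this converges to √(2 ln 2) ≈ 1.18 node spacings.
- **Threshold**: the critical value u solves, per tail at α/2,
  `resels · ρ₁(u) + P(T > u) = α/2`, with the 1-D Euler-characteristic
  density `ρ₁(u) = (√(4 ln 2)/2π)(1 + u²/df)^(−(df−1)/2)` and
  resels = (Q − 1)/FWHM (Q = 101). Root-finding uses `brentq` (xtol 1e-6).
  The result is capped at the two-sided Bonferroni value
  `t.ppf(1 − α/202, df)`, because the EC approximation overshoots Bonferroni
  at very low smoothness where the field is effectively discrete. In the
  infinite-smoothness limit the threshold reduces to the ordinary paired-t
  critical value (2.1788 at df = 12, α = 0.05), which is verified in the
  tests.
- **Clusters**: maximal runs with |t| ≥ u, with linearly interpolated
  threshold crossings at the edges. Cluster p-values use the Poisson-clump
  approximation `p = 1 − exp(−E[N]·exp(−k/η))` with η = E[area]/E[N],
  clipped to (1e-6, α].
- At df = 1 the EC density does not decay, so no finite RFT threshold
  exists; this is raised as `ThresholdError` rather than silently
  approximated. At least 3 participants are required in practice.

Monte-Carlo calibration (1 000 repetitions of smooth Gaussian null fields,
FWHM 15, n = 13) gives a family-wise error rate of 0.047 at α = 0.05.

## 5. Agreement metrics

- **RMSE** between brace and criterion curves, computed per participant and
  averaged; qualitative bands for angle: < 5° *excellent*, 5–10° *good*,
  > 10° *poor*.
- **RSR** = RMSE / SD, with SD taken over the 101 nodes of the criterion
  group-mean curve — i.e. error relative to how much the signal itself
  varies across the cycle. Bands: ≤ 0.50 *very good*, ≤ 0.60 *good*,
  ≤ 0.70 *satisfactory*, > 0.70 *unsatisfactory*. Velocity curves are
  labelled by RSR rather than absolute RMSE because velocity magnitudes
  differ strongly between tasks.
- **Bland–Altman** on per-participant peak values: bias, 95 % limits of
  agreement (±1.96 SD of the differences), a t-based 95 % CI for the bias,
  and whether the bias is within 5 % of the grand mean.
- **SEM** = SD(differences)/√2 and **MDC** = 1.96·√2·SEM, the minimal
  change detectable beyond measurement error at 95 % confidence.

## 6. Numerical choices

- All interpolation is linear (`np.interp`); curves are smooth and densely
  sampled relative to their frequency content, so higher-order schemes add
  nothing but ringing risk.
- Analytic task profiles are differentiated by central differences with
  h = 1e-4 s, well below the 0.05 s brace sample period.
- Ensemble SD uses ddof = 1; when all input rows are bitwise identical the
  SD is forced to exactly 0 to avoid spurious 1e-16 floors.
- All randomness flows from a single `numpy` `SeedSequence`-derived
  generator per dataset, so datasets are reproducible from one seed.

## 7. Limitations

- The simulator's noise model is stylised; real soft-tissue artefact is not
  a pure 0.1 Hz sinusoid, and real mounting error can vary within a trial.
  Absolute RMSE values obtained on synthetic data therefore characterise
  the pipeline, not the hardware.
- Validity is assessed in the sagittal plane only.
- The RFT threshold assumes a stationary, Gaussian difference field;
  heavy-tailed artefacts would inflate the error rate beyond the
  Monte-Carlo figure quoted above.
- Event windows come from the manifest; applying the pipeline to real
  recordings requires supplying movement start/end times (or adding an
  event-detection step, which is out of scope here).
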
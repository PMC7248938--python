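# Methods

This note documents the model assumptions, parameter choices, numerical
conventions, and known limits of `msamap`. It is the package's own account;
every number quoted here is computed by the test suite or the acceptance
script.

## The statistic

For one sensor locus, let x(t) ∈ ℝᵖ stack the time–frequency envelope
features of its co-localized channels (p = channels × bands, channel-major)
and let y(t) ∈ {0,1} mark stimulus onsets on the feature frame grid. For a
latency τ (an integer number of frames), the shifted multiple Pearson
correlation is

  R(τ) = corr( ŷ(t), y(t−τ) ),

where ŷ(t) are *out-of-fold* predictions of the shifted train from ridge
regression fitted under k-fold cross-validation. Two conventions deserve
note:

- **Correlation, not √R².** In-sample, the multiple correlation equals the
  square root of the coefficient of determination of the regression;
  out-of-fold the two diverge (the CV R² can be negative). The correlation
  form is used because it remains defined and keeps its sign for negative
  associations; downstream region statistics take absolute values, so
  clipping negatives would bias the null distribution instead.
- **Shifting by truncation.** y is shifted by whole frames and both series
  are truncated to their overlap; circular shifting would correlate the
  session's tail with its head.

### Ridge regression

Predictors are column-standardized; coefficients solve
(X̃ᵀX̃ + λI) b = X̃ᵀ(y − ȳ) and are mapped back to the original scale. λ = 0
reduces exactly to OLS and raises on rank-deficient designs. The default
λ = 1 on standardized predictors is deliberately mild: its role is to
stabilize the solve under strongly correlated neighboring bands, and
because R(τ) is a correlation, any monotone shrinkage of ŷ leaves R nearly
unchanged. Cross-validation uses contiguous equal time blocks (default 4) so
that temporally autocorrelated features do not leak between train and
validation; each frame is predicted exactly once by a model that never saw
it. A single "fold" is the documented refit-on-all (in-sample) mode.

### Shift grid

Default τ ∈ [0, 1.5] s in steps equal to the feature step (50 ms): the
latency of a cue-locked response is nonnegative and the post-cue epoch of
interest is 1.5 s. A movement-locked analysis would pass τ ∈ [−0.5, 1] via
`tau_min`/`tau_max`; both bounds are plain parameters.

## Features

- **Filterbank.** Complex Morlet wavelets at geometrically spaced centers
  (constant ratio), the standard choice when responses may span 1–250 Hz.
  The wavelet width is 7 cycles for all bands, a common electrophysiology
  default; Q is then constant across bands, matching the log spacing.
- **Envelopes.** |CWT| averaged in centered sliding windows of 300 ms,
  stepped by 50 ms. The step oversamples the window ~6×, which sets the
  resolution of the shift grid; it is configurable. Frames whose window
  would leave the recording are dropped, and the CWT itself is computed on
  a reflection-padded signal so no frame sits in the cone of influence of
  a zero boundary.
- **Normalization.** Per (channel, band): subtract the session mean, then
  divide by that same session-mean envelope. Features are therefore
  relative modulations, exactly invariant to any positive per-channel gain
  (asserted end-to-end in the tests). The normalization statistics are
  session-wide, not fold-wise; this is a mild leakage of second-order
  information into the CV folds, accepted because the alternative couples
  feature scaling to the fold plan. Degenerate (zero-energy) bands raise,
  naming the channel and band.

## Projection and region statistics

Each mesh vertex takes a weighted mean of the values at its k = 3 nearest
sensor loci with weights 1/d (Euclidean, in the common mm frame); a vertex
coincident with a locus takes that locus's value exactly. The projection is
applied independently per shift, and obeys the maximum principle (vertex
values never leave the range of the contributing loci). No smoothing beyond
IDW is applied, and no inverse problem is solved — the statistic being
projected is nonlinear in the data, so linear inverse operators do not
apply.

Region time courses are means of absolute vertex values per labeled region.
Significance uses the pooled empirical distribution of all region × time
values of the run: the threshold is its q-quantile (default q = 0.95, the
"95% of a Gaussian" reading of the top quintile; the literal 80th-percentile
reading is available by passing q = 0.8) computed with the
linear-interpolation order-statistic convention, and flags are strict
(value > threshold). With fewer than 20 pooled values a warning notes the
threshold is unstable. Selectivity is the percentage of significant
region–time points in the target region (undefined — reported as missing,
not 0 — when nothing is significant), with the median time of the target's
significant points as its timing.

The exact one-tailed Wilcoxon signed-rank test drops zero differences,
mid-ranks ties, and enumerates the full null distribution of the rank sum
for up to 25 effective pairs (dynamic programming over the doubled ranks is
an exact equivalent of enumerating all 2ⁿ sign patterns); beyond that a
continuity-corrected normal approximation with tie-corrected variance is
used. The adjusted-Wald margin of error adds two successes and two failures
before forming the Wald interval — reliable at small n and extreme
proportions — and the effectiveness bound is (1 − MOE)·(x/n).

## Synthetic sessions

The generator emulates a cue-paced motor session:

| parameter | default | meaning |
|---|---|---|
| `fs` | 1000 Hz | sampling rate |
| `duration` | 600 s | session length (~10 min) |
| `n_trials` | 110 | cue presentations (>100) |
| `fixation_range` | 2.25–4 s | uniform fixation before each 2 s cue |
| `response_delay` | 0.4 s | cue-to-response latency |
| `jitter_sd` | 0.1 s | Gaussian latency jitter, clipped at 0 (with warning) |
| `modulation_gain` | 2.0 | burst amplitude relative to unit noise |
| `target_band` | 20 Hz | burst carrier frequency |
| `noise_exponent` | 1.0 | 1/f background slope |

Noise is spectrally shaped Gaussian noise, independent per channel,
generated in the frequency domain and normalized to unit variance — it has
the 1/f character of MEG background without modeling head geometry or
sensor cross-talk. The response is a 0.5 s Hann-windowed burst of the
carrier, *centered* at onset + delay (+ per-trial jitter) and phase-locked
to its center, added to the channels of the target loci. Phase locking
matters for the jitter experiments: a jitter-free session has a genuine
trial-averaged evoked response, which latency jitter then nulls (3 carrier
cycles of spread at 0.15 s jitter and 20 Hz), while the envelope-based MSA
statistic degrades only through envelope smearing. Response-delay and
jitter defaults are plausible placeholders for a self-paced finger tap, not
published values.

Geometry: sensor loci on a Fibonacci lattice over an upper hemisphere
(100 mm, 2 channels per locus; the seed rotates the lattice), the cortical
mesh on a hemisphere at 0.8× the shell radius, triangulated by planar
Delaunay. The ten region labels form compact contiguous patches — an
equal-count left/right split on x, then five equal-count
anterior-to-posterior bands per half (front, mot, par, temp, occ). Patches
are used rather than full-latitude azimuthal wedges because wedges all meet
at the helmet apex, where no overhead sensor can separate them.
`pick_target_loci` chooses the loci "overlying" a region through the
analysis's own projection operator: the locus set maximizing the IDW weight
margin of the target region over the best other region.

What the generator does **not** emulate: spatially correlated noise and
physiological artifacts (cardiac, ocular), realistic forward fields
(dipole orientation, field spread), head movement, and non-stationary
background rhythms. Passing tests therefore demonstrate the statistical
machinery — recovery, calibration, jitter robustness — under an idealized
sensor model, not performance on real recordings.

## Scaled-down study sizes

The validation studies in the test suite run at desk scale, chosen once:
fs = 200 Hz, 8 bands over 4–40 Hz, 60 trials in 365 s for recovery
(12 loci, 2 target loci, 200-vertex mesh), 40 trials for the jitter
comparison, 20 for null calibration. At these sizes the recovery study
identifies the planted locus and the 0.4 s delay essentially always, and
null sessions show calibrated flag rates and no preferred locus.

**Spatial selectivity depends on array density.** With 12 loci the k = 3
inverse-distance footprint of a locus spans roughly 3 of the 10 regions
(~3/12 of the cap) and power-1 weights are shallow, so the regions adjacent
to the targets respond at ~0.65× the target region and capture roughly half
of the top-5% significant points: target-region selectivity plateaus near
45%. The same pipeline at 24 loci exceeds 50% (asserted in the tests) and
at 48 loci reaches ~65%; dense whole-head arrays are denser still. This is
a resolution property of the sparse scaled-down geometry, not of the
statistic.

## Degenerate inputs and tie-breaks

- Zero-variance feature columns: error in `shifted_pc`; in `ridge_fit`
  an error at λ = 0, a zero coefficient at λ > 0.
- Constant shifted event train on an overlap (extreme shifts): per-locus
  curves are flagged, never a global failure; flagged loci are masked to 0
  before projection by the pipeline (logged).
- Constant out-of-fold predictions with a varying target: R = 0 by
  definition.
- Onset-to-frame assignment: nearest frame, exact midpoints to the earlier
  frame; onsets beyond half a step outside the grid are dropped and
  counted; collisions merge with a warning.
- Argmax over loci/shifts and nearest-loci ties: lowest index wins
  (stable sorts throughout), making every pipeline output reproducible
  byte-for-byte from the resolved configuration.
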
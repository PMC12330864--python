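# Methods

This document records the models implemented by `fluideeg`, the
conventions and defaults they are pinned to, and their known limits. No
empirical claim here goes beyond what the test suite
(`tests/`) and the acceptance script (`scripts/acceptance.py`) compute.

## Preprocessing

Raw multichannel recordings (nominally 30-channel, 1 kHz surface grids)
pass through three stages:

1. **Channel rejection** — channels that are flat (zero variance),
   saturated (a large fraction of samples pinned at the extremes) or
   explicitly listed are removed. A subject with more than 5 faulty
   channels is flagged for exclusion rather than silently analyzed.
2. **Lowpass filtering** — 4th-order Butterworth at 100 Hz, applied
   forward-backward (`sosfiltfilt`) for zero phase distortion. Note that
   a 4th-order filter has a soft shoulder: reapplying it to broadband
   input changes in-band energy by a few percent, so idempotence holds
   only for signals already inside the passband (the unit tests check it
   there).
3. **Coarse-graining** — non-overlapping 40 ms block means, converting
   1 kHz input to the 25 Hz trajectory used by the fluidity and
   microstate analyses and matching a 25 fps behavioral video stream. A
   trailing partial block is dropped. Recording phases (e.g., task
   segments) can be concatenated with the join positions recorded in
   metadata so downstream gap statistics can censor them.

## Dynamics fluidity (extremal index)

For the coarse-grained trajectory `u_t` and a reference `u_0`, the
observable is `g(t) = -log ||u_t - u_0||` (Euclidean norm over
channels). The self point is excluded; exact duplicates of the reference
are excluded with a warning. `g` is thresholded at its empirical
`q`-quantile, default `q = 0.98`; exceedances are strict.

Let `T_i` be the inter-exceedance times and `S_i = T_i - 1` (so adjacent
exceedances contribute zero spacing — the convention is pinned because
the two conventions in the literature disagree exactly in the clustered
regime that matters here; `use_t_gaps=True` switches to `S_i = T_i`).
With `p = 1 - q`, `N` gaps and `N_c` positive spacings, the Süveges
estimator maximizes

```
l(theta) = (N - N_c) log(1 - theta) + 2 N_c log(theta) - theta * p * sum(S_i)
```

whose closed form is the smaller root of the implied quadratic, clipped
to [0, 1]. Edge conventions: all-adjacent exceedances (`sum S = 0`) give
θ = 0 exactly (fixed-point limit); fewer than 2 exceedances, or a series
shorter than 100 samples, give NaN with a recorded reason. The closed
form is tested against direct numerical maximization of the same
likelihood to 1e-6 on random exceedance patterns, and against the two
analytic limits: iid input gives mean θ ≈ 0.98 (the estimator is
slightly below 1 at finite `n` because the empirical quantile forces a
fixed exceedance count), and a single contiguous exceedance run gives
θ = 0.

Repeating the estimate with every `ref_stride`-th observation as the
reference yields the fluidity time series; cost is O(n²/ref_stride).
The exponential tail scale σ (mean excess over the threshold, the
local-dimension proxy) is fitted alongside and stored, not analyzed.

## Microstates

Topographies are clustered by Lloyd k-means under signed correlation
distance `d = 1 - r` (Pearson across channels), hand-rolled because
library k-means is Euclidean; restarts (default 10) guard against local
minima and empty clusters are reseeded at the worst-fit sample.
`ignore_polarity=True` uses `1 - |r|`. The alternative route clusters
only global-field-power peaks (local maxima of across-channel variance
with prominence 0.5; prominence 0 falls back to plain local maxima) and
backfits every sample by maximal correlation. Recovered centroids are
matched to known templates with the Hungarian algorithm on (absolute)
correlation cost.

From the label sequence:

- **Transition matrix** — counts of consecutive-sample moves; rows of
  unvisited states are NaN.
- **Microstates fluidity** — `1 / mean(diagonal)` over visited states;
  1 when the sequence never switches, unbounded as dwells shrink.
- **Mean dwell** — `method="runs"` is the raw mean run length, unbiased
  only for noiseless labels. At finite SNR even an ideal classifier
  misassigns a few percent of samples, and independent misassignments
  fragment runs (a 4% error rate cuts an expected run of 10 to about 6),
  so `method="markov"` estimates the dwell from the lagged
  label-agreement curve `q_d = P(label_t = label_{t+d})`: independent
  label noise attenuates the amplitude of `q_d` but not its geometric
  decay rate, so the chain eigenvalue is recovered from median ratios of
  successive differences (lags 1–8) and the dwell follows from the stay
  probability of a symmetric K-state chain. On the synthetic generator at
  noise 0.3 this recovers the designed dwell within a few percent where
  the raw run length is ~40% low.
- **DL complexity** — the original description of a length-`n` sequence
  over an alphabet `A` costs `L_orig = |A| + n` tokens (the dictionary
  plus one position token per symbol). The compressed description lists,
  per symbol, (block length, shift) token pairs for its runs, the final
  block of each symbol carrying no shift token:
  `L_comp = |A| + sum(2 * blocks - 1)`. The reported value is
  `100**(L_comp / L_orig)`: 100 means no compression; below 100,
  dwell-dominated sequences; above 100, anti-compressible alternation.
  Hand-counted anchors: "AAAA" → (5, 2) → 100^0.4 ≈ 6.31; "A" → (2, 2)
  → 100; "ABABABAB" → (10, 16) → 100^1.6.
- **Occupancy entropy by fluidity decile** — Shannon entropy of state
  occupancy within rank-based deciles of the fluidity series, sampled at
  the fluidity reference times.

Per-subject summaries average fluidity and complexity over a K-sweep
(default K = 3…8), which avoids committing to one segmentation order.

## Spectral analysis

Spectrograms use Slepian (DPSS) tapers with time-bandwidth product 3 and
5 tapers, on the raw (non-coarse-grained) signal: 10 s windows with 5 s
overlap for band power, 60 s windows with 30 s overlap for the 40 Hz
stimulation bin (the longer window narrows the bins around 40 Hz; by
default the single nearest bin is read out, optionally ± an integration
half-width). The time-averaged spectrum of each channel is normalized to
unit total power, so band values are fractions; bands are half-open
[low, high): delta 0.5–4, theta 4–12, gamma 30–80 Hz. Channels are
averaged within six named cortical territories (PFC, MOC, SSC, PAR, RSC,
VIS); without an electrode map, channels are assigned to territories in
contiguous front-to-back blocks.

## Behavior

Pose tracks (DeepLabCut CSV with the 3-row scorer/bodyparts/coords
header, plus a JSON sidecar holding the arena corners and frame rate)
are normalized by translating the bottom-left corner to the origin,
rotating the bottom wall onto the x-axis, and scaling each axis by its
wall length — an exact inverse of any rotation+scale+offset camera
transform, including non-square arenas. The barycenter is the mean of
the neck and body-mid markers; speed is its per-frame displacement.
Egocentric coordinates rotate each barycenter-centered point by
`exp(i * (pi/2 - phi))`, `phi` the barycenter-to-neck angle, so the neck
points along +y; head movement is the per-frame change of the stacked
egocentric nose/ear 6-vector, exactly zero for rigid motion. The memory
index is `(t_new - t_familiar) / (t_new + t_familiar)`.

## Group statistics

`bootstrap_ks_compare` models each input distribution as a 200-bin
histogram, draws 5000 Monte-Carlo samples per group, and forms 500
bootstrap replicas of 500 observations under H1 (group-specific pools)
and H0 (merged pool); the statistic is the H1 replica mean ± sd of the
two-sample KS distance. The primary p-value is the overlap coefficient
of the H1 and H0 replica-KS histograms (shared area of the normalized
histograms): identical inputs give p near 1, separated replica
distributions give p = 0. A one-sided alternative — the fraction of H0
replicas reaching the H1 mean — is reported as `p_exceedance`; it is not
the primary value because under the null the KS statistic is
right-skewed, which concentrates the one-sided fraction near 0.37 rather
than spreading it over [0, 1]. Bonferroni correction over the requested
number of comparisons is applied to the primary value. Calibration and
power are tested end-to-end: on synthetic null cohorts the procedure
stays within a 10% false-positive budget, and a large designed
persistence gap is detected in ≥ 90% of seeds — provided the pooled
per-group sample is at least comparable to the replica size (500); with
much smaller pools the histogram model's own sampling noise inflates the
H1 replica distances.

Fluidity–behavior coupling uses decile binning (rank-based, so ties are
deterministic and bins equally populated): normalized mutual information
MI/max(H) with a paired-bootstrap observed estimate and an independently
shuffled null, and decile-wise locomotor medians with paired (H1) and
independent (H0) bootstrap bands.

## Synthetic generators

The generators are the package's study conditions, with known ground
truth rather than realism as the goal:

- `gen_iid_gaussian` — temporal independence; the Poisson limit θ → 1.
- `gen_var1` — channel-wise AR(1) with persistence ρ and a 1000-sample
  burn-in; persistence is the single knob that makes dynamics less
  fluid, and θ decreases monotonically in ρ.
- `gen_microstate_hmm` — K unit-norm random templates (redrawn until all
  pairwise |r| < 0.7), a symmetric Markov chain with stay probability
  `1 - 1/mean_dwell`, additive Gaussian observation noise. Ground-truth
  labels and templates are returned for recovery tests.
- `gen_pose_track` — a smoothed, wall-reflected random walk of the
  barycenter inside the unit arena with a rigid 8-marker skeleton under
  a drifting heading, rendered through a known rotation/scale/offset
  camera transform; the arena-frame ground truth is stored in metadata.
- `gen_cohort` — two groups of AR(1) subjects differing only in the
  designed persistence; subject seeds are `seed + index`.

Realism limits: real EEG is nonstationary, spatially correlated and
1/f-spectral, none of which AR(1) channels reproduce; the HMM's
geometric dwells are shorter-tailed than empirical microstate dwells;
the pose walk has no behavioral structure (no thigmotaxis, rearing or
object interactions). The generators validate estimator *properties*
(limits, monotonicity, recovery, calibration), not biological effect
sizes.

## Numerical choices and problem sizes

- Quantile thresholds use the empirical (`np.quantile`) estimator;
  exceedances are strict, so the exceedance count is fixed by `q` and
  the series length.
- Seeds: every stochastic routine takes an explicit seed;
  `numpy.random.default_rng` throughout; derived seeds stay below 2^31.
- Default analysis sizes in the pipeline (8 channels, a few thousand
  coarse samples, `ref_stride` 25) are scaled for interactive runs and
  CI; they are package choices, not biological constants — production
  runs on full-length recordings only change the cost, which is
  O(n²/ref_stride) for fluidity and linear elsewhere.
- The pipeline caches per-subject stage outputs keyed on a content hash
  of input plus parameters; the manifest echoes versions, seeds and
  every parameter so each number in a report is reproducible.

## Limitations

- The extremal-index machinery assumes stationarity within the analyzed
  window; drifting recordings should be segmented first.
- σ (local-dimension proxy) is stored but deliberately not analyzed.
- The finite-sample bias of θ at the Poisson limit (~0.98 instead of 1
  at n = 20,000, q = 0.98) is inherent to the fixed exceedance budget of
  the empirical quantile, not corrected for.
- The bootstrap KS p-value is a calibrated overlap measure, not a
  frequentist tail probability; use the provided calibration behavior
  (false-positive budget) rather than nominal α semantics when designing
  comparisons.
- EDF ingestion requires the optional `mne` dependency; native formats
  are plain TSV/JSON.
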
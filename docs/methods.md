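# Methods

## Scoring model

The Digital Facial Index (DFI) is a peak-based bilateral asymmetry score.
Its inputs are six blend-shape coefficient time series in [0, 1]: brow
raise, eye closure and mouth-corner lift, each for the subject's
anatomical left and right. Scoring proceeds in three steps:

1. **Maxima extraction.** For each channel, the maximum coefficient over
   all *valid* (face-tracked) frames. Invalid frames are excluded, never
   interpolated: a maximum over the surviving frames is unchanged by any
   gap that misses the movement peaks, which is what makes the score
   robust to intermittent tracking loss.
2. **Per-region assessment.** Within each region the side with the
   strictly greater maximum is attributed as healthy; the correction
   factor f_C = 1/max rescales it to 100 % and the weaker side
   proportionally, yielding the relative difference
   ΔM_rel = 100·(max−min)/max. This normalization makes the score
   invariant to overall movement amplitude (healthy subjects rarely drive
   the coefficients to 1.0 even at full effort).
3. **Weighted deduction.** DFI_side = 100 − Σ w_r·ΔM_rel(r) over the
   regions where that side is the weaker one, with default weights 0.10 /
   0.40 / 0.50 (forehead / eyes / mouth). Attribution is per region, so
   mixed findings can deduct from both sides; a side weaker in no region
   scores exactly 100.

Assumptions: the palsy is unilateral and expressed in voluntary gesture
amplitude; synkinesis, resting tone and bilateral palsy are outside the
model. Timestamps are authoritative; the nominal frame rate is metadata
only, since maxima are sampling-rate independent.

### Parameters

| parameter | default | meaning |
|---|---|---|
| region weights | 0.10 / 0.40 / 0.50 | functional/cosmetic importance of forehead / eyes / mouth; must sum to 1 |
| `activity_threshold` | 0.05 | if both side maxima of a region fall below it, the gesture was not performed; the region contributes zero asymmetry and is flagged, rather than dividing by ≈0 and reading a skipped gesture as palsy |
| display precision | 0.1 % | reporting only; internal computation is full double precision |

Degenerate inputs: an exact tie in maxima yields no healthy-side
attribution and no deduction (symmetric evidence). A session with no
valid frame raises an error; less than 1 s of valid tracking scores but
carries a warning. Coefficients on ingest are clamped into [0, 1] when
within ±0.05 of the range (logged) and rejected beyond that; NaN is
always rejected.

The `stennert_equivalent` mapping, 10·(1 − min-side DFI/100), is a linear
convenience onto the reciprocal 0–10 clinical scale and is not a
validated conversion.

## Synthetic motion model

The simulator stands in for the depth camera. Each measurement is a
5–15 s window (default 10 s) sampled at 60 frames/s, with the three
gestures scheduled as non-overlapping epochs — by default three equal
thirds in the order brow, eyes, mouth. Each gesture is a raised-cosine
pulse, 0.5·(1 − cos 2πφ) over the epoch, chosen because it is smooth,
unimodal and makes the noise-free channel maxima analytic (the pulse peak
equals the channel amplitude times the side factors). With the default
schedule every pulse midpoint falls on a sampling instant, so noise-free
sampled maxima equal the analytic peaks exactly.

Generative parameters and defaults:

- **Healthy amplitudes** 0.8 / 0.9 / 0.7 (forehead / eyes / mouth): full
  voluntary effort does not saturate tracked coefficients; eye closure
  comes closest.
- **Weakness** w_r ∈ [0, 1] multiplies the affected side's amplitude per
  region (1 healthy, 0 complete palsy).
- **Contralateral coupling** (default 0.05): the paralyzed side still
  shows a small fraction of the healthy side's movement; the affected
  side's factor is w + c·(1 − w).
- **Noise** `noise_sd` (default 0): additive zero-mean Gaussian per frame
  and channel, truncated by clamping into [0, 1].
- **Dropout**: a fraction of frames marked untracked, scattered at random
  or as one contiguous gap; at least one frame always survives.
- **Angle attenuation**: static per-side multiplicative factors with a
  region profile; `lateral_attenuation` builds the mouth-dominant profile
  (forehead and eyes 1.0, mouth < 1) that qualitatively emulates oblique
  camera angles. No optical model is attempted, and no attempt is made to
  reproduce hardware-specific angle numbers.

Identical scenario and seed reproduce the session byte-for-byte through
the raw-export writer.

What the simulator does *not* emulate: real tracker noise correlation in
time, drift, synkinetic co-movement, asymmetric gesture timing, facial
geometry. Passing tests therefore demonstrate correctness of the scoring
pipeline and its stated invariances under this generative model — not
clinical validity on real faces.

## Known limitation: peak-estimator noise bias

Under additive per-frame noise the sample maximum overestimates the true
peak by roughly σ·√(2 ln n_eff), where n_eff is the number of samples
competing near the peak (~600 for a silent channel over a 10 s window,
fewer near a pulse peak). The bias largely cancels between sides when
both move, but it inflates a near-silent weak side: at σ = 0.02 a fully
paralyzed mouth region reads ≈ +4 DFI points above the analytic truth.
The test suite documents a ±1.5-point tolerance band at σ = 0.02 for
replicate-mean recovery; that band is exceeded as regional weakness
approaches complete (w → 0), which is inherent to any max-based score
under additive noise, not an implementation defect. Likewise, single
noisy measurements of a symmetric subject scatter with a ≈3 % lower tail
below 97.5 %.

## Statistics

Repeated measurements are summarized per group by mean and sample SD
(n−1 denominator). Across ≥2 labeled groups a one-way ANOVA is computed
from the between/within sum-of-squares decomposition with
F = MS_between/MS_within, df = (k−1, N−k), and p from the F survival
function (reported to 4 decimals; significance at P ≤ .05). Degenerate
cases are explicit: all-constant groups with equal means give F = 0; zero
within-group variance with unequal means gives F = ∞, p = 0, flagged.
The from-scratch decomposition is cross-checked against
`scipy.stats.f_oneway` in the test suite.

## Test problem sizes

Property tests run on randomized small sessions (hundreds of examples);
simulation-based checks use the default 10 s / 60 Hz window (601 frames),
10 replicates per condition and a 4-subject × 10-measurement cohort for
the healthy-pattern check. The full suite and the acceptance script each
complete in well under a minute.
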
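# Methods

`magbehave` quantifies the readouts used to phenotype magnetogenetic
neuromodulation in freely moving mice: trajectory-derived motor behavior,
behavior conditioned on a measured magnetic field map, fiber-photometry
calcium dynamics, in vitro ROI fluorescence, FDG-PET uptake, and c-fos
histology. This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic-data generators do and do not
emulate.

## Trajectory behavior

Tracks are multi-keypoint arena coordinates (nose, center, fore/hind paws,
tail; cm) on a uniform time grid. Recordings digitized at 5 Hz are decimated
to the 2.5 Hz analysis grid by keeping every second frame (150 positions per
minute per keypoint), matching the manual-tracking protocol the metrics were
defined on.

**Freezing of gait.** The assay definition — at least 1 s with no change of
spatial position of the head, center, or extremities — is evaluated on
inter-sample steps: a step is *static* iff every required keypoint (default
nose, center, both paw points) is displaced by at most ε, and maximal runs of
static steps spanning ≥ `min_duration` become bouts. Choices:

- **ε (default 0.5 cm/step).** "No change of position" has no tolerance in
  the assay description, but tracking always jitters; 0.5 cm per 0.4 s step
  separates tracker noise (≤ ~0.1 cm) from locomotion (≳ 1 cm/step) by an
  order of magnitude on each side. Exposed in `FreezeParams`.
- **Grid for the 1-s rule.** The static predicate runs on the 2.5 Hz grid and
  a bout must span ≥ 1.0 s (three consecutive static steps). A run that
  reaches the end of the recording is credited with the final sample period,
  so a fully static recording scores its whole duration.
- **Gap policy.** A step with any required keypoint missing is non-static.
  This is deliberately conservative: tracker dropouts can only reduce, never
  inflate, freezing.

**Ambulation.** Distance is the summed center displacement; a step is active
when center speed exceeds a threshold (default 2 cm/s — below typical mouse
walking speed, above jitter); activity percent is active time over valid
(non-missing) time. Ambulation is reported as total active seconds per epoch;
mean bout length can be derived from the bouts if needed.

**Rotations.** Heading is the center→nose axis angle. The signed, unwrapped
heading increments feed a threshold-crossing counter with reset — ±90° per
count for open-field rotation scoring, ±360° for rotometer scoring. With a
declared lesion side, net contralateral = rotations away from the lesioned
hemisphere minus toward it. Degenerate body axes (zero-length or missing)
carry the previous heading and contribute no rotation.

## Field-map analysis

A gaussmeter map is a rectangular grid of flux density (mT) interpolated
bilinearly (exact at nodes, no extrapolation; out-of-hull positions count as
missing). Each 2.5 Hz sample contributes one sample period of occupancy to
the field bin of its center keypoint — the center is the body-exposure proxy,
not the nose — and samples inside freeze bouts contribute freezing time to
the same bin. Bins are half-open `[low, high)` with the last bin closed, so a
180 mT edge puts "at or above 180 mT" in the upper bin. Occupancy plus
missing time equals the epoch duration exactly. Regime labels follow the
field-source definitions (high: 0.5–1.3 T; low: 0.1–0.27 T, both in mT
internally).

## Fiber photometry

The isosbestic correction is a session-wide OLS fit of the 465 nm channel on
the 405 nm channel; the fitted trace is subtracted and the residual is
expressed in percent of its session median:
`net = F465 − F405_fitted`, `ΔF/F% = 100·(net − median(net))/median(net)`.
Numerical choices:

- **Filtering order.** Both raw channels are low-pass conditioned first
  (2nd-order Butterworth, 15 Hz corner, zero-phase), mirroring the
  acquisition chain; the filter is skipped when the corner is at or above
  Nyquist. The fit always covers the entire session; per-epoch refits are not
  offered.
- **Denominator guard.** After a session-wide OLS fit the residual median is
  ~0 by construction, so dividing by it is ill-posed. When |median(net)| is
  below 1% of median(F465), the denominator falls back to median(F465) and
  the trace is flagged (`denominator_guarded`). The stored denominator lets
  ΔF/F% be mapped back to raw fluorescence units, which is how event
  amplitudes are compared against ground truth.
- **Event values.** Epoch means average all samples in an epoch (no peak
  picking). Event alignment re-baselines each trial to its pre-event window
  mean; events whose window exceeds the session are dropped with a warning.

## ROI fluorescence

After frame-wise subtraction of a single background-ROI trace, each cell
trace is normalized to the mean over the baseline window (everything before
stimulus onset by default): `ΔF/F0 = (F − F0)/F0`. The quantity is signed —
calcium indicators rise, chloride-quench indicators (MQAE) fall. ROIs whose
baseline is non-positive after background subtraction are excluded and
reported. Per-cell peak is the maximum (largest |value| in quench mode,
signed value returned), earliest time on ties. AUC integrates ΔF/F0 over a
stated window (48–180 s for the magnet-exposure assay) by the trapezoid rule
on a grid refined with the interpolated window endpoints, which makes the
integral exactly additive over abutting windows. AUC is computed on ΔF/F0,
not raw fluorescence.

## PET quantification

Final dose = initial − residual activity (MBq). %ID/g = 100·C/(dose/weight)
with the standard small-animal 1 ml ≡ 1 g tissue convention; left and right
dorsal striata are averaged before any ratio. The cerebellum (no D2-type
receptors) is the reference region: the striatum/cerebellum ratio cancels
dose, weight and any global scanner calibration factor. Stimulation-over-
baseline ratios are emitted in both the raw-concentration and the
cerebellum-normalized variant. No radioactive-decay correction is applied.

## c-fos counting

The counting macro is deliberately fixed-parameter: Gaussian blur (sigma 2 px
— the blur radius is not part of the published macro parameters and is a
documented assumption), intensity threshold 30 of 255, connected components,
and removal of objects under 20 px (interpreted as minimum area). A c-fos
object is valid only when its centroid lies in the DAPI mask, and
double-positive when the centroid also lies inside a transduced-marker
object; the reported percentage is double positives over marker cells.
Centroid-in-mask colocalization is deterministic and size-robust. 16-bit
inputs are min-max rescaled to 8-bit with a warning. Quantification ROIs are
fixed-size crops drawn uniformly over the feasible position grid with
rejection of overlaps, reproducible by seed.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of its parameters including the seed, and
returns ground truth for parameter-recovery testing.

- **Locomotion** is a two-state semi-Markov process: ambulation is a
  correlated random walk at constant speed (default 8 cm/s, heading SD
  0.6 rad/frame, wall reflection) and freezing pins all keypoints up to
  tracking jitter (default SD 0.05 cm). Dwell times are gamma with shape 3;
  means realize the requested long-run freeze fraction (default freeze-bout
  mean 12 s). The gamma choice matters: memoryless (exponential) bouts put a
  substantial share of freeze time into bouts near or below the 1-s
  detectability floor of the assay definition, biasing any detector low;
  shape-3 bouts have a refractory-like hazard, which is also closer to
  observed bout-length statistics for strong indirect-pathway activation,
  where freezes last many seconds. Keypoints ride as rigid body-frame offsets
  rotated by heading, so rotation metrics are testable from the same
  process. Optional dropout runs emulate tracker gaps. A field-gated variant
  sets the freeze-entry hazard nonzero only where the local field is at or
  above a threshold, which produces the field-titration ground truth.
- **Photometry**: F465 = baseline·bleach + artifact + transient train +
  noise; F405 = iso_gain·(baseline·bleach + artifact) + noise. The artifact
  is a smooth random sum of slow sinusoids. No artifact or noise magnitudes
  are published for these recordings; the defaults (bleach tau 2000 s,
  artifact ~8% of baseline, noise 0.3%) describe a session in which shared
  artifacts are a substantial raw-signal component — the regime the
  isosbestic correction exists for. Transients are difference-of-exponential
  kernels (rise 0.5 s, decay 2.5 s) normalized to unit peak.
- **Field maps** decay exponentially with distance from the magnet-proximal
  edge, uniform across the width; the decay length can be fixed directly or
  chosen so the distal edge sits at a stated value (e.g. a 100–270 mT
  titration map).
- **Cell images** place non-overlapping disks with a minimum separation
  (default 2r + 8 px) so blurring cannot merge neighbors; the positive subset
  is exactly `round(n·fraction)`.
- **PET tables** draw per-animal cerebellar uptake and apply a striatal
  contrast at baseline and a multiplicative gain under stimulation, with
  a few-percent measurement noise.

None of the generators model biophysics — channel gating, ferritin
magnetics, hemodynamics, or neuron-to-behavior coupling. Passing recovery
tests therefore shows that the *quantification* is correct and unbiased under
realistic noise, not that the pipeline would reproduce any particular animal
experiment.

## Problem sizes and determinism

Default validation sizes are chosen to estimate each quantity stably at desk
scale: 600 s tracks × 20 seeds for freeze-fraction recovery, 300 s × 10
sessions for the field-threshold pattern, 50 event-locked trials for
amplitude recovery, 100-cell images for counting, 10-animal PET cohorts, 100
random datasets for statistics cross-checks. All randomness flows through
numpy `default_rng` seeds; the pipeline writes reports with sorted keys and
no timestamps, so a config plus seed reproduces outputs byte-for-byte.

## Known limitations

- The freezing detector's time resolution is one analysis step (0.4 s);
  bout boundaries are accurate only to that quantum.
- Samples are assigned to field bins through the *tracked* (jittered) center,
  so a freeze located within the jitter range of a bin edge can place
  isolated samples in the neighboring bin.
- The EthoVision reader shim covers the common semicolon dialect with a
  metadata preamble, not every export variant.
- ANOVA/Tukey and Holm corrections are wrapped from scipy/statsmodels, not
  re-derived; paired contrasts assume complete pairs.
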
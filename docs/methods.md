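# Methods

This note documents the models, numerical choices and limitations behind
`pursuitlab`. The README describes what the package computes; this note
describes *how* and *why*, at the level a maintainer or reviewer needs.

## Signal model

A session consists of three time series in degrees of visual angle: the
hand-moved target location (scene-camera clock, nominally 29.97 Hz) and the
two gaze positions with pupil diameter (eye-camera clock, nominally 240 Hz).
Timestamps are stored per sample and used directly everywhere; the nominal
rates are metadata. This matters because the clinically reported latencies
are quantized by the real scene-camera frame clock — analysis on an assumed
uniform grid would hide exactly the structure the numbers show.

The pursuit channel is modelled (and simulated) as

    eye(t) = o + g · (target(t − L) − o) + ε(t)

where `o` is the plate-vs-camera offset, `g` the pursuit gain, `L` the
latency and `ε` tracking/measurement noise. Gain scales the excursion about
the plate centre; the delay is applied in continuous time before sampling,
so frame quantization of the estimates arises from the clocks rather than
being injected.

## Preprocessing

* **Blink rule.** Sample *i* of an eye trace is blink-flagged when
  |pupil[i] − pupil[i−1]| > 2 mm. A blink produces a collapse and a recovery
  transition, so both its entry and exit samples are flagged; the samples in
  between are position dropouts (invalid) and are caught by the missing-data
  path. The rule is applied on the eye-camera clock, where pupil diameter
  lives.
* **Gap interpolation.** Blink-flagged and missing samples are replaced by
  linear interpolation in time against the nearest valid neighbours;
  leading/trailing gaps are constant-extended. Valid samples are returned
  bit-for-bit unchanged (property-tested). Missing target frames (detector
  dropouts, < 1% of frames) receive the symmetric treatment before
  synchronization.
* **I-VT filter.** Per-sample 2-D speed is the Euclidean first difference
  over Δt. Speeds are averaged over tiled blocks of 3 samples, and a sample
  is a saccade when the median of its block's speed with its two neighbours
  exceeds 100°/s (edge blocks clamp the neighbourhood). The median exists to
  reject isolated one-frame spikes — a lone 240°/s frame is *not* a saccade
  under this rule, while any ≥ 100°/s movement sustained over a couple of
  blocks is. Whether the windows tile or slide is an open choice; the block
  arithmetic is isolated in `_window_speeds` so the alternative reading is a
  one-function substitution.
* **Synchronization.** Both eyes are linearly interpolated at every target
  timestamp inside the common time span (down-sampling to the scene-camera
  clock); the target series is preserved exactly. Latency and gain are
  therefore measured on the clock that also quantizes them. Saccade/blink
  flags are carried to the nearest synced sample.

## Direction classification

The per-recording median of the target track defines the relative origin;
subtracting it removes the unknown plate-vs-camera offset from every later
step (the whole pipeline is translation-invariant, which is property-tested).
The position vector r(t) collapses the 2-D track to its distance from that
origin.

Peak detection keeps alternating maxima/minima of r with same-type extrema
≥ 3 s apart: local extrema come from sign changes of the first difference
(plateaus count once, at their centre), same-type extrema closer than the
separation are pruned greedily keeping the more extreme one, and alternation
is enforced by keeping the single lowest minimum between consecutive maxima
(and symmetrically). Two additions make this robust on real-shaped data:

* maxima that never reach `min_peak_height` (default 2°) are discarded
  up front — hand tremor wiggles r around the origin during rest phases, and
  motion that stays inside the central region is not a sweep;
* if the outermost retained extremum is a maximum, the rest-phase minimum at
  the trace end is added, so the first and last sweeps are properly bounded
  (a triangular wave of n cycles has n + 1 valleys, the outer two at the
  endpoints).

Each (min, max, min) triple is one excursion. Medians of the origin-corrected
horizontal/vertical location are taken over the triple's interval with 1 s
trimmed from both ends, which removes the ramp tails nearest the rest phases.
The eight excursions are then rank-grouped (three smallest h-medians = left
group, three largest = right, likewise vertically); an excursion in two
groups is oblique, the remaining member of each group cardinal. Ranking ties
are broken by larger peak amplitude, then presentation order — exact ties are
measure-zero on real data but must not crash. On well-formed sessions the
result is a bijection onto the eight directions; anything else raises a
degeneracy error listing the ambiguous excursions rather than guessing.

The threshold baseline bins each excursion's medians into fixed ±2° boxes in
the *camera* frame (no origin correction — that is the point of the
comparison); medians inside the central box are unclassified. The 2° default
half-width can be re-derived from a calibration cohort via
`derive_threshold_cutoff` (minimum over directions of mean − 2 SD of the
informative median components).

## Latency and gain

Each series — target, left eye, right eye — is origin-corrected with the same
relative origin and segmented **on its own position vector**. This is the one
place the implementation departs from the obvious composition (reusing the
target's segment window for the eyes): a pursuing eye lags the target, and a
cubic fitted to a delayed bump inside a window centred on the *target's*
sweep amplifies the delay roughly 2.2× (measured on trapezoidal sweeps).
Segmenting each series on its own minima keeps each fit window centred on its
own sweep. Eye excursions are matched to target excursions by nearest
maximum-peak time.

Within a min-to-min span, the cubic is fitted between the first and last
quarter-amplitude crossings of r rather than over the whole span. The
bounding minima fall wherever hand tremor happens to dip during the flat
rest phases, so the full span is asymmetric about the sweep by up to a
couple of seconds, and a cubic fitted to a flat-topped bump in an asymmetric
window drags its peak toward the longer side by hundreds of milliseconds.
The quarter-amplitude window is symmetric about the sweep by construction,
includes enough of both ramps to pin the cubic's curvature, and keeps the
fitted-peak error below ~7 ms across sample-grid phases and amplitudes
(measured on noiseless trapezoids; the full-span fit reaches ~54 ms). The
fitted peak time is snapped to the nearest raw sample; the raw r there is
the peak amplitude.

Latency = (eye snapped peak time − target snapped peak time) × 1000, signed,
positive when the eye lags. With ideal timestamps every estimate is an
integer number of scene-camera frames (33.37 ms), matching the pattern
clinical values show. Under the default noise model the per-excursion
scatter is ≈ 60–100 ms SD — comparable to the spread real cohorts show — and
the median error across excursions stays within half a frame.

Gain uses the outgoing (centrifugal) limb only: for each series, the window
runs from the first crossing of 25% of its peak amplitude to the first
crossing of 75%, each located by linear interpolation between the bracketing
samples ("first crossing" on the noisy trace; if both crossings fall inside
one sample interval the limb is a step and the window is rejected). The
25%/75% levels are amplitude fractions, not value-distribution percentiles:
the level lines sit on the rising ramp. An ordinary least-squares line of r
versus t is fitted inside each series' own window — using the target's
window for the eye would bias the sampled limb by the latency — and gain is
the eye/target slope ratio. Saccade-flagged samples are excluded from the
eye regression (≥ 3 samples must remain); excluding them prevents catch-up
saccades from inflating pursuit gain, which is exactly the quantity they
corrupt. Known estimator property: because the window endpoints are chosen
where noise first pushes r across the level, correlated noise biases the
slope ratio slightly downward (≈ −0.02 at gain 1.0, ≈ −0.04 at gain 0.7
under the default noise model); the recovery tests bound the effect at 0.05.

Per-excursion failures (degenerate segments, unreachable windows, too few
usable samples) are recorded on the metrics row, never fatal to the session.

## The synthetic-data generator

`SimulationConfig` defaults describe one healthy subject under the clinical
protocol and are the conditions the test suite and acceptance script run:

| parameter | default | meaning |
|---|---|---|
| `amplitude` | (10, 15)° | radial sweep amplitude, inside the ±15° test field (obliques on the diagonal) |
| `ramp_speed` | 10°/s | examiner's hand speed, the reference speed for healthy gain |
| `dwell`, `center_dwell` | 2 s | peripheral hold and central rest; must stay below the 3 s peak separation so each rest phase keeps exactly one retained extremum |
| `lead_in` | 3 s | initial central fixation |
| `plate_offset` | ±5° per axis | plate-vs-camera misalignment, drawn per subject |
| `latency_ms` | (50, 300) ms | healthy pursuit latency range, drawn per subject |
| `gain` | (0.85, 1.0) | healthy pursuit gain range, drawn per subject |
| `jitter_sd` | 0.3° (2 Hz low-pass) | hand tremor on the target path |
| `noise_sd` | 0.5° | total per-axis gaze error: slow drift (2 Hz low-pass) plus 0.1° white frame noise |
| `blink_rate` | 3/min | binocular pupil collapses (4 → 1 mm) with 200 ms position dropout |
| `saccade_rate` | 6/min/eye | 3° catch-up intrusions over 25 ms (300°/s limbs) |
| `eye_rate`, `target_rate` | 240, 29.97 Hz | the two camera clocks |

Noise spectra are deliberate: VOG gaze error is dominated by slow accuracy
drift (calibration residue, fixational wander — the 0.2–0.5° figure a
tracker quotes), with only ~0.1° frame-to-frame precision noise. White noise
at the full 0.5° would read as continuous > 100°/s motion and no I-VT filter
could ever have worked on such a device. Filtered-noise series are generated
with padding and cropped so filter edge transients never leak into a trace.

What the generator does **not** emulate: head movement, asymmetric or
direction-dependent pursuit deficits, saccades that persistently re-position
the eye (intrusions return to the pursuit path), pupil-size dynamics beyond
blinks, detector mislocalizations (only dropped frames), or examiner paths
that deviate from ramp-hold-return. Passing tests therefore demonstrate
correctness of the *algorithms* under a faithful rendering of the protocol's
geometry and clocks, not robustness to every pathology of clinical data.

Determinism: cohorts draw per-subject random streams spawned from the config
seed, so a fixed seed reproduces every trace bitwise, independent of session
lengths.

## Numerical details and degenerate inputs

* Cubic fits centre the time axis before `polyfit` for conditioning; a
  constant segment raises a degenerate-segment error; a segment with no
  interior concave stationary point falls back to the raw argmax (monotone
  limbs).
* First-crossing times interpolate linearly between the bracketing samples.
* Peak-detector ties on plateaus resolve to the plateau centre sample.
* The synchronizer requires a non-empty three-way time overlap; empty
  overlap, all-invalid traces, and non-monotone timestamps raise typed
  errors naming the offending row where applicable.
* Sessions whose segmentation does not yield exactly the expected excursion
  count fail loudly (`ExcursionCountError`); the expected count is
  configurable for partial protocols.

## Problem sizes used by the test suite and acceptance script

The bundled checks run cohorts of 1–23 subjects (8 sweeps each, ~55 s of
simulated session time per subject; ≈ 13 000 eye samples and ≈ 1 650 target
frames). Recovery properties use 100+ excursions per parameter level. The
full suite runs in well under a minute on one CPU; the acceptance script in
a few seconds.

## Known limitations

* The latency estimator's per-excursion scatter under realistic hand paths
  (flat 2 s dwells plus tremor) is of the order of one to three scene-camera
  frames; the peak time of a flat-topped noisy sweep is intrinsically less
  determined than that of a triangular one. Medians across excursions are
  frame-accurate.
* The slope-ratio gain carries the small downward bias described above;
  clinical interpretation against a 0.9 normal-range bound is unaffected.
* The threshold baseline is implemented exactly as the fixed-box rule it is
  meant to represent; its accuracy on offset recordings is a property of the
  rule, not a tunable of this package.
* `expected_excursions` other than 8 disables the rank-grouping classifier
  (it is defined by the 3-of-8 grouping); partial protocols can still be
  segmented and measured.
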
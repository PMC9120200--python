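# pursuitlab

Trigger-free analysis of smooth pursuit eye movements for clinical
nine-direction testing.

## The problem

In routine ophthalmic practice, smooth pursuit is assessed by having the
patient track a hand-held fixation target that the examiner moves to the
center and eight peripheral directions. Video-oculography (VOG) records both
eyes at 240 Hz, and an object detector on the scene camera reports the target
location at 29.97 Hz — but nothing records *when* each sweep started or
*which* direction it went. Without a stimulus trigger, the latency and gain
measures that laboratory setups compute cannot be read off directly.

`pursuitlab` recovers all of it from the two position streams alone:

1. **Preprocessing** — blink rejection (pupil-diameter jumps > 2 mm/frame),
   linear interpolation of gaps, saccade flagging with a velocity-threshold
   (I-VT) filter (median of three consecutive 3-sample window speeds >
   100°/s), and synchronization of both eyes onto the target's 29.97 Hz
   timeline.
2. **Direction classification** — the target track is re-expressed relative
   to its own median location (the *relative origin*, standing in for the
   unknown center of the hand-held plate) and collapsed to the position
   vector r(t) = ‖(x, y) − (x₀, y₀)‖. Alternating maxima/minima of r, at
   least 3 s apart, delimit one *excursion* per sweep. After trimming 1 s
   from each end, the per-axis medians of the eight excursions are ranked:
   the three smallest horizontal medians form the left group, the three
   largest the right group (and likewise vertically); membership in two
   groups names an oblique direction, the remainder of each group the
   cardinal one. Because everything is relative to the recording's own
   origin, a constant plate-vs-camera offset cannot break the labels — the
   failure mode that defeats the conventional fixed ±2° box classifier,
   which is included as a baseline.
3. **Latency and gain** — each series (target, left eye, right eye) is
   converted to its position vector and each excursion fitted with a cubic
   polynomial; the fitted peak time, snapped to the nearest raw sample,
   is the series' peak time. Latency is the eye-minus-target peak-time
   difference (so it comes out quantized to the 33.4 ms scene-camera frame),
   and gain is the ratio of the eye's to the target's ordinary-least-squares
   slope of r versus t inside each series' own 25–75% amplitude window on
   the outgoing limb, with saccade-flagged samples excluded.

A bundled simulator generates complete ground-truthed sessions — ramp-and-
hold target sweeps with hand jitter and plate offset, eyes that follow with
configurable latency (50–300 ms) and gain (0.7–1.1), tracking noise, blinks
and catch-up saccades — so the whole pipeline is testable without any
recordings.

## Worked example

```python
from pursuitlab import AnalysisConfig, SimulationConfig, run_pipeline, render_tables

sim = SimulationConfig(n_subjects=5, seed=42)   # 5 subjects, 8 sweeps each
report, per_excursion = run_pipeline(sim, AnalysisConfig())

peak = report.classification["peak"]
thr = report.classification["threshold"]
print(f"peak classifier:      {peak['correct']}/{peak['total']} correct "
      f"({peak['accuracy_pct']:.1f}%)")
print(f"threshold classifier: {thr['correct']}/{thr['total']} correct "
      f"({thr['accuracy_pct']:.1f}%)")
tables = render_tables(report)
print(tables["latency_table"].head(4).to_string(index=False))
print(tables["gain_table"].head(4).to_string(index=False))
```

prints

```
peak classifier:      40/40 correct (100.0%)
threshold classifier: 28/40 correct (70.0%)
direction   eye  n  latency_ms_mean  latency_ms_sd
     left  left  5        186.85352     119.376335
     left right  5        120.12012      69.190662
    right  left  5        160.16016     123.501872
    right right  5        186.85352     134.712240
direction   eye  n  gain_mean  gain_sd
     left  left  5   0.790239 0.089867
     left right  5   0.959351 0.165878
    right  left  5   0.815195 0.076310
    right right  5   0.920340 0.234269
```

The peak-fitting classifier labels all 40 sweeps despite per-subject plate
offsets of up to 5°, while the fixed-box baseline mislabels 12 of them.
Latency means sit in the healthy 50–300 ms range (and are multiples of the
33.37 ms scene-camera frame); gains sit near the injected 0.85–1.0 range.
`per_excursion` holds the row-per-eye-per-sweep values behind these
aggregates.

The same stages are available on the command line:

```bash
pursuitlab simulate --out-dir sessions/          # CSV traces + truth.json
pursuitlab preprocess --eye sessions/S01_left.csv --eye sessions/S01_right.csv \
    --target sessions/S01_target.csv --out synced.csv
pursuitlab classify --synced synced.csv --method peak --out labels.json
pursuitlab analyze --synced synced.csv --out metrics.csv
pursuitlab run --out report/                     # whole cohort, one command
```

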
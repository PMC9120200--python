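"""Relative origin, position vector, peak detection, and both classifiers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pursuitlab import (
    AnalysisConfig,
    Direction,
    TargetTrace,
    classify_peak,
    classify_threshold,
    detect_peaks,
    relative_origin,
    score_classification,
    segment_excursions,
    simulate_session,
    to_position_vector,
)
from pursuitlab.direction import (
    Excursion,
    PositionVectorTrace,
    RelativeOrigin,
    classify_threshold_session,
    derive_threshold_cutoff,
)
from pursuitlab.errors import (
    ClassificationDegeneracyError,
    ExcursionCountError,
    SegmentTooShortError,
)
from pursuitlab.preprocess import preprocess_recording
from pursuitlab.report import classify_session

from conftest import quiet_sim_config


class TestRelativeOrigin:
    def test_constant_track(self):
        n = 10
        target = TargetTrace(t=np.arange(n) / 29.97, x=np.full(n, 3.0), y=np.full(n, -2.0))
        assert relative_origin(target) == pytest.approx((3.0, -2.0))

    def test_symmetric_track_centres_at_zero(self):
        angles = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        x = np.concatenate([10 * np.cos(angles), np.zeros(20)])
        y = np.concatenate([10 * np.sin(angles), np.zeros(20)])
        target = TargetTrace(t=np.arange(28) / 29.97, x=x, y=y)
        assert relative_origin(target) == pytest.approx((0.0, 0.0), abs=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(
        xs=st.lists(st.floats(min_value=-20, max_value=20), min_size=2, max_size=30),
        ys=st.lists(st.floats(min_value=-20, max_value=20), min_size=2, max_size=30),
    )
    def test_matches_sort_and_pick_median(self, xs, ys):
        n = min(len(xs), len(ys))
        target = TargetTrace(t=np.arange(n) / 29.97, x=xs[:n], y=ys[:n])
        got = relative_origin(target)

        def median_oracle(vals):  # sort-and-pick, averaging the middle pair
            s = sorted(vals)
            m = len(s) // 2
            return s[m] if len(s) % 2 else 0.5 * (s[m - 1] + s[m])

        assert got.x0 == pytest.approx(median_oracle(xs[:n]))
        assert got.y0 == pytest.approx(median_oracle(ys[:n]))


class TestPositionVector:
    def test_three_four_five(self):
        pv = to_position_vector([0.0], [3.0], [4.0], RelativeOrigin(0.0, 0.0))
        assert pv.r[0] == pytest.approx(5.0)

    def test_origin_maps_to_zero(self):
        pv = to_position_vector([0.0], [2.0], [-1.0], RelativeOrigin(2.0, -1.0))
        assert pv.r[0] == 0.0

    @settings(max_examples=50, deadline=None)
    @given(data=st.data())
    def test_matches_per_point_hypotenuse(self, data):
        n = data.draw(st.integers(min_value=1, max_value=20))
        vals = st.floats(min_value=-30, max_value=30)
        xs = [data.draw(vals) for _ in range(n)]
        ys = [data.draw(vals) for _ in range(n)]
        ox, oy = data.draw(vals), data.draw(vals)
        pv = to_position_vector(np.arange(n), xs, ys, RelativeOrigin(ox, oy))
        for i in range(n):
            assert pv.r[i] == pytest.approx(((xs[i] - ox) ** 2 + (ys[i] - oy) ** 2) ** 0.5)


def peak_oracle(t, r, separation, min_height):
    """Literal rule-by-rule pruning, all loops, no vectorization."""
    maxima, minima = [], []
    d = [np.sign(r[i + 1] - r[i]) for i in range(len(r) - 1)]
    nz = [i for i, s in enumerate(d) if s != 0]
    for a, b in zip(nz[:-1], nz[1:]):
        if d[a] != d[b]:
            idx = (a + 1 + b) // 2
            (maxima if d[a] > 0 else minima).append(idx)
    maxima = [i for i in maxima if r[i] >= min_height]

    def prune(idxs, better):
        kept = []
        for i in idxs:
            if kept and t[i] - t[kept[-1]] < separation:
                if better(r[i], r[kept[-1]]):
                    kept[-1] = i
            else:
                kept.append(i)
        return kept

    maxima = prune(maxima, lambda a, b: a > b)
    minima = prune(minima, lambda a, b: a < b)
    merged = sorted([(i, "max") for i in maxima] + [(i, "min") for i in minima],
                    key=lambda p: t[p[0]])
    out = []
    for i, kind in merged:
        if out and out[-1][1] == kind:
            keep_new = r[i] > r[out[-1][0]] if kind == "max" else r[i] < r[out[-1][0]]
            if keep_new:
                out[-1] = (i, kind)
        else:
            out.append((i, kind))
    if out and out[0][1] == "max" and out[0][0] > 0:
        seg = list(r[: out[0][0]])
        lo = min(seg)
        ties = [j for j, v in enumerate(seg) if v == lo]
        out.insert(0, (ties[(len(ties) - 1) // 2], "min"))
    if out and out[-1][1] == "max" and out[-1][0] < len(r) - 1:
        start = out[-1][0] + 1
        seg = list(r[start:])
        lo = min(seg)
        ties = [j for j, v in enumerate(seg) if v == lo]
        out.append((start + ties[(len(ties) - 1) // 2], "min"))
    return out


class TestDetectPeaks:
    def test_triangular_wave_yields_alternating_apexes_and_valleys(self):
        t = np.arange(0, 40, 1 / 29.97)
        r = 10.0 * np.abs(2 * ((t / 8) % 1) - 1)  # valleys at 4, 12, ...; apexes at 0, 8, ...
        r = 10.0 - r  # apexes at 4, 12, ...; valleys at 0, 8, ..., 40
        extrema = detect_peaks(PositionVectorTrace(t=t, r=r), separation=3.0)
        kinds = [e.kind for e in extrema]
        assert kinds == ["min", "max"] * 5 + ["min"]
        apex_times = [e.t for e in extrema if e.kind == "max"]
        np.testing.assert_allclose(apex_times, [4, 12, 20, 28, 36], atol=0.05)

    def test_constant_trace_has_no_extrema(self):
        t = np.arange(0, 10, 1 / 29.97)
        assert detect_peaks(PositionVectorTrace(t=t, r=np.full(len(t), 2.0))) == []

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_matches_exhaustive_pruning_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(0, 25, 1 / 29.97)
        r = np.full(len(t), 1.0)
        for _ in range(rng.integers(1, 5)):  # smooth random multi-bump profile
            c = rng.uniform(2, 23)
            w = rng.uniform(0.5, 3.0)
            r += rng.uniform(3, 12) * np.exp(-((t - c) ** 2) / (2 * w**2))
        got = detect_peaks(PositionVectorTrace(t=t, r=r), separation=3.0, min_peak_height=2.0)
        expected = peak_oracle(t, r, 3.0, 2.0)
        assert [(e.index, e.kind) for e in got] == expected


def make_session_pv(amplitudes, dwell=2.0, rest=2.0, speed=10.0, rate=29.97):
    """Piecewise-linear position-vector profile of consecutive sweeps."""
    knots_t, knots_r = [0.0], [0.0]
    for amp in amplitudes:
        ramp = amp / speed
        for dt_, r_ in ((rest, 0.0), (ramp, amp), (dwell, amp), (ramp, 0.0)):
            knots_t.append(knots_t[-1] + dt_)
            knots_r.append(r_)
    knots_t.append(knots_t[-1] + rest)
    knots_r.append(0.0)
    t = np.arange(0, knots_t[-1], 1 / rate)
    return t, np.interp(t, knots_t, knots_r)


class TestSegmentExcursions:
    def test_single_sweep_medians_reflect_the_dwell_location(self):
        t, r = make_session_pv([10.0], dwell=4.0)
        h = r.copy()       # sweep to (10, 0)
        v = np.zeros_like(r)
        extrema = detect_peaks(PositionVectorTrace(t=t, r=r))
        excs = segment_excursions(PositionVectorTrace(t=t, r=r), extrema, 1.0, h, v)
        assert len(excs) == 1
        assert excs[0].h_med == pytest.approx(10.0, abs=0.5)
        assert excs[0].v_med == pytest.approx(0.0, abs=1e-9)

    def test_eight_sweep_session_segments_in_presentation_order(self):
        rec, truth = simulate_session(quiet_sim_config(seed=5))
        synced = preprocess_recording(rec, AnalysisConfig())
        peak, _ = classify_session(synced, AnalysisConfig())
        assert len(peak.excursions) == 8
        onsets = [e.onset_t for e in truth.excursions]
        max_ts = [e.max_t for e in peak.excursions]
        assert all(a < b for a, b in zip(max_ts[:-1], max_ts[1:]))
        # each detected apex falls after its sweep's onset and before the next
        for k, m in enumerate(max_ts):
            assert m > onsets[k]
            if k + 1 < len(onsets):
                assert m < onsets[k + 1]

    def test_trim_wider_than_triple_is_an_error(self):
        from pursuitlab.direction import Extremum

        t = np.arange(0, 20, 1 / 29.97)
        r = np.interp(t, [0, 6.5, 7.25, 8.0, 20], [0, 0, 10, 0, 0])

        def at(tq, kind):
            i = int(np.argmin(np.abs(t - tq)))
            return Extremum(float(t[i]), float(r[i]), kind, i)

        # a min->max->min triple spanning only 1.5 s cannot survive 1 s trims
        triple = [at(6.5, "min"), at(7.25, "max"), at(8.0, "min")]
        with pytest.raises(SegmentTooShortError):
            segment_excursions(PositionVectorTrace(t=t, r=r), triple, 1.0, r, r)


def ideal_excursions(offsets=None, jitter=None):
    """Eight excursions with textbook medians, one per direction."""
    medians = {
        Direction.LEFT: (-10, 0), Direction.RIGHT: (10, 0),
        Direction.UPPER: (0, 10), Direction.LOWER: (0, -10),
        Direction.UPPER_LEFT: (-10, 10), Direction.UPPER_RIGHT: (10, 10),
        Direction.LOWER_LEFT: (-10, -10), Direction.LOWER_RIGHT: (10, -10),
    }
    out, truth = [], {}
    for k, (d, (h, v)) in enumerate(medians.items()):
        dh, dv = jitter[k] if jitter is not None else (0.0, 0.0)
        out.append(Excursion(ordinal=k, start_t=8.0 * k, max_t=8.0 * k + 4,
                             end_t=8.0 * k + 8, h_med=h + dh, v_med=v + dv,
                             peak_r=float(np.hypot(h, v))))
        truth[k] = d
    return out, truth


class TestClassifyPeak:
    def test_ideal_medians_recover_all_eight_labels(self):
        excs, truth = ideal_excursions()
        result = classify_peak(excs)
        assert result.labels == truth

    @settings(max_examples=40, deadline=None)
    @given(data=st.data())
    def test_one_degree_noise_never_changes_labels(self, data):
        jitter = [
            (data.draw(st.floats(min_value=-1, max_value=1)),
             data.draw(st.floats(min_value=-1, max_value=1)))
            for _ in range(8)
        ]
        excs, truth = ideal_excursions(jitter=jitter)
        assert classify_peak(excs).labels == truth

    @settings(max_examples=30, deadline=None)
    @given(perm=st.permutations(range(8)))
    def test_labels_invariant_under_presentation_order(self, perm):
        excs, truth = ideal_excursions()
        shuffled = [
            Excursion(ordinal=excs[i].ordinal, start_t=8.0 * k, max_t=8.0 * k + 4,
                      end_t=8.0 * k + 8, h_med=excs[i].h_med, v_med=excs[i].v_med,
                      peak_r=excs[i].peak_r)
            for k, i in enumerate(perm)
        ]
        assert classify_peak(shuffled).labels == truth

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_output_is_always_a_bijection_under_noise(self, seed):
        rng = np.random.default_rng(seed)
        jitter = rng.uniform(-2, 2, size=(8, 2))
        excs, _ = ideal_excursions(jitter=jitter)
        labels = classify_peak(excs).labels
        assert sorted(labels) == list(range(8))
        assert set(labels.values()) == set(Direction)

    def test_wrong_count_fails_loudly(self):
        excs, _ = ideal_excursions()
        with pytest.raises(ExcursionCountError):
            classify_peak(excs[:7])

    def test_degenerate_medians_fail_loudly(self):
        excs, _ = ideal_excursions()
        for e in excs:
            e.h_med, e.v_med = 0.0, 0.0
        with pytest.raises(ClassificationDegeneracyError):
            classify_peak(excs)


class TestClassifyThreshold:
    @pytest.mark.parametrize(
        "h,v,expected",
        [
            (-5.0, 0.0, Direction.LEFT),
            (5.0, 1.9, Direction.RIGHT),
            (3.0, 3.0, Direction.UPPER_RIGHT),
            (-3.0, 3.0, Direction.UPPER_LEFT),
            (-3.0, -3.0, Direction.LOWER_LEFT),
            (3.0, -3.0, Direction.LOWER_RIGHT),
            (0.0, 9.0, Direction.UPPER),
            (1.0, -9.0, Direction.LOWER),
            (0.0, 0.0, None),
            (1.9, 1.9, None),
        ],
    )
    def test_box_rules(self, h, v, expected):
        assert classify_threshold(h, v, cutoff=2.0) == expected

    def test_cutoff_must_be_positive(self):
        with pytest.raises(ValueError):
            classify_threshold(0.0, 0.0, cutoff=0.0)


class TestScoreClassification:
    def test_identical_maps_score_perfectly(self):
        _, truth = ideal_excursions()
        score = score_classification(truth, truth)
        assert (score.correct, score.incorrect) == (8, 0)

    def test_one_swap_miscounts_two(self):
        _, truth = ideal_excursions()
        pred = dict(truth)
        pred[0], pred[1] = pred[1], pred[0]
        score = score_classification(pred, truth)
        assert (score.correct, score.incorrect) == (6, 2)

    def test_unclassified_counts_as_incorrect(self):
        _, truth = ideal_excursions()
        pred = dict(truth)
        pred[3] = None
        assert score_classification(pred, truth).incorrect == 1

    def test_cohort_of_23_subjects_scores_184_trials(self):
        total = 0
        _, truth = ideal_excursions()
        for _ in range(23):
            total += score_classification(truth, truth).total
        assert total == 184


class TestPipelineInvariants:
    def test_translation_invariance_of_labels_and_excursions(self):
        base_cfg = quiet_sim_config(seed=3, jitter_sd=0.3, noise_sd=0.5)
        rec, truth = simulate_session(base_cfg)
        synced = preprocess_recording(rec, AnalysisConfig())
        peak_a, _ = classify_session(synced, AnalysisConfig())
        dx, dy = 4.2, -6.9
        for arr in (synced.target_x, synced.left_x, synced.right_x):
            arr += dx
        for arr in (synced.target_y, synced.left_y, synced.right_y):
            arr += dy
        peak_b, _ = classify_session(synced, AnalysisConfig())
        assert peak_a.labels == peak_b.labels
        for a, b in zip(peak_a.excursions, peak_b.excursions):
            assert a.h_med == pytest.approx(b.h_med, abs=1e-9)
            assert a.start_t == b.start_t and a.end_t == b.end_t

    def test_classifiers_agree_without_offset_but_threshold_breaks_under_offset(self):
        """The motivating failure mode: a plate-vs-camera offset at or above
        the cutoff degrades the fixed-box classifier while the relative-origin
        peak classifier is untouched."""
        cfg_centered = quiet_sim_config(seed=9, plate_offset=(0.0, 0.0))
        rec, truth = simulate_session(cfg_centered)
        synced = preprocess_recording(rec, AnalysisConfig())
        peak, thr = classify_session(synced, AnalysisConfig())
        assert peak.labels == truth.labels
        assert thr.labels == truth.labels

        cfg_offset = quiet_sim_config(seed=9, plate_offset=(4.0, 4.0))
        rec, truth = simulate_session(cfg_offset)
        synced = preprocess_recording(rec, AnalysisConfig())
        peak, thr = classify_session(synced, AnalysisConfig())
        assert peak.labels == truth.labels
        n_wrong = sum(thr.labels[k] != truth.labels[k] for k in truth.labels)
        assert n_wrong > 0


class TestDeriveCutoff:
    def test_tight_cohort_yields_cutoff_near_amplitude(self):
        rng = np.random.default_rng(1)
        rows = []
        for _ in range(5):
            for d, (h, v) in {
                Direction.LEFT: (-10, 0), Direction.RIGHT: (10, 0),
                Direction.UPPER: (0, 10), Direction.LOWER: (0, -10),
                Direction.UPPER_LEFT: (-7, 7), Direction.UPPER_RIGHT: (7, 7),
                Direction.LOWER_LEFT: (-7, -7), Direction.LOWER_RIGHT: (7, -7),
            }.items():
                rows.append((d, h + rng.normal(0, 0.5), v + rng.normal(0, 0.5)))
        cutoff = derive_threshold_cutoff(rows)
        assert 4.0 < cutoff < 10.0

    def test_empty_cohort_raises(self):
        with pytest.raises(Exception):
            derive_threshold_cutoff([])
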
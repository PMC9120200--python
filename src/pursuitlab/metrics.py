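"""Latency and gain estimation per eye and per excursion.

Without a trigger signal the onset of each sweep is unknown, so latency is
measured between *peak times*: each series' position vector over one excursion
is fitted with a cubic polynomial, the fitted peak time is snapped back to the
nearest raw sample, and latency is the (signed) difference between the eye's
and the target's snapped peak times.  Because both series live on the
scene-camera timeline, latencies come out quantized to its frame period
(~33.4 ms at 29.97 Hz) — the clock that actually limits the measurement.

Gain compares pursuit speed on the outgoing (centrifugal) limb: within each
series' own 25–75% amplitude window an ordinary least-squares line is fitted
to position vector versus time, and gain is the ratio of the eye's slope to
the target's.  Saccade-flagged samples are excluded from the eye regression so
catch-up saccades do not inflate pursuit gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .direction import (
    ClassificationResult,
    Direction,
    detect_peaks,
    relative_origin,
    to_position_vector,
)
from .errors import (
    DegenerateSegmentError,
    DegenerateTargetError,
    InsufficientSamplesError,
    TraceValidationError,
    WindowNotFoundError,
)
from .preprocess import SyncedRecording
from .trace_io import AnalysisConfig, TargetTrace


@dataclass
class PeakEstimate:
    """Peak time of one series over one excursion.

    ``fitted_peak_t`` is the argmax of the cubic fit; ``snapped_t`` is the raw
    sample time nearest to it and ``max_value`` the raw position vector there.
    """

    fitted_peak_t: float
    snapped_t: float
    max_value: float
    index: int  # sample index of snapped_t within the segment


@dataclass
class GainEstimate:
    gain: float
    target_window: tuple[float, float]
    eye_window: tuple[float, float]


@dataclass
class ExcursionMetrics:
    """Clinical output for one labeled excursion: per-eye latency and gain."""

    ordinal: int
    direction: Direction
    latency_left: float | None = None
    latency_right: float | None = None
    gain_left: float | None = None
    gain_right: float | None = None
    windows: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)


def fit_cubic_peak(t: np.ndarray, r: np.ndarray) -> PeakEstimate:
    """Least-squares cubic fit of r(t); peak time from its interior maximum.

    The time axis is centered before fitting for conditioning.  If the cubic
    has no interior stationary point with negative curvature inside the
    segment, the raw argmax time is used instead (monotone segments).  The
    fitted peak time is then snapped to the nearest raw sample, whose raw
    value becomes ``max_value``.
    """
    t = np.asarray(t, float)
    r = np.asarray(r, float)
    if len(t) != len(r):
        raise TraceValidationError("cubic fit: t/r length mismatch")
    if len(t) < 8:
        raise TraceValidationError(f"cubic fit needs >= 8 samples, got {len(t)}")
    if np.ptp(r) == 0.0:
        raise DegenerateSegmentError("constant segment: no peak to fit")
    t0 = t.mean()
    tc = t - t0
    coeffs = np.polyfit(tc, r, 3)
    # Stationary points: roots of the derivative with negative second derivative.
    deriv = np.polyder(coeffs)
    curv = np.polyder(deriv)
    fitted = None
    for root in np.roots(deriv):
        if abs(root.imag) > 1e-9:
            continue
        tau = root.real
        if tc[0] < tau < tc[-1] and np.polyval(curv, tau) < 0:
            fitted = tau + t0
            break
    if fitted is None:
        fitted = float(t[int(np.argmax(r))])
    idx = int(np.argmin(np.abs(t - fitted)))
    return PeakEstimate(
        fitted_peak_t=float(fitted),
        snapped_t=float(t[idx]),
        max_value=float(r[idx]),
        index=idx,
    )


def estimate_peak_time(t: np.ndarray, r: np.ndarray) -> PeakEstimate:
    """Cubic peak time fitted over the body of the sweep.

    A cubic fitted over the full min-to-min span is sensitive to where the
    bounding minima happen to fall inside the flat rest phases: an asymmetric
    window drags the fitted peak toward its longer side.  Fitting between the
    first and last quarter-amplitude crossings instead centres the window on
    the sweep itself — symmetric about the bump regardless of where the
    minima fell or how the sample grid is phased, with enough of both ramps
    included to pin the cubic's curvature — while keeping the cubic-fit peak
    rule unchanged.  The returned ``index`` refers to the full segment
    arrays.
    """
    t = np.asarray(t, float)
    r = np.asarray(r, float)
    if len(t) < 8:
        raise TraceValidationError(f"peak estimation needs >= 8 samples, got {len(t)}")
    level = r.min() + 0.25 * (r.max() - r.min())
    above = np.flatnonzero(r >= level)
    lo, hi = int(above[0]), int(above[-1]) + 1
    if hi - lo < 8:  # narrow bump: use the whole span
        lo, hi = 0, len(t)
    est = fit_cubic_peak(t[lo:hi], r[lo:hi])
    idx = int(np.argmin(np.abs(t - est.fitted_peak_t)))
    return PeakEstimate(
        fitted_peak_t=est.fitted_peak_t,
        snapped_t=float(t[idx]),
        max_value=float(r[idx]),
        index=idx,
    )


def latency(eye_peak: PeakEstimate, target_peak: PeakEstimate) -> float:
    """Signed latency in milliseconds; positive when the eye peaks after the
    target."""
    return (eye_peak.snapped_t - target_peak.snapped_t) * 1000.0


def _first_crossing(t: np.ndarray, r: np.ndarray, level: float) -> tuple[float, int]:
    """First time r reaches ``level`` (linear interpolation) and the index of
    the sample interval that brackets the crossing."""
    above = r >= level
    if not above.any():
        raise WindowNotFoundError(
            f"rising limb never reaches {level:.3f} deg (max {r.max():.3f})"
        )
    k = int(np.argmax(above))
    if k == 0:
        return float(t[0]), 0
    frac = (level - r[k - 1]) / (r[k] - r[k - 1])
    return float(t[k - 1] + frac * (t[k] - t[k - 1])), k


def percentile_window(
    t: np.ndarray,
    r: np.ndarray,
    peak: PeakEstimate,
    lo_frac: float = 0.25,
    hi_frac: float = 0.75,
) -> tuple[float, float]:
    """Times at which the rising limb first crosses lo/hi fractions of the peak.

    The limb runs from the segment start to the snapped peak sample.  A step
    that crosses both levels inside one sample interval yields a degenerate
    (empty) window, which is rejected.
    """
    if not (0.0 < lo_frac < hi_frac < 1.0):
        raise ValueError("require 0 < lo_frac < hi_frac < 1")
    if peak.max_value <= 0:
        raise WindowNotFoundError("peak amplitude is not positive")
    limb_t = np.asarray(t, float)[: peak.index + 1]
    limb_r = np.asarray(r, float)[: peak.index + 1]
    t_lo, k_lo = _first_crossing(limb_t, limb_r, lo_frac * peak.max_value)
    t_hi, k_hi = _first_crossing(limb_t, limb_r, hi_frac * peak.max_value)
    if not t_lo < t_hi or k_lo == k_hi:
        # both crossings inside one sample interval: the limb is a step and
        # holds no samples to regress on
        raise WindowNotFoundError("degenerate amplitude window (step-like limb)")
    return t_lo, t_hi


def _ols_slope(t: np.ndarray, r: np.ndarray) -> float:
    return float(np.polyfit(t, r, 1)[0])


def gain_from_segments(
    eye_t: np.ndarray,
    eye_r: np.ndarray,
    target_t: np.ndarray,
    target_r: np.ndarray,
    eye_peak: PeakEstimate,
    target_peak: PeakEstimate,
    lo_frac: float = 0.25,
    hi_frac: float = 0.75,
    eye_exclude: np.ndarray | None = None,
) -> GainEstimate:
    """Slope-ratio gain with independent eye/target segments.

    Each series gets its own 25–75% amplitude window on its own outgoing
    limb; ``eye_exclude`` marks samples (saccades) left out of the eye
    regression.  At least 3 samples must remain in each window.
    """
    eye_t = np.asarray(eye_t, float)
    target_t = np.asarray(target_t, float)
    tw = percentile_window(target_t, target_r, target_peak, lo_frac, hi_frac)
    ew = percentile_window(eye_t, eye_r, eye_peak, lo_frac, hi_frac)
    t_mask = (target_t >= tw[0]) & (target_t <= tw[1])
    e_mask = (eye_t >= ew[0]) & (eye_t <= ew[1])
    if eye_exclude is not None:
        e_mask &= ~np.asarray(eye_exclude, bool)
    if t_mask.sum() < 3:
        raise InsufficientSamplesError(
            f"target window holds {int(t_mask.sum())} samples, need >= 3"
        )
    if e_mask.sum() < 3:
        raise InsufficientSamplesError(
            f"eye window holds {int(e_mask.sum())} usable samples, need >= 3"
        )
    slope_target = _ols_slope(target_t[t_mask], target_r[t_mask])
    if abs(slope_target) < 1e-9:
        raise DegenerateTargetError("target slope is numerically zero")
    slope_eye = _ols_slope(eye_t[e_mask], eye_r[e_mask])
    return GainEstimate(gain=slope_eye / slope_target, target_window=tw, eye_window=ew)


def gain(
    t: np.ndarray,
    eye_r: np.ndarray,
    target_r: np.ndarray,
    eye_peak: PeakEstimate,
    target_peak: PeakEstimate,
    lo_frac: float = 0.25,
    hi_frac: float = 0.75,
    eye_exclude: np.ndarray | None = None,
) -> GainEstimate:
    """Slope-ratio gain for eye and target sharing one timeline ``t``."""
    return gain_from_segments(
        t, eye_r, t, target_r, eye_peak, target_peak, lo_frac, hi_frac, eye_exclude
    )


def _own_spans(
    t: np.ndarray,
    r: np.ndarray,
    separation: float,
    ref_max_t: list[float],
    min_peak_height: float = 2.0,
) -> list[tuple[float, float] | None]:
    """Min-to-min span of each excursion of *this* series.

    The series is peak-detected on its own position vector (a delayed eye
    peaks later than the target, so its bounding minima shift with it) and
    each (min, max, min) triple is matched to the reference excursion whose
    maximum-peak time is nearest.  Unmatched references yield ``None``.
    """
    from .direction import PositionVectorTrace

    extrema = detect_peaks(PositionVectorTrace(t=t, r=r), separation, min_peak_height)
    triples = [
        (extrema[i].t, extrema[i + 1].t, extrema[i + 2].t)
        for i in range(len(extrema) - 2)
        if (extrema[i].kind, extrema[i + 1].kind, extrema[i + 2].kind)
        == ("min", "max", "min")
    ]
    spans: list[tuple[float, float] | None] = []
    for ref in ref_max_t:
        if not triples:
            spans.append(None)
            continue
        best = min(triples, key=lambda tr: abs(tr[1] - ref))
        spans.append((best[0], best[2]) if abs(best[1] - ref) < separation else None)
    return spans


def analyze_session(
    synced: SyncedRecording,
    classification: ClassificationResult,
    cfg: AnalysisConfig | None = None,
) -> list[ExcursionMetrics]:
    """Per-eye latency and gain for every labeled excursion of a session.

    Both eyes and the target are origin-corrected with the same relative
    origin (the target-track median) and converted to position vectors.  Each
    series is then segmented on its *own* peaks: a pursuing eye lags the
    target, so fitting its cubic inside the target's window would skew the
    fitted peak time, whereas each series' own min-to-min span keeps the peak
    estimate centred.  Failures are recorded per excursion and per eye, never
    fatal for the session.
    """
    cfg = cfg or AnalysisConfig()
    origin = relative_origin(
        TargetTrace(t=synced.t, x=synced.target_x, y=synced.target_y)
    )
    r_target = to_position_vector(synced.t, synced.target_x, synced.target_y, origin).r
    r_eye = {
        "left": to_position_vector(synced.t, synced.left_x, synced.left_y, origin).r,
        "right": to_position_vector(synced.t, synced.right_x, synced.right_y, origin).r,
    }
    saccade = {"left": synced.left_flags.saccade, "right": synced.right_flags.saccade}
    ref_max_t = [exc.max_t for exc in classification.excursions]
    spans = {
        side: _own_spans(
            synced.t, r_eye[side], cfg.peak_separation, ref_max_t, cfg.min_peak_height
        )
        for side in ("left", "right")
    }
    results: list[ExcursionMetrics] = []
    for k, exc in enumerate(classification.excursions):
        label = classification.labels.get(exc.ordinal)
        row = ExcursionMetrics(ordinal=exc.ordinal, direction=label)
        mask = (synced.t >= exc.start_t) & (synced.t <= exc.end_t)
        seg_t = synced.t[mask]
        try:
            target_peak = estimate_peak_time(seg_t, r_target[mask])
        except Exception as err:  # degenerate target segment: nothing to measure
            row.errors["target"] = str(err)
            results.append(row)
            continue
        row.windows["target_peak_t"] = target_peak.snapped_t
        for side in ("left", "right"):
            span = spans[side][k]
            if span is None:
                row.errors[side] = "no matching excursion in this eye's position vector"
                continue
            e_mask = (synced.t >= span[0]) & (synced.t <= span[1])
            e_t = synced.t[e_mask]
            try:
                eye_peak = estimate_peak_time(e_t, r_eye[side][e_mask])
                lat = latency(eye_peak, target_peak)
                g = gain_from_segments(
                    e_t,
                    r_eye[side][e_mask],
                    seg_t,
                    r_target[mask],
                    eye_peak,
                    target_peak,
                    cfg.gain_lo_frac,
                    cfg.gain_hi_frac,
                    eye_exclude=saccade[side][e_mask],
                )
            except Exception as err:
                row.errors[side] = str(err)
                continue
            setattr(row, f"latency_{side}", lat)
            setattr(row, f"gain_{side}", g.gain)
            row.windows[f"{side}_window"] = g.eye_window
            row.windows["target_window"] = g.target_window
        results.append(row)
    return results
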
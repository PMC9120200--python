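"""Blink rejection, gap interpolation, I-VT saccade flagging, synchronization.

The cleaning order mirrors how the signals are corrupted: blinks collapse the
pupil and drop the gaze estimate, so blink-corrupted and missing samples are
found first and replaced by linear interpolation in time; only then is a
velocity-threshold (I-VT) pass meaningful, because artificial gaps would
otherwise masquerade as high-velocity saccades.  Finally both eyes are
re-expressed on the target's (scene-camera) timeline, which is the clock on
which latencies are ultimately quantized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import TraceValidationError, UnrecoverableTraceError
from .trace_io import AnalysisConfig, EyeTrace, Recording, TargetTrace


@dataclass
class SampleFlags:
    """Per-sample boolean annotations for one eye trace."""

    blink: np.ndarray
    interpolated: np.ndarray
    saccade: np.ndarray

    @classmethod
    def empty(cls, n: int) -> "SampleFlags":
        return cls(np.zeros(n, bool), np.zeros(n, bool), np.zeros(n, bool))

    def __len__(self) -> int:
        return len(self.blink)

    def copy(self) -> "SampleFlags":
        return SampleFlags(self.blink.copy(), self.interpolated.copy(), self.saccade.copy())

    def merge(self, other: "SampleFlags") -> "SampleFlags":
        return SampleFlags(
            self.blink | other.blink,
            self.interpolated | other.interpolated,
            self.saccade | other.saccade,
        )


def flag_blinks(trace: EyeTrace, delta: float = 2.0) -> SampleFlags:
    """Flag samples whose pupil diameter jumps more than ``delta`` mm per frame.

    Sample ``i`` is flagged when ``|pupil[i] - pupil[i-1]| > delta``; the first
    sample has no predecessor and is never flagged by the rule.  A real blink
    produces both a collapse and a recovery transition, so its entry and exit
    samples are both caught.
    """
    flags = SampleFlags.empty(len(trace))
    if len(trace) < 2:
        return flags
    with np.errstate(invalid="ignore"):
        jump = np.abs(np.diff(trace.pupil)) > delta  # NaN diffs compare False
    flags.blink[1:] = jump
    return flags


def interpolate_gaps(trace: EyeTrace, flags: SampleFlags) -> EyeTrace:
    """Replace blink-flagged and missing samples by linear interpolation in time.

    Interior gaps are interpolated against the nearest valid neighbours;
    leading/trailing gaps are filled by constant extension of the nearest valid
    sample.  Valid, unflagged samples are returned bit-for-bit unchanged.  The
    caller's ``flags.interpolated`` array is updated in place to mark replaced
    samples.
    """
    if len(trace) == 0:
        raise UnrecoverableTraceError("empty trace")
    bad = (
        flags.blink
        | ~trace.valid
        | ~np.isfinite(trace.x)
        | ~np.isfinite(trace.y)
        | ~np.isfinite(trace.pupil)
    )
    if bad.all():
        raise UnrecoverableTraceError(f"eye trace ({trace.side}): every sample is invalid")
    out = trace.copy()
    if bad.any():
        good = ~bad
        for name in ("x", "y", "pupil"):
            arr = getattr(out, name)
            arr[bad] = np.interp(trace.t[bad], trace.t[good], arr[good])
    out.valid = np.ones(len(trace), dtype=bool)
    flags.interpolated[:] = bad
    return out


def _sample_speeds(trace: EyeTrace) -> np.ndarray:
    """Per-sample 2-D gaze speed (deg/s) from first differences.

    Sample ``i`` carries the speed of the step arriving at it; the first sample
    copies the first step so the array stays congruent with the trace.
    """
    dt = np.diff(trace.t)
    step = np.hypot(np.diff(trace.x), np.diff(trace.y)) / dt
    speeds = np.empty(len(trace))
    speeds[1:] = step
    speeds[0] = step[0] if len(step) else 0.0
    return speeds


def _window_speeds(speeds: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean speed over non-overlapping blocks of ``window`` samples.

    Returns (block means, per-sample block index).  Leftover tail samples are
    absorbed into the final block.  Kept as a separate function because the
    window arithmetic is the one point where alternative I-VT readings
    (sliding vs. tiled windows) would plug in.
    """
    n = len(speeds)
    n_blocks = max(n // window, 1)
    block_of = np.minimum(np.arange(n) // window, n_blocks - 1)
    means = np.array([speeds[block_of == j].mean() for j in range(n_blocks)])
    return means, block_of


def _median_over_block_triples(means: np.ndarray) -> np.ndarray:
    """Median of each block's speed with its two neighbours (clamped at edges)."""
    j = np.arange(len(means))
    lo = np.clip(j - 1, 0, len(means) - 1)
    hi = np.clip(j + 1, 0, len(means) - 1)
    return np.median(np.stack([means[lo], means[j], means[hi]]), axis=0)


def classify_ivt(trace: EyeTrace, threshold: float = 100.0, window: int = 3) -> SampleFlags:
    """Velocity-threshold (I-VT) saccade flagging.

    Speeds are averaged over tiled blocks of ``window`` samples; a sample is a
    saccade when the median of the three consecutive block speeds covering its
    block exceeds ``threshold`` deg/s.  Gaps must already be interpolated.
    """
    n = len(trace)
    if n < 3 * window:
        raise TraceValidationError(
            f"I-VT needs at least {3 * window} samples, trace has {n}"
        )
    speeds = _sample_speeds(trace)
    means, block_of = _window_speeds(speeds, window)
    med = _median_over_block_triples(means)
    flags = SampleFlags.empty(n)
    flags.saccade = med[block_of] > threshold
    return flags


@dataclass
class SyncedRecording:
    """Both eyes re-expressed on the target timeline.

    All series share the target's timestamps; per-eye flags are carried over to
    the nearest synced sample.
    """

    t: np.ndarray
    target_x: np.ndarray
    target_y: np.ndarray
    left_x: np.ndarray
    left_y: np.ndarray
    right_x: np.ndarray
    right_y: np.ndarray
    left_flags: SampleFlags
    right_flags: SampleFlags
    viewing_distance: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("target_x", "target_y", "left_x", "left_y", "right_x", "right_y"):
            if len(getattr(self, name)) != n:
                raise TraceValidationError(f"synced recording: '{name}' length mismatch")
        if len(self.left_flags) != n or len(self.right_flags) != n:
            raise TraceValidationError("synced recording: flag length mismatch")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "target_x": self.target_x,
                "target_y": self.target_y,
                "left_x": self.left_x,
                "left_y": self.left_y,
                "right_x": self.right_x,
                "right_y": self.right_y,
                "left_saccade": self.left_flags.saccade.astype(int),
                "right_saccade": self.right_flags.saccade.astype(int),
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def read_csv(cls, path) -> "SyncedRecording":
        df = pd.read_csv(path)
        n = len(df)
        lf, rf = SampleFlags.empty(n), SampleFlags.empty(n)
        lf.saccade = df["left_saccade"].to_numpy(bool)
        rf.saccade = df["right_saccade"].to_numpy(bool)
        return cls(
            t=df["t"].to_numpy(float),
            target_x=df["target_x"].to_numpy(float),
            target_y=df["target_y"].to_numpy(float),
            left_x=df["left_x"].to_numpy(float),
            left_y=df["left_y"].to_numpy(float),
            right_x=df["right_x"].to_numpy(float),
            right_y=df["right_y"].to_numpy(float),
            left_flags=lf,
            right_flags=rf,
        )


def interpolate_target_gaps(target: TargetTrace) -> TargetTrace:
    """Fill frames where the detector missed the target by linear interpolation.

    Mirrors the eye-gap rule: interior misses are interpolated from the nearest
    detected frames, edge misses constant-extended.
    """
    bad = ~target.present | ~np.isfinite(target.x) | ~np.isfinite(target.y)
    if bad.all():
        raise UnrecoverableTraceError("target trace: target never detected")
    out = target.copy()
    if bad.any():
        good = ~bad
        out.x[bad] = np.interp(target.t[bad], target.t[good], target.x[good])
        out.y[bad] = np.interp(target.t[bad], target.t[good], target.y[good])
    out.present = np.ones(len(target), dtype=bool)
    return out


def _project_flags(eye_t: np.ndarray, flags: SampleFlags, sync_t: np.ndarray) -> SampleFlags:
    """Carry each flagged eye sample onto its nearest synced timestamp."""
    out = SampleFlags.empty(len(sync_t))
    for src, dst in (
        (flags.blink, out.blink),
        (flags.interpolated, out.interpolated),
        (flags.saccade, out.saccade),
    ):
        if not src.any():
            continue
        ts = eye_t[src]
        pos = np.searchsorted(sync_t, ts)
        pos = np.clip(pos, 1, len(sync_t) - 1)
        nearest = np.where(ts - sync_t[pos - 1] <= sync_t[pos] - ts, pos - 1, pos)
        dst[nearest] = True
    return out


def synchronize(
    rec: Recording,
    left_flags: SampleFlags | None = None,
    right_flags: SampleFlags | None = None,
) -> SyncedRecording:
    """Interpolate both eyes onto the target timestamps inside the common span.

    The target series is preserved exactly (after gap filling); target frames
    outside either eye's coverage are dropped.  Eye flags are propagated to the
    nearest synced sample.
    """
    lo, hi = rec.overlap()
    target = interpolate_target_gaps(rec.target)
    keep = (target.t >= lo) & (target.t <= hi)
    if not keep.any():
        raise TraceValidationError("no target timestamps fall inside the eye coverage")
    t = target.t[keep]
    left_flags = left_flags if left_flags is not None else SampleFlags.empty(len(rec.left))
    right_flags = right_flags if right_flags is not None else SampleFlags.empty(len(rec.right))
    return SyncedRecording(
        t=t,
        target_x=target.x[keep],
        target_y=target.y[keep],
        left_x=np.interp(t, rec.left.t, rec.left.x),
        left_y=np.interp(t, rec.left.t, rec.left.y),
        right_x=np.interp(t, rec.right.t, rec.right.x),
        right_y=np.interp(t, rec.right.t, rec.right.y),
        left_flags=_project_flags(rec.left.t, left_flags, t),
        right_flags=_project_flags(rec.right.t, right_flags, t),
        viewing_distance=rec.viewing_distance,
        meta=dict(rec.meta),
    )


def preprocess_recording(rec: Recording, cfg: AnalysisConfig | None = None) -> SyncedRecording:
    """Run the full cleaning chain on one recording.

    Blink flagging -> gap interpolation -> I-VT saccade flagging per eye, then
    synchronization of both eyes onto the target timeline.
    """
    cfg = cfg or AnalysisConfig()
    eyes = {}
    flags = {}
    for side in ("left", "right"):
        eye: EyeTrace = getattr(rec, side)
        f = flag_blinks(eye, cfg.blink_delta_mm)
        clean = interpolate_gaps(eye, f)
        f = f.merge(classify_ivt(clean, cfg.ivt_threshold, cfg.ivt_window))
        eyes[side], flags[side] = clean, f
    clean_rec = Recording(
        left=eyes["left"], right=eyes["right"], target=rec.target,
        viewing_distance=rec.viewing_distance, meta=rec.meta,
    )
    return synchronize(clean_rec, flags["left"], flags["right"])
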
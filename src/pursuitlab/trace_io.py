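"""Domain containers, the on-disk trace dialect, configuration and geometry helpers.

Video-oculography recordings arrive as two comma-separated streams per session:

* an *eye* trace per eye — header ``t,x,y,pupil`` — gaze position in degrees of
  visual angle (right/up positive) plus pupil diameter in millimetres, sampled
  at a nominal 240 Hz;
* a *target* trace — header ``t,x,y,present`` — the location of the hand-moved
  fixation target as reported by an upstream object detector on the scene
  camera, sampled at a nominal 29.97 Hz.

Timestamps are stored explicitly per sample and are the authority for every
downstream computation; the nominal rates are metadata only, because latencies
are quantized by the real frame clock, not by an assumed one.  Rows whose
position fields cannot be parsed become *missing* samples (``valid``/``present``
false) rather than being dropped, so sample indices always match the file.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal, NamedTuple

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .errors import TraceFormatError, TraceValidationError

EYE_COLUMNS = ("t", "x", "y", "pupil")
TARGET_COLUMNS = ("t", "x", "y", "present")

_TRUE_TOKENS = {"1", "1.0", "true", "t", "yes"}
_FALSE_TOKENS = {"0", "0.0", "false", "f", "no", ""}


class EyeSample(NamedTuple):
    """One eye-camera frame: time (s), gaze (deg), pupil diameter (mm)."""

    t: float
    x: float
    y: float
    pupil: float
    valid: bool


class TargetSample(NamedTuple):
    """One scene-camera frame: time (s), target location (deg), detector hit."""

    t: float
    x: float
    y: float
    present: bool


def _check_time_axis(t: np.ndarray, what: str) -> None:
    if t.size == 0:
        return
    if not np.all(np.isfinite(t)) or t[0] < 0:
        bad = int(np.flatnonzero(~np.isfinite(t))[0]) if not np.all(np.isfinite(t)) else 0
        raise TraceValidationError(f"{what}: non-finite or negative timestamp at row {bad}")
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.flatnonzero(dt <= 0)[0]) + 1
        raise TraceValidationError(
            f"{what}: timestamps must be strictly increasing; row {bad} "
            f"(t={t[bad]:.6f}) does not advance past row {bad - 1} (t={t[bad - 1]:.6f})"
        )


@dataclass
class EyeTrace:
    """Time-ordered gaze samples for one eye.

    Arrays are congruent; ``valid`` is false for samples whose position could
    not be measured (blink dropout, unparseable row).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pupil: np.ndarray
    valid: np.ndarray | None = None
    side: Literal["left", "right"] = "left"
    nominal_rate: float = 240.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.x) & np.isfinite(self.y) & np.isfinite(self.pupil)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        for name in ("x", "y", "pupil", "valid"):
            if len(getattr(self, name)) != n:
                raise TraceValidationError(f"eye trace ({self.side}): '{name}' length mismatch")
        if self.nominal_rate <= 0:
            raise TraceValidationError("nominal_rate must be positive")
        _check_time_axis(self.t, f"eye trace ({self.side})")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    @property
    def samples(self) -> Iterator[EyeSample]:
        for i in range(len(self)):
            yield EyeSample(
                float(self.t[i]), float(self.x[i]), float(self.y[i]),
                float(self.pupil[i]), bool(self.valid[i]),
            )

    def copy(self) -> "EyeTrace":
        return replace(
            self, t=self.t.copy(), x=self.x.copy(), y=self.y.copy(),
            pupil=self.pupil.copy(), valid=self.valid.copy(),
        )


@dataclass
class TargetTrace:
    """Time-ordered target locations from the scene-camera detector."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    present: np.ndarray | None = None
    nominal_rate: float = 29.97

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.present is None:
            self.present = np.isfinite(self.x) & np.isfinite(self.y)
        self.present = np.asarray(self.present, dtype=bool)
        n = len(self.t)
        for name in ("x", "y", "present"):
            if len(getattr(self, name)) != n:
                raise TraceValidationError(f"target trace: '{name}' length mismatch")
        if self.nominal_rate <= 0:
            raise TraceValidationError("nominal_rate must be positive")
        _check_time_axis(self.t, "target trace")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    @property
    def presence_fraction(self) -> float:
        """Fraction of frames on which the detector found the target.

        A healthy recording sits above 0.99; a much lower value usually means
        the detector lost the target and the track should be re-recorded.
        """
        return float(self.present.mean()) if len(self) else 0.0

    @property
    def samples(self) -> Iterator[TargetSample]:
        for i in range(len(self)):
            yield TargetSample(
                float(self.t[i]), float(self.x[i]), float(self.y[i]), bool(self.present[i])
            )

    def copy(self) -> "TargetTrace":
        return replace(
            self, t=self.t.copy(), x=self.x.copy(), y=self.y.copy(), present=self.present.copy()
        )


@dataclass
class Recording:
    """One session: both eyes plus the target track, with session metadata."""

    left: EyeTrace
    right: EyeTrace
    target: TargetTrace
    viewing_distance: float = 1.0
    meta: dict = field(default_factory=dict)

    def overlap(self) -> tuple[float, float]:
        """Common time span of the three traces; raises if they do not meet."""
        if not (len(self.left) and len(self.right) and len(self.target)):
            raise TraceValidationError("recording has an empty trace")
        lo = max(self.left.t[0], self.right.t[0], self.target.t[0])
        hi = min(self.left.t[-1], self.right.t[-1], self.target.t[-1])
        if hi <= lo:
            raise TraceValidationError("eye and target traces do not overlap in time")
        return float(lo), float(hi)


class AnalysisConfig(BaseModel):
    """Every numeric constant of the analysis, with its clinical default.

    Attributes
    ----------
    blink_delta_mm : pupil-diameter jump (mm per eye-camera frame) above which
        a sample is treated as blink-corrupted.
    ivt_threshold : gaze speed (deg/s) above which a sample is a saccade under
        the velocity-threshold (I-VT) rule.
    ivt_window : samples per I-VT averaging window.
    peak_separation : minimum spacing (s) between retained same-type peaks of
        the position-vector trace.
    min_peak_height : degrees the position vector must reach for a maximum to
        count as a sweep rather than central hand tremor.
    end_trim : seconds removed from both ends of each excursion before the
        location medians are taken.
    threshold_cutoff : half-width (deg) of the central box of the baseline
        threshold classifier.
    gain_lo_frac / gain_hi_frac : amplitude fractions of the peak bounding the
        slope-regression window on the outgoing limb.
    expected_excursions : excursions a complete protocol must yield.
    """

    blink_delta_mm: float = Field(default=2.0, gt=0)
    ivt_threshold: float = Field(default=100.0, gt=0)
    ivt_window: int = Field(default=3, ge=1)
    peak_separation: float = Field(default=3.0, gt=0)
    min_peak_height: float = Field(default=2.0, ge=0)
    end_trim: float = Field(default=1.0, ge=0)
    threshold_cutoff: float = Field(default=2.0, gt=0)
    gain_lo_frac: float = 0.25
    gain_hi_frac: float = 0.75
    expected_excursions: int = Field(default=8, ge=1)
    rng_seed: int = 0

    @model_validator(mode="after")
    def _check_fracs(self) -> "AnalysisConfig":
        if not (0.0 < self.gain_lo_frac < self.gain_hi_frac < 1.0):
            raise ValueError("require 0 < gain_lo_frac < gain_hi_frac < 1")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load from YAML (or JSON, a YAML subset)."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# CSV dialect


def _parse_numeric(series: pd.Series) -> np.ndarray:
    return pd.to_numeric(series, errors="coerce").to_numpy(dtype=float)


def _parse_bool(series: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Token -> bool; second array marks unparseable tokens."""
    tokens = series.astype(str).str.strip().str.lower()
    true = tokens.isin(_TRUE_TOKENS).to_numpy()
    known = (tokens.isin(_TRUE_TOKENS) | tokens.isin(_FALSE_TOKENS)).to_numpy()
    return true, ~known


def read_trace_csv(path: str | Path, kind: Literal["eye", "target"],
                   side: Literal["left", "right"] = "left") -> EyeTrace | TargetTrace:
    """Read one trace file in the package dialect.

    Unparseable position/pupil fields yield missing samples (``valid`` or
    ``present`` false) at their original index; an unparseable or non-monotone
    timestamp is unrecoverable and raises, naming the offending row.
    """
    path = Path(path)
    expected = EYE_COLUMNS if kind == "eye" else TARGET_COLUMNS
    try:
        df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True,
                         skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise TraceFormatError(f"{path}: empty file, expected header {','.join(expected)}")
    if tuple(df.columns) != expected:
        raise TraceFormatError(
            f"{path}: header is {','.join(df.columns)!r}, expected {','.join(expected)!r}"
        )
    t = _parse_numeric(df["t"])
    if np.any(~np.isfinite(t)):
        bad = int(np.flatnonzero(~np.isfinite(t))[0])
        raise TraceValidationError(f"{path}: unparseable timestamp at data row {bad}")
    x = _parse_numeric(df["x"])
    y = _parse_numeric(df["y"])
    if kind == "eye":
        pupil = _parse_numeric(df["pupil"])
        valid = np.isfinite(x) & np.isfinite(y) & np.isfinite(pupil) & (pupil > 0)
        return EyeTrace(t=t, x=x, y=y, pupil=pupil, valid=valid, side=side)
    present, unknown = _parse_bool(df["present"])
    present = present & np.isfinite(x) & np.isfinite(y) & ~unknown
    return TargetTrace(t=t, x=x, y=y, present=present)


def _fmt(v: float) -> str:
    return "" if not math.isfinite(v) else f"{v:.6f}"


def write_trace_csv(trace: EyeTrace | TargetTrace, path: str | Path) -> None:
    """Write a trace in the package dialect (6 decimals; missing fields empty)."""
    buf = io.StringIO()
    if isinstance(trace, EyeTrace):
        buf.write(",".join(EYE_COLUMNS) + "\n")
        for s in trace.samples:
            if s.valid:
                buf.write(f"{s.t:.6f},{_fmt(s.x)},{_fmt(s.y)},{_fmt(s.pupil)}\n")
            else:
                buf.write(f"{s.t:.6f},,,\n")
    else:
        buf.write(",".join(TARGET_COLUMNS) + "\n")
        for s in trace.samples:
            buf.write(f"{s.t:.6f},{_fmt(s.x)},{_fmt(s.y)},{1 if s.present else 0}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def visual_angle(extent: float, distance: float) -> float:
    """Visual angle (degrees) subtended by ``extent`` metres at ``distance`` metres.

    A 10 cm plate at 1.0 m subtends 2*atan(0.05) = 5.7 degrees.
    """
    if extent <= 0 or distance <= 0:
        raise ValueError("extent and distance must be positive")
    return math.degrees(2.0 * math.atan2(extent, 2.0 * distance))
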
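"""Ground-truthed synthetic nine-direction sessions.

The generator emulates what the recording rig delivers: a hand-moved target
plate swept from a central rest position out to each of the eight peripheral
directions and back (constant-speed ramps with hand jitter, sampled on the
29.97 Hz scene-camera clock, offset by the unknown plate-vs-camera
misalignment), and two eyes that follow it with a subject-specific latency
and gain, additive tracking noise, occasional catch-up-saccade intrusions and
binocular blinks with pupil collapse (sampled on the 240 Hz eye-camera
clock).  Every generated session carries its ground truth, so each pipeline
stage can be scored against known answers.

Latency is applied as a continuous-time delay before the eye is sampled, so
frame quantization of the estimates arises from the clocks, as in a real
recording, rather than being injected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import signal

from .direction import DIRECTION_VECTORS, Direction
from .trace_io import EyeTrace, Recording, TargetTrace

_EIGHT = list(DIRECTION_VECTORS)


def _as_range(v) -> tuple[float, float]:
    if isinstance(v, (int, float)):
        return float(v), float(v)
    lo, hi = float(v[0]), float(v[1])
    if hi < lo:
        raise ValueError(f"range {v} has hi < lo")
    return lo, hi


class SimulationConfig(BaseModel):
    """Generative parameters of one synthetic cohort.

    Scalar-or-range fields (``amplitude``, ``latency_ms``, ``gain``) are drawn
    uniformly per subject/excursion when given as a (lo, hi) pair.  Defaults
    describe a healthy cohort under the clinical protocol: radial excursions
    of 10–15 deg (within the ±15 deg test field), ~10 deg/s hand ramps,
    pursuit latencies of 50–300 ms, gains of 0.85–1.0, 0.5 deg tracking noise
    (the recorder's stated error band), and a plate-vs-camera offset of up to
    5 deg per axis.
    """

    n_subjects: int = Field(default=23, ge=1)
    directions: str | list[str] = "random8"
    amplitude: float | tuple[float, float] = (10.0, 15.0)
    ramp_speed: float = Field(default=10.0, gt=0)
    dwell: float = Field(default=2.0, gt=0)
    center_dwell: float = Field(default=2.0, gt=0)
    lead_in: float = Field(default=3.0, gt=0)
    plate_offset: float | tuple[float, float] = 5.0
    latency_ms: float | tuple[float, float] = (50.0, 300.0)
    gain: float | tuple[float, float] = (0.85, 1.0)
    noise_sd: float = Field(default=0.5, ge=0)
    noise_drift_hz: float = Field(default=2.0, gt=0)
    noise_white_sd: float = Field(default=0.1, ge=0)
    jitter_sd: float = Field(default=0.3, ge=0)
    jitter_cutoff_hz: float = Field(default=2.0, gt=0)
    blink_rate: float = Field(default=3.0, ge=0)  # events/min, binocular
    blink_duration: float = Field(default=0.2, gt=0)
    saccade_rate: float = Field(default=6.0, ge=0)  # events/min per eye
    saccade_amplitude: float = Field(default=3.0, gt=0)
    saccade_duration: float = Field(default=0.025, gt=0)  # 300 deg/s limbs
    target_dropout: float = Field(default=0.003, ge=0, lt=1)
    pupil_mm: float = Field(default=4.0, gt=0)
    eye_rate: float = Field(default=240.0, gt=0)
    target_rate: float = Field(default=29.97, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if _as_range(self.amplitude)[1] > 15.0:
            raise ValueError("amplitude must stay within the ±15 deg test field")
        if max(self.dwell, self.center_dwell) >= 3.0 + 1e-9:
            # Peak pruning keeps one extremum per dwell only while dwells are
            # shorter than the 3.0 s separation rule.
            raise ValueError("dwell times must be shorter than the 3 s peak separation")
        if isinstance(self.directions, list):
            bad = [d for d in self.directions if d not in {x.value for x in Direction}]
            if bad:
                raise ValueError(f"unknown directions {bad}")
        elif self.directions != "random8":
            raise ValueError("directions must be 'random8' or an explicit list")
        return self


@dataclass
class ExcursionTruth:
    ordinal: int
    direction: Direction
    onset_t: float  # ramp-out start, seconds
    amplitude: float


@dataclass
class GroundTruth:
    """Truth labels for one simulated session."""

    excursions: list[ExcursionTruth]
    plate_offset: tuple[float, float]
    latency_ms: float | None = None
    gain: float | None = None
    blink_times: list[float] = field(default_factory=list)
    saccade_times: dict[str, list[float]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def labels(self) -> dict[int, Direction]:
        return {e.ordinal: e.direction for e in self.excursions}


def _draw(rng: np.random.Generator, rng_or_val) -> float:
    lo, hi = _as_range(rng_or_val)
    return lo if lo == hi else float(rng.uniform(lo, hi))


def _smooth_jitter(rng: np.random.Generator, n: int, rate: float,
                   sd: float, cutoff_hz: float) -> np.ndarray:
    """Low-pass-filtered Gaussian noise, rescaled to the requested SD.

    Generated with padding on both sides and cropped, so filter edge
    transients never leak into the trace.
    """
    if sd == 0 or n < 20:
        return np.zeros(n)
    pad = int(4 * rate / cutoff_hz)
    white = rng.standard_normal(n + 2 * pad)
    sos = signal.butter(2, cutoff_hz / (rate / 2.0), output="sos")
    smooth = signal.sosfiltfilt(sos, white)[pad:pad + n]
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else np.zeros(n)


def _session_knots(
    dirs: Sequence[Direction], amps: Sequence[float], cfg: SimulationConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float]]:
    """Piecewise-linear ideal path: (knot times, x, y, per-excursion onsets)."""
    t, xs, ys = [0.0], [0.0], [0.0]
    onsets: list[float] = []

    def hold(dur: float) -> None:
        t.append(t[-1] + dur)
        xs.append(xs[-1])
        ys.append(ys[-1])

    def ramp_to(x: float, y: float, dur: float) -> None:
        t.append(t[-1] + dur)
        xs.append(x)
        ys.append(y)

    hold(cfg.lead_in)
    for d, amp in zip(dirs, amps):
        ux, uy = DIRECTION_VECTORS[d]
        dur = amp / cfg.ramp_speed
        onsets.append(t[-1])
        ramp_to(amp * ux, amp * uy, dur)
        hold(cfg.dwell)
        ramp_to(0.0, 0.0, dur)
        hold(cfg.center_dwell)
    return np.array(t), np.array(xs), np.array(ys), onsets


def simulate_target(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[TargetTrace, GroundTruth]:
    """One hand-moved target track sampled on the scene-camera clock."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if cfg.directions == "random8":
        dirs = [_EIGHT[i] for i in rng.permutation(len(_EIGHT))]
    else:
        dirs = [Direction(d) for d in cfg.directions]
    amps = [_draw(rng, cfg.amplitude) for _ in dirs]
    if isinstance(cfg.plate_offset, (int, float)):
        m = float(cfg.plate_offset)
        offset = (float(rng.uniform(-m, m)), float(rng.uniform(-m, m)))
    else:
        offset = (float(cfg.plate_offset[0]), float(cfg.plate_offset[1]))
    kt, kx, ky, onsets = _session_knots(dirs, amps, cfg)
    t = np.arange(0.0, kt[-1], 1.0 / cfg.target_rate)
    x = np.interp(t, kt, kx) + offset[0]
    y = np.interp(t, kt, ky) + offset[1]
    x += _smooth_jitter(rng, len(t), cfg.target_rate, cfg.jitter_sd, cfg.jitter_cutoff_hz)
    y += _smooth_jitter(rng, len(t), cfg.target_rate, cfg.jitter_sd, cfg.jitter_cutoff_hz)
    present = np.ones(len(t), dtype=bool)
    if cfg.target_dropout > 0:
        present &= rng.random(len(t)) >= cfg.target_dropout
        present[[0, -1]] = True  # keep anchors for interpolation
        x = np.where(present, x, np.nan)
        y = np.where(present, y, np.nan)
    truth = GroundTruth(
        excursions=[
            ExcursionTruth(ordinal=i, direction=d, onset_t=o, amplitude=a)
            for i, (d, o, a) in enumerate(zip(dirs, onsets, amps))
        ],
        plate_offset=offset,
    )
    return TargetTrace(t=t, x=x, y=y, present=present, nominal_rate=cfg.target_rate), truth


def _inject_saccades(
    rng: np.random.Generator, t: np.ndarray, x: np.ndarray, y: np.ndarray,
    cfg: SimulationConfig,
) -> list[float]:
    """Brief triangular intrusions: out and back within ``saccade_duration``,
    fast enough (amplitude / (duration/2) deg/s) to trip the I-VT rule."""
    duration = t[-1] - t[0]
    n = rng.poisson(cfg.saccade_rate * duration / 60.0)
    times = []
    for _ in range(n):
        tc = rng.uniform(t[0] + 1.0, t[-1] - 1.0)
        half = cfg.saccade_duration / 2.0
        bump = np.clip(1.0 - np.abs(t - tc) / half, 0.0, None) * cfg.saccade_amplitude
        theta = rng.uniform(0, 2 * np.pi)
        x += bump * np.cos(theta)
        y += bump * np.sin(theta)
        times.append(float(tc))
    return times


def _inject_blinks(
    rng: np.random.Generator, t: np.ndarray, x: np.ndarray, y: np.ndarray,
    pupil: np.ndarray, valid: np.ndarray, cfg: SimulationConfig,
) -> None:
    """Pupil collapse (well above the 2 mm/frame rule) with position dropout."""
    duration = t[-1] - t[0]
    n = rng.poisson(cfg.blink_rate * duration / 60.0)
    times = []
    for _ in range(n):
        tb = rng.uniform(t[0] + 1.0, t[-1] - 1.0 - cfg.blink_duration)
        mask = (t >= tb) & (t < tb + cfg.blink_duration)
        pupil[mask] = 1.0
        x[mask] = np.nan
        y[mask] = np.nan
        valid[mask] = False
        times.append(float(tb))
    return times


def simulate_eyes(
    target: TargetTrace,
    truth: GroundTruth,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[EyeTrace, EyeTrace]:
    """Two eyes following the target with one subject-level latency and gain.

    Eye position is ``offset + gain * (target(t - latency) - offset)`` — the
    gain scales the excursion about the plate centre — plus per-eye Gaussian
    tracking noise, catch-up-saccade intrusions and binocular blinks.  Fills
    ``truth.latency_ms`` and ``truth.gain``.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    lat_s = _draw(rng, cfg.latency_ms) / 1000.0
    g = _draw(rng, cfg.gain)
    truth.latency_ms = lat_s * 1000.0
    truth.gain = g
    ox, oy = truth.plate_offset
    # Delayed target evaluated in continuous time via linear interpolation of
    # the observed track (exact on the ramps; jitter is band-limited).
    tx = np.where(target.present, target.x, np.nan)
    ok = np.isfinite(tx)
    t_eye = np.arange(target.t[0], target.t[-1], 1.0 / cfg.eye_rate)
    base_x = np.interp(t_eye - lat_s, target.t[ok], target.x[ok])
    base_y = np.interp(t_eye - lat_s, target.t[ok], target.y[ok])
    eyes = []
    blink_rng = np.random.default_rng(rng.integers(2**31))  # shared: blinks are binocular
    blink_state = blink_rng.bit_generator.state
    def tracking_noise(n: int) -> np.ndarray:
        # VOG error splits into slow accuracy drift (calibration residue and
        # fixational wander, the dominant share of the stated 0.2-0.5 deg
        # device error) and small frame-to-frame precision noise.  White
        # noise at the full stated SD would read as continuous >100 deg/s
        # motion, which no tracker exhibits.
        white = min(cfg.noise_white_sd, cfg.noise_sd)
        drift = np.sqrt(max(cfg.noise_sd**2 - white**2, 0.0))
        return _smooth_jitter(rng, n, cfg.eye_rate, drift, cfg.noise_drift_hz) + (
            rng.normal(0.0, white, n) if white > 0 else 0.0
        )

    for side in ("left", "right"):
        x = ox + g * (base_x - ox) + tracking_noise(len(t_eye))
        y = oy + g * (base_y - oy) + tracking_noise(len(t_eye))
        truth.saccade_times[side] = _inject_saccades(rng, t_eye, x, y, cfg)
        pupil = np.full(len(t_eye), cfg.pupil_mm) + rng.normal(0.0, 0.02, len(t_eye))
        valid = np.ones(len(t_eye), dtype=bool)
        blink_rng.bit_generator.state = blink_state
        truth.blink_times = _inject_blinks(blink_rng, t_eye, x, y, pupil, valid, cfg)
        eyes.append(
            EyeTrace(t=t_eye.copy(), x=x, y=y, pupil=pupil, valid=valid,
                     side=side, nominal_rate=cfg.eye_rate)
        )
    return eyes[0], eyes[1]


def simulate_session(
    cfg: SimulationConfig, rng: np.random.Generator | None = None,
    meta: dict | None = None,
) -> tuple[Recording, GroundTruth]:
    """One complete synthetic recording with its ground truth."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    target, truth = simulate_target(cfg, rng)
    left, right = simulate_eyes(target, truth, cfg, rng)
    truth.meta = dict(meta or {})
    return Recording(left=left, right=right, target=target, meta=dict(meta or {})), truth


def simulate_cohort(cfg: SimulationConfig) -> list[tuple[Recording, GroundTruth]]:
    """Independent sessions for ``cfg.n_subjects`` subjects.

    Per-subject random streams are spawned from the config seed, so the cohort
    is bitwise-reproducible and insensitive to per-session sample counts.
    """
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)
    out = []
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        out.append(simulate_session(cfg, rng, meta={"subject": f"S{i + 1:02d}"}))
    return out
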
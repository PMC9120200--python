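"""Direction classification for nine-direction testing without a trigger signal.

The examiner moves a hand-held target plate out to eight peripheral directions
and back; nothing records when or where each sweep started.  Two classifiers
recover the presentation directions from the target track alone:

* the *peak-fitting* classifier collapses the track to its position vector
  (distance from the per-recording median location, the "relative origin"),
  segments it into one excursion per min->max->min sweep, takes trimmed
  per-axis medians of each excursion, and assigns directions by rank grouping
  (top three horizontal medians are the right-group, etc.), which is immune to
  a constant offset of the plate relative to the camera;
* the *threshold* baseline bins each excursion's medians into a fixed +/-2 deg
  box grid around the camera origin, the conventional approach it is compared
  against.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .errors import (
    ClassificationDegeneracyError,
    ExcursionCountError,
    SegmentTooShortError,
    TraceValidationError,
)
from .trace_io import TargetTrace


class Direction(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    UPPER = "upper"
    LOWER = "lower"
    UPPER_LEFT = "upper_left"
    UPPER_RIGHT = "upper_right"
    LOWER_LEFT = "lower_left"
    LOWER_RIGHT = "lower_right"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Unit vectors (x right-positive, y up-positive); obliques lie on the diagonal,
#: so a radial amplitude A puts every direction within +/-A on both axes.
DIRECTION_VECTORS: dict[Direction, tuple[float, float]] = {
    Direction.LEFT: (-1.0, 0.0),
    Direction.RIGHT: (1.0, 0.0),
    Direction.UPPER: (0.0, 1.0),
    Direction.LOWER: (0.0, -1.0),
    Direction.UPPER_LEFT: (-np.sqrt(0.5), np.sqrt(0.5)),
    Direction.UPPER_RIGHT: (np.sqrt(0.5), np.sqrt(0.5)),
    Direction.LOWER_LEFT: (-np.sqrt(0.5), -np.sqrt(0.5)),
    Direction.LOWER_RIGHT: (np.sqrt(0.5), -np.sqrt(0.5)),
}

_OBLIQUE = {
    frozenset({"left", "upper"}): Direction.UPPER_LEFT,
    frozenset({"right", "upper"}): Direction.UPPER_RIGHT,
    frozenset({"left", "lower"}): Direction.LOWER_LEFT,
    frozenset({"right", "lower"}): Direction.LOWER_RIGHT,
}
_CARDINAL = {
    "left": Direction.LEFT,
    "right": Direction.RIGHT,
    "upper": Direction.UPPER,
    "lower": Direction.LOWER,
}


class RelativeOrigin(NamedTuple):
    """Per-recording stand-in for the unknown centre of the target plate."""

    x0: float
    y0: float


@dataclass
class PositionVectorTrace:
    """Euclidean distance of the origin-corrected location, over time."""

    t: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if len(self.t) != len(self.r):
            raise TraceValidationError("position vector: t/r length mismatch")

    def __len__(self) -> int:
        return len(self.t)


class Extremum(NamedTuple):
    """One retained peak of the position-vector trace."""

    t: float
    value: float
    kind: str  # "min" | "max"
    index: int


@dataclass
class Excursion:
    """One out-and-back sweep: two bounding minima around one maximum."""

    ordinal: int
    start_t: float
    max_t: float
    end_t: float
    h_med: float
    v_med: float
    peak_r: float


@dataclass
class ClassificationResult:
    labels: dict[int, Direction]
    method: str
    groups: dict[str, list[int]]
    excursions: list[Excursion]


@dataclass
class ScoreCard:
    """Agreement between predicted and true directions."""

    correct: int
    incorrect: int
    per_direction: dict[Direction, tuple[int, int]]  # direction -> (correct, total)

    @property
    def total(self) -> int:
        return self.correct + self.incorrect

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.correct / self.total if self.total else float("nan")


def relative_origin(target: TargetTrace) -> RelativeOrigin:
    """Component-wise median of the target track over the whole recording."""
    if len(target) == 0:
        raise TraceValidationError("relative origin of an empty target trace")
    ok = np.isfinite(target.x) & np.isfinite(target.y)
    if not ok.any():
        raise TraceValidationError("relative origin: no finite target samples")
    return RelativeOrigin(float(np.median(target.x[ok])), float(np.median(target.y[ok])))


def to_position_vector(
    t: np.ndarray, xs: np.ndarray, ys: np.ndarray, origin: RelativeOrigin
) -> PositionVectorTrace:
    """Collapse a 2-D track to its distance from the relative origin."""
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    if len(xs) != len(ys):
        raise TraceValidationError("position vector: x/y length mismatch")
    return PositionVectorTrace(t=np.asarray(t, float),
                               r=np.hypot(xs - origin.x0, ys - origin.y0))


def _raw_extrema(r: np.ndarray) -> tuple[list[int], list[int]]:
    """Interior local maxima/minima from sign changes of the first difference.

    Plateaus count once, at their centre sample.
    """
    maxima: list[int] = []
    minima: list[int] = []
    d = np.sign(np.diff(r))
    nz = np.flatnonzero(d)
    for a, b in zip(nz[:-1], nz[1:]):
        if d[a] == d[b]:
            continue
        idx = (a + 1 + b) // 2  # centre of the plateau r[a+1..b]
        (maxima if d[a] > 0 else minima).append(int(idx))
    return maxima, minima


def _prune_separation(cands: list[Extremum], separation: float, kind: str) -> list[Extremum]:
    """Greedy left-to-right pruning: within ``separation`` of the last kept
    extremum, keep whichever is more extreme."""
    better = (lambda a, b: a.value > b.value) if kind == "max" else (lambda a, b: a.value < b.value)
    kept: list[Extremum] = []
    for c in cands:
        if kept and c.t - kept[-1].t < separation:
            if better(c, kept[-1]):
                kept[-1] = c
        else:
            kept.append(c)
    return kept


def _collapse_alternation(extrema: list[Extremum]) -> list[Extremum]:
    """Collapse runs of same-type extrema, keeping the single most extreme one
    (lowest minimum between consecutive maxima, and symmetrically)."""
    out: list[Extremum] = []
    for e in extrema:
        if out and out[-1].kind == e.kind:
            if (e.kind == "max" and e.value > out[-1].value) or (
                e.kind == "min" and e.value < out[-1].value
            ):
                out[-1] = e
        else:
            out.append(e)
    return out


def _plateau_argmin(r: np.ndarray, lo: int, hi: int) -> int:
    """Index of the minimum of r[lo:hi], centre sample on exact ties."""
    seg = r[lo:hi]
    ties = np.flatnonzero(seg == seg.min())
    return lo + int(ties[(len(ties) - 1) // 2])


def _add_boundary_minima(extrema: list[Extremum], pv: PositionVectorTrace) -> list[Extremum]:
    """Bound leading/trailing maxima with the rest-phase minima at the trace ends.

    A session starts and ends at rest, so the trace boundaries act as the
    valleys enclosing the first and last sweeps (a triangular wave of n cycles
    has n maxima and n+1 minima, the outer two at the endpoints).
    """
    out = list(extrema)
    if out and out[0].kind == "max" and out[0].index > 0:
        i = _plateau_argmin(pv.r, 0, out[0].index)
        out.insert(0, Extremum(float(pv.t[i]), float(pv.r[i]), "min", i))
    if out and out[-1].kind == "max" and out[-1].index < len(pv) - 1:
        i = _plateau_argmin(pv.r, out[-1].index + 1, len(pv))
        out.append(Extremum(float(pv.t[i]), float(pv.r[i]), "min", i))
    return out


def detect_peaks(
    pv: PositionVectorTrace, separation: float = 3.0, min_peak_height: float = 2.0
) -> list[Extremum]:
    """Alternating maxima/minima of the position vector.

    Retained same-type extrema are at least ``separation`` seconds apart and
    types strictly alternate; leading/trailing maxima are bounded by the rest
    minima at the trace ends; a constant trace yields no extrema.

    Maxima below ``min_peak_height`` degrees are discarded before pruning:
    hand tremor wiggles the position vector around the origin between sweeps,
    and motion that never leaves the central region is not an excursion.
    """
    if len(pv) < 3:
        return []
    if pv.t[-1] - pv.t[0] <= 2 * separation:
        raise TraceValidationError("position-vector trace shorter than twice the peak separation")
    max_idx, min_idx = _raw_extrema(pv.r)
    maxima = [
        Extremum(float(pv.t[i]), float(pv.r[i]), "max", i)
        for i in max_idx
        if pv.r[i] >= min_peak_height
    ]
    minima = [Extremum(float(pv.t[i]), float(pv.r[i]), "min", i) for i in min_idx]
    maxima = _prune_separation(maxima, separation, "max")
    minima = _prune_separation(minima, separation, "min")
    merged = sorted(maxima + minima, key=lambda e: e.t)
    return _add_boundary_minima(_collapse_alternation(merged), pv)


def segment_excursions(
    pv: PositionVectorTrace,
    extrema: Sequence[Extremum],
    trim: float,
    h: np.ndarray,
    v: np.ndarray,
) -> list[Excursion]:
    """One excursion per (min, max, min) triple of the extrema list.

    ``h``/``v`` are the origin-corrected horizontal/vertical locations on the
    same timeline as ``pv``; medians are taken over the triple's interval with
    ``trim`` seconds removed at both ends.
    """
    if len(h) != len(pv) or len(v) != len(pv):
        raise TraceValidationError("segment_excursions: component series length mismatch")
    for a, b in zip(extrema[:-1], extrema[1:]):
        if a.kind == b.kind:
            raise TraceValidationError("extrema list does not alternate")
    excursions: list[Excursion] = []
    ordinal = 0
    for i in range(len(extrema) - 2):
        a, b, c = extrema[i], extrema[i + 1], extrema[i + 2]
        if (a.kind, b.kind, c.kind) != ("min", "max", "min"):
            continue
        mask = (pv.t >= a.t + trim) & (pv.t <= c.t - trim)
        if not mask.any():
            raise SegmentTooShortError(ordinal)
        excursions.append(
            Excursion(
                ordinal=ordinal,
                start_t=a.t,
                max_t=b.t,
                end_t=c.t,
                h_med=float(np.median(h[mask])),
                v_med=float(np.median(v[mask])),
                peak_r=b.value,
            )
        )
        ordinal += 1
    return excursions


def _rank(excursions: Sequence[Excursion], key) -> list[int]:
    """Ordinals sorted ascending by ``key``; ties broken by larger peak
    amplitude, then by presentation order, so exact ties cannot crash."""
    order = sorted(excursions, key=lambda e: (key(e), -e.peak_r, e.ordinal))
    return [e.ordinal for e in order]


def classify_peak(
    excursions: Sequence[Excursion], expected_excursions: int = 8
) -> ClassificationResult:
    """Rank-grouping direction assignment.

    The three smallest horizontal medians form the left group and the three
    largest the right group; likewise the three largest vertical medians are
    the upper group and the three smallest the lower group.  An excursion in
    two groups is oblique (e.g. left and upper -> upper_left); the remaining
    member of each group takes the cardinal label.  On a well-formed session
    the result is a bijection onto the eight peripheral directions.
    """
    if len(excursions) != expected_excursions:
        raise ExcursionCountError(
            f"expected {expected_excursions} excursions, found {len(excursions)}"
        )
    if expected_excursions != 8:
        raise ExcursionCountError(
            "rank grouping is defined for the 8-direction protocol"
        )
    by_h = _rank(excursions, lambda e: e.h_med)
    by_v = _rank(excursions, lambda e: e.v_med)
    groups = {
        "left": by_h[:3],
        "right": by_h[-3:],
        "lower": by_v[:3],
        "upper": by_v[-3:],
    }
    membership: dict[int, set[str]] = {e.ordinal: set() for e in excursions}
    for name, members in groups.items():
        for o in members:
            membership[o].add(name)
    labels: dict[int, Direction] = {}
    ambiguous: list[int] = []
    for o, names in membership.items():
        if frozenset(names) in _OBLIQUE:
            labels[o] = _OBLIQUE[frozenset(names)]
        elif len(names) == 1:
            labels[o] = _CARDINAL[next(iter(names))]
        else:
            ambiguous.append(o)
    if ambiguous or len(set(labels.values())) != 8:
        seen: dict[Direction, list[int]] = {}
        for o, lab in labels.items():
            seen.setdefault(lab, []).append(o)
        dupes = [o for v in seen.values() if len(v) > 1 for o in v]
        raise ClassificationDegeneracyError(sorted(set(ambiguous + dupes)))
    return ClassificationResult(
        labels=labels, method="peak", groups=groups, excursions=list(excursions)
    )


def classify_threshold(h_med: float, v_med: float, cutoff: float = 2.0) -> Direction | None:
    """Fixed box-grid baseline around the camera origin.

    Returns ``None`` (unclassified) for a median inside the central box.  A
    constant plate offset shifts every median and degrades this classifier —
    the failure mode the relative-origin correction of the peak method avoids.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    h_left, h_right = h_med <= -cutoff, h_med >= cutoff
    h_mid = -cutoff <= h_med <= cutoff
    v_low, v_up = v_med <= -cutoff, v_med >= cutoff
    v_mid = -cutoff <= v_med <= cutoff
    if h_left and v_mid:
        return Direction.LEFT
    if h_right and v_mid:
        return Direction.RIGHT
    if h_left and v_up:
        return Direction.UPPER_LEFT
    if h_right and v_up:
        return Direction.UPPER_RIGHT
    if h_left and v_low:
        return Direction.LOWER_LEFT
    if h_right and v_low:
        return Direction.LOWER_RIGHT
    if h_mid and v_up:
        return Direction.UPPER
    if h_mid and v_low:
        return Direction.LOWER
    return None


def classify_threshold_session(
    excursions: Sequence[Excursion],
    origin: RelativeOrigin,
    cutoff: float = 2.0,
) -> ClassificationResult:
    """Apply the threshold baseline to a whole session.

    The boxes sit in the *camera* frame (no relative-origin correction), so the
    stored origin-corrected medians are shifted back before binning.
    """
    labels = {
        e.ordinal: classify_threshold(e.h_med + origin.x0, e.v_med + origin.y0, cutoff)
        for e in excursions
    }
    return ClassificationResult(labels=labels, method="threshold", groups={},
                                excursions=list(excursions))


def score_classification(
    predicted: Mapping[int, Direction | None], truth: Mapping[int, Direction]
) -> ScoreCard:
    """Count agreements with the true presentation order; unclassified and
    missing predictions count as incorrect."""
    if set(predicted) - set(truth):
        raise TraceValidationError("predicted labels reference unknown ordinals")
    per: dict[Direction, list[int]] = {d: [0, 0] for d in Direction}
    correct = 0
    for o, true_label in truth.items():
        hit = predicted.get(o) == true_label
        per[true_label][1] += 1
        if hit:
            per[true_label][0] += 1
            correct += 1
    return ScoreCard(
        correct=correct,
        incorrect=len(truth) - correct,
        per_direction={d: (c, t) for d, (c, t) in per.items()},
    )


def derive_threshold_cutoff(
    calibration: Iterable[tuple[Direction, float, float]], ddof: int = 1
) -> float:
    """Derive the box half-width from a calibration cohort.

    For each direction, the magnitudes of the informative median components
    (horizontal for left/right, vertical for upper/lower, both for obliques)
    are pooled across subjects; the cutoff is the minimum over directions of
    mean - 2 SD.  The clinical default of 2.0 deg stands in when no
    calibration cohort is available.
    """
    pools: dict[Direction, list[float]] = {}
    for d, h, v in calibration:
        vals = pools.setdefault(d, [])
        ux, uy = DIRECTION_VECTORS[d]
        if ux != 0:
            vals.append(abs(h))
        if uy != 0:
            vals.append(abs(v))
    if not pools:
        raise TraceValidationError("empty calibration cohort")
    cutoffs = []
    for vals in pools.values():
        arr = np.asarray(vals, float)
        sd = arr.std(ddof=ddof) if len(arr) > ddof else 0.0
        cutoffs.append(arr.mean() - 2.0 * sd)
    return float(min(cutoffs))
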
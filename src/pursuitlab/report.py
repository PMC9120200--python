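"""Cohort orchestration: simulate -> preprocess -> classify -> analyze -> tables.

The report mirrors how the clinic would summarize a cohort: a contingency of
correct/incorrect direction classifications per method, and per-direction,
per-eye mean ± SD latency and gain tables.  Aggregation is a pure function of
the per-excursion rows, so re-running it alone reproduces the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .direction import (
    Direction,
    classify_peak,
    classify_threshold_session,
    detect_peaks,
    relative_origin,
    score_classification,
    segment_excursions,
    to_position_vector,
)
from .metrics import analyze_session
from .preprocess import SyncedRecording, preprocess_recording
from .synthetic import GroundTruth, SimulationConfig, simulate_cohort
from .trace_io import AnalysisConfig, Recording, TargetTrace

logger = logging.getLogger("pursuitlab")

_DIRECTION_ORDER = [
    Direction.LEFT, Direction.RIGHT, Direction.UPPER_LEFT, Direction.UPPER_RIGHT,
    Direction.LOWER_LEFT, Direction.LOWER_RIGHT, Direction.UPPER, Direction.LOWER,
]


@dataclass
class SessionResult:
    """Everything the pipeline derived from one recording."""

    subject: str
    synced: SyncedRecording
    peak_labels: dict[int, Direction]
    threshold_labels: dict[int, Direction | None]
    truth_labels: dict[int, Direction]
    metrics: pd.DataFrame  # one row per (excursion, eye)


@dataclass
class CohortReport:
    """Aggregated cohort tables plus run provenance."""

    summary: pd.DataFrame  # direction x eye: latency/gain mean, sd, n
    classification: dict[str, dict[str, float]]
    n_subjects: int
    excursions_per_subject: int
    seed: int
    config_hash: str
    version: str = __version__
    errors: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "n_subjects": self.n_subjects,
            "excursions_per_subject": self.excursions_per_subject,
            "classification": self.classification,
            "summary": self.summary.to_dict(orient="records"),
            "errors": self.errors,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _config_hash(sim_cfg: SimulationConfig, cfg: AnalysisConfig) -> str:
    blob = json.dumps(
        {"sim": sim_cfg.model_dump(), "analysis": cfg.model_dump()},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def classify_session(
    synced: SyncedRecording, cfg: AnalysisConfig
) -> tuple[object, object]:
    """Segment one synced session and run both classifiers on it.

    Returns (peak ClassificationResult, threshold ClassificationResult).
    """
    origin = relative_origin(TargetTrace(t=synced.t, x=synced.target_x, y=synced.target_y))
    pv = to_position_vector(synced.t, synced.target_x, synced.target_y, origin)
    extrema = detect_peaks(pv, cfg.peak_separation, cfg.min_peak_height)
    excursions = segment_excursions(
        pv, extrema, cfg.end_trim,
        synced.target_x - origin.x0, synced.target_y - origin.y0,
    )
    peak = classify_peak(excursions, cfg.expected_excursions)
    threshold = classify_threshold_session(excursions, origin, cfg.threshold_cutoff)
    return peak, threshold


def analyze_recording(
    rec: Recording, truth: GroundTruth, cfg: AnalysisConfig
) -> SessionResult:
    """Full pipeline for one recording, scored against its ground truth."""
    synced = preprocess_recording(rec, cfg)
    peak, threshold = classify_session(synced, cfg)
    metrics = analyze_session(synced, peak, cfg)
    rows = []
    for m in metrics:
        for side in ("left", "right"):
            rows.append(
                {
                    "subject": rec.meta.get("subject", ""),
                    "ordinal": m.ordinal,
                    "direction": m.direction.value if m.direction else None,
                    "eye": side,
                    "latency_ms": getattr(m, f"latency_{side}"),
                    "gain": getattr(m, f"gain_{side}"),
                    "error": m.errors.get(side) or m.errors.get("target"),
                }
            )
    return SessionResult(
        subject=rec.meta.get("subject", ""),
        synced=synced,
        peak_labels=peak.labels,
        threshold_labels=threshold.labels,
        truth_labels=truth.labels,
        metrics=pd.DataFrame(rows),
    )


_SUMMARY_COLUMNS = [
    "direction", "eye", "n",
    "latency_ms_mean", "latency_ms_sd", "gain_mean", "gain_sd",
]


def aggregate(per_excursion: pd.DataFrame) -> pd.DataFrame:
    """Direction x eye mean ± SD table from per-excursion metric rows."""
    if per_excursion.empty:
        return pd.DataFrame(columns=_SUMMARY_COLUMNS)
    rows = []
    for direction in _DIRECTION_ORDER:
        for eye in ("left", "right"):
            sel = per_excursion[
                (per_excursion["direction"] == direction.value)
                & (per_excursion["eye"] == eye)
            ]
            lat = sel["latency_ms"].dropna().to_numpy(float)
            gn = sel["gain"].dropna().to_numpy(float)
            rows.append(
                {
                    "direction": direction.value,
                    "eye": eye,
                    "n": int(len(sel)),
                    "latency_ms_mean": float(np.mean(lat)) if len(lat) else np.nan,
                    "latency_ms_sd": float(np.std(lat, ddof=1)) if len(lat) > 1 else np.nan,
                    "gain_mean": float(np.mean(gn)) if len(gn) else np.nan,
                    "gain_sd": float(np.std(gn, ddof=1)) if len(gn) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    sim_cfg: SimulationConfig | None = None,
    cfg: AnalysisConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[CohortReport, pd.DataFrame]:
    """Simulate a cohort and push every session through the full pipeline.

    Returns the aggregated report and the per-excursion metric rows.  Per-
    session failures are logged, recorded in ``report.errors`` and re-raised
    only if every session failed.
    """
    sim_cfg = sim_cfg or SimulationConfig()
    cfg = cfg or AnalysisConfig()
    sessions = simulate_cohort(sim_cfg)
    frames: list[pd.DataFrame] = []
    counts = {m: {"correct": 0, "incorrect": 0} for m in ("peak", "threshold")}
    errors: list[str] = []
    n_ok = 0
    for rec, truth in sessions:
        subject = rec.meta.get("subject", "?")
        try:
            res = analyze_recording(rec, truth, cfg)
        except Exception as err:
            msg = f"{subject}: {type(err).__name__}: {err}"
            logger.error("session failed: %s", msg)
            errors.append(msg)
            continue
        n_ok += 1
        for method, labels in (("peak", res.peak_labels), ("threshold", res.threshold_labels)):
            score = score_classification(labels, res.truth_labels)
            counts[method]["correct"] += score.correct
            counts[method]["incorrect"] += score.incorrect
        frames.append(res.metrics)
    if not n_ok:
        raise RuntimeError("every session failed: " + "; ".join(errors))
    per_excursion = pd.concat(frames, ignore_index=True)
    classification = {}
    for method, c in counts.items():
        total = c["correct"] + c["incorrect"]
        classification[method] = {
            "correct": c["correct"],
            "incorrect": c["incorrect"],
            "total": total,
            "accuracy_pct": 100.0 * c["correct"] / total if total else float("nan"),
        }
    report = CohortReport(
        summary=aggregate(per_excursion),
        classification=classification,
        n_subjects=sim_cfg.n_subjects,
        excursions_per_subject=cfg.expected_excursions,
        seed=sim_cfg.seed,
        config_hash=_config_hash(sim_cfg, cfg),
        errors=errors,
    )
    if out_dir is not None:
        write_report(report, per_excursion, out_dir)
    return report, per_excursion


def render_tables(report: CohortReport) -> dict[str, pd.DataFrame]:
    """Latency, gain and classification tables as tidy DataFrames."""
    s = report.summary
    latency = s[["direction", "eye", "n", "latency_ms_mean", "latency_ms_sd"]].copy()
    gain = s[["direction", "eye", "n", "gain_mean", "gain_sd"]].copy()
    cls = pd.DataFrame(
        [{"method": m, **v} for m, v in report.classification.items()]
    )
    return {"latency_table": latency, "gain_table": gain, "classification_table": cls}


def write_report(report: CohortReport, per_excursion: pd.DataFrame,
                 out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json(), encoding="utf-8")
    per_excursion.to_csv(out / "per_excursion.csv", index=False, float_format="%.6f")
    for name, df in render_tables(report).items():
        df.to_csv(out / f"{name}.csv", index=False, float_format="%.6f")
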
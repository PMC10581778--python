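"""End-to-end analysis: downsample, segment, fit, and tabulate metrics.

``analyze_recording`` turns one gap-free recording into per-activation
metrics; ``analyze_population`` maps it over many recordings, collecting a
tidy table (one row per cell x activation) and logging per-cell failures
without aborting the run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .traces import Recording, downsample, segment_activations
from .vanthoff import (
    ActivationMetrics,
    EmptyCurveError,
    FitError,
    derive_metrics,
    fit_segmented,
    to_vanthoff,
)

__all__ = ["AnalysisOptions", "analyze_recording", "analyze_population", "metrics_long"]


@dataclass(frozen=True)
class AnalysisOptions:
    """Tunable parameters of the standard analysis chain."""

    downsample_to: float = 100.0
    min_peak_temp: float = 30.0
    min_separation: float = 10.0
    q10_floor: float = 3.0
    max_breakpoints: int = 2
    min_seg_points: int = 5
    max_candidates: int = 400
    current_floor: float = 1e-3
    max_current_at: float = 35.0
    bootstrap_reps: int = 0
    seed: int = 0


def analyze_recording(
    rec: Recording, options: AnalysisOptions = AnalysisOptions()
) -> list[ActivationMetrics]:
    """Per-activation metrics for one recording.

    Downsampling is skipped when the recording is already at or below the
    target rate.  Activations whose van't Hoff fit is under-determined are
    skipped (they are reported by :func:`analyze_population`).
    """
    if rec.sample_rate > options.downsample_to:
        rec = downsample(rec, options.downsample_to)
    segments = segment_activations(
        rec, min_peak_temp=options.min_peak_temp, min_separation=options.min_separation
    )
    out = []
    for seg in segments:
        curve = to_vanthoff(seg, current_floor=options.current_floor)
        fit = fit_segmented(
            curve,
            max_breakpoints=options.max_breakpoints,
            min_seg_points=options.min_seg_points,
            max_candidates=options.max_candidates,
            bootstrap_reps=options.bootstrap_reps,
            seed=options.seed,
        )
        out.append(
            derive_metrics(
                fit, seg, q10_floor=options.q10_floor, max_current_at=options.max_current_at
            )
        )
    return out


def analyze_population(
    recordings: Iterable[Recording],
    options: AnalysisOptions = AnalysisOptions(),
) -> tuple[pd.DataFrame, list[dict]]:
    """Analyze many recordings into a tidy metrics table.

    Returns ``(table, failures)``: the table has one row per cell x
    activation with threshold/Q10/leak/max-current columns plus the
    recording metadata; failures list per-cell error descriptions for
    recordings that could not be analyzed (the run continues past them).
    """
    rows = []
    failures: list[dict] = []
    for rec in recordings:
        cell_id = str(rec.metadata.get("cell_id", "?"))
        try:
            metrics = analyze_recording(rec, options)
        except (FitError, EmptyCurveError, ValueError) as exc:
            failures.append({"cell_id": cell_id, "error": str(exc)})
            continue
        for m in metrics:
            row = dataclasses.asdict(m)
            row["cell_id"] = cell_id
            row["condition"] = rec.metadata.get("condition", "control")
            row["construct"] = rec.metadata.get("construct", "")
            if "rna_ng" in rec.metadata:
                row["rna_ng"] = rec.metadata["rna_ng"]
            rows.append(row)
    table = pd.DataFrame(rows)
    return table, failures


def metrics_long(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Extract one metric as the long-format table the stats layer expects."""
    if metric not in table.columns:
        raise ValueError(f"unknown metric {metric!r}")
    cols = ["cell_id", "condition", "activation_index"]
    extra = [c for c in ("rna_ng",) if c in table.columns]
    out = table[cols + extra + [metric]].rename(columns={metric: "value"})
    return out.dropna(subset=["value"]).reset_index(drop=True)
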
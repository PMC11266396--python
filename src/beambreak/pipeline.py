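"""Run-level orchestration: from per-column logfiles to the standard result
tables (event series, activity series, phase statistics, group mean,
average-day profile), all in experiment-local time."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .activity import activity_series
from .config import ExperimentConfig
from .events import BinnedSeries, module_series
from .stats import (
    AverageDayProfile,
    GroupSeries,
    QCDecision,
    average_day,
    group_series,
    label_phases,
    phase_comparison,
    qc_screen,
)


@dataclass
class AnalysisResult:
    qc: dict[str, QCDecision]
    kept_columns: list[str]
    events: pd.DataFrame
    activity: pd.DataFrame
    phase: pd.DataFrame
    group_mean: GroupSeries | None
    profile: AverageDayProfile | None
    column_activity_norm: dict[str, BinnedSeries] = field(default_factory=dict)


def _localized(records: pd.DataFrame, config: ExperimentConfig) -> pd.DataFrame:
    out = records.copy()
    out["timestamp"] = config.to_local(out["timestamp"])
    return out


def analyze_experiment(
    records_by_column: dict[str, pd.DataFrame],
    config: ExperimentConfig,
    bin_minutes: int = 10,
    smooth_bins: int = 6,
) -> AnalysisResult:
    """Full analysis of one recording run.

    Columns failing quality screening are excluded up front; per-module
    event series and the column-level upward-swimming activity series are
    binned, normalized and smoothed; light phases are compared per module,
    per column and on the group-mean activity; the group activity is folded
    into an average day.
    """
    qc = qc_screen(
        records_by_column,
        config.geometry,
        config.scan,
        duration_ms=config.duration_s * 1000.0,
    )
    kept = [c for c, d in qc.items() if d.keep]
    start, end = config.start_local, config.end_local

    event_rows, activity_rows, phase_rows = [], [], []
    norm_by_column: dict[str, BinnedSeries] = {}
    for col in kept:
        rec = _localized(records_by_column[col], config)
        on = straddle = None
        for m in range(1, config.geometry.n_modules + 1):
            trio = module_series(
                rec, m, start=start, end=end,
                bin_minutes=bin_minutes, smooth_bins=smooth_bins,
            )
            bs = trio["normalized"]
            if on is None:
                on, straddle = label_phases(bs.bin_starts, config.regime, bin_minutes)
            event_rows.append(
                pd.DataFrame(
                    {
                        "column_id": col,
                        "module": m,
                        "bin_start": bs.bin_starts,
                        "raw": trio["raw"].values.to_numpy(),
                        "normalized": bs.values.to_numpy(),
                        "smoothed": trio["smoothed"].values.to_numpy(),
                        "partial": bs.partial.to_numpy(),
                    }
                )
            )
            phase_rows.append(
                phase_comparison(bs, on, straddle, unit=f"{col}/module {m}")
            )
        act = activity_series(
            rec, start=start, end=end, bin_minutes=bin_minutes, smooth_bins=smooth_bins
        )
        bs = act["normalized"]
        norm_by_column[col] = bs
        activity_rows.append(
            pd.DataFrame(
                {
                    "column_id": col,
                    "bin_start": bs.bin_starts,
                    "upward_count": act["raw"].values.to_numpy(),
                    "normalized": bs.values.to_numpy(),
                    "smoothed": act["smoothed"].values.to_numpy(),
                    "partial": bs.partial.to_numpy(),
                }
            )
        )
        phase_rows.append(
            phase_comparison(bs, on, straddle, unit=f"{col}/activity")
        )

    group = None
    profile = None
    if norm_by_column:
        group = group_series(list(norm_by_column.values()))
        on, straddle = label_phases(
            group.mean.bin_starts, config.regime, bin_minutes
        )
        phase_rows.append(
            phase_comparison(group.mean, on, straddle, unit="group/activity")
        )
        profile = average_day(list(norm_by_column.values()))

    phase = pd.DataFrame(
        [
            {
                "unit": p.unit,
                "U": p.u,
                "p": p.p_two_sided,
                "n_on": p.n_on,
                "n_off": p.n_off,
                "direction": p.direction,
                "stars": p.stars,
                "testable": p.testable,
            }
            for p in phase_rows
        ]
    )
    return AnalysisResult(
        qc=qc,
        kept_columns=kept,
        events=pd.concat(event_rows, ignore_index=True) if event_rows else pd.DataFrame(),
        activity=pd.concat(activity_rows, ignore_index=True) if activity_rows else pd.DataFrame(),
        phase=phase,
        group_mean=group,
        profile=profile,
        column_activity_norm=norm_by_column,
    )


def write_tables(result: AnalysisResult, out_dir) -> None:
    """Write the standard delimiter-separated result tables."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    result.events.to_csv(os.path.join(out_dir, "event_series.csv"), index=False)
    result.activity.to_csv(os.path.join(out_dir, "activity_series.csv"), index=False)
    result.phase.to_csv(os.path.join(out_dir, "phase_comparisons.csv"), index=False)
    qc_df = pd.DataFrame(
        [
            {"column_id": d.column_id, "keep": d.keep, "reasons": "; ".join(d.reasons)}
            for d in result.qc.values()
        ]
    )
    qc_df.to_csv(os.path.join(out_dir, "qc_decisions.csv"), index=False)
    if result.group_mean is not None:
        pd.DataFrame(
            {
                "bin_start": result.group_mean.mean.bin_starts,
                "mean": result.group_mean.mean.values.to_numpy(),
                "sem": result.group_mean.sem.to_numpy(),
            }
        ).to_csv(os.path.join(out_dir, "group_activity.csv"), index=False)
    if result.profile is not None:
        result.profile.frame().to_csv(
            os.path.join(out_dir, "average_day.csv"), index=False
        )
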
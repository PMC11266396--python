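"""Per-module beam-break event series: 1-min event rule, 10-min binning,
min-max normalization and a centered moving average.

A *beam-break event* is a presence indicator: at least one detection at a
module within a calendar minute.  Events are summed into calendar-aligned
10-min bins (values 0..10), rescaled to [0, 1] over the whole recording per
module, and smoothed for visualisation with a 6-bin centered moving average.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


@dataclass
class BinnedSeries:
    """A calendar-aligned binned series with explicit processing state.

    ``values`` is indexed by bin-start timestamps; ``partial`` flags bins not
    fully covered by the recording span (kept for series continuity, excluded
    from statistics).
    """

    values: pd.Series
    level: str
    bin_minutes: int = 10
    normalized: bool = False
    smoothed: bool = False
    partial: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        if len(idx) > 1:
            step = pd.Timedelta(minutes=self.bin_minutes)
            if not (pd.DatetimeIndex(idx).to_series().diff().dropna() == step).all():
                raise ValueError("bins must be contiguous and non-overlapping")
        if self.partial is None:
            self.partial = pd.Series(False, index=idx)

    @property
    def bin_starts(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.values.index)

    def usable(self) -> pd.Series:
        """Values of complete (non-partial) bins."""
        return self.values[~self.partial]


def _span(records_ts, start, end):
    ts = pd.DatetimeIndex(records_ts)
    if start is None:
        if len(ts) == 0:
            raise ValueError("empty records need an explicit start/end span")
        start = ts.min()
    if end is None:
        if len(ts) == 0:
            raise ValueError("empty records need an explicit start/end span")
        end = ts.max() + pd.Timedelta(milliseconds=1)
    return pd.Timestamp(start), pd.Timestamp(end)


def minute_events(
    records: pd.DataFrame,
    module_index: int,
    start=None,
    end=None,
    time_column: str = "timestamp",
) -> pd.Series:
    """Binary per-minute event series for one module of one column.

    A minute scores 1 iff it contains at least one detection at the module
    (saturating — duplicate detections within the minute are irrelevant).
    The series covers every calendar minute of [start, end).
    """
    start, end = _span(records[time_column] if len(records) else [], start, end)
    idx = pd.date_range(start.floor("min"), (end - pd.Timedelta(nanoseconds=1)).floor("min"), freq="min")
    out = pd.Series(0, index=idx, dtype=np.int64)
    sel = records[records["module"] == module_index]
    if len(sel):
        minutes = pd.DatetimeIndex(sel[time_column]).floor("min")
        out[minutes.unique().intersection(idx)] = 1
    return out


def bin_10min(
    minute_series: pd.Series, bin_minutes: int = 10, level: str = "module"
) -> BinnedSeries:
    """Sum calendar-minute events into calendar-aligned bins.

    First/last bins only partly covered by the minute series are retained
    but flagged partial.
    """
    if bin_minutes < 1:
        raise ValueError("bin_minutes must be >= 1")
    freq = f"{bin_minutes}min"
    grouped = minute_series.groupby(minute_series.index.floor(freq)).sum()
    idx = pd.date_range(grouped.index.min(), grouped.index.max(), freq=freq)
    values = grouped.reindex(idx, fill_value=0).astype(float)
    counts = minute_series.groupby(minute_series.index.floor(freq)).size()
    partial = counts.reindex(idx, fill_value=0) < bin_minutes
    return BinnedSeries(values=values, level=level, bin_minutes=bin_minutes, partial=partial)


def count_bins(
    timestamps,
    start,
    end,
    bin_minutes: int = 10,
    level: str = "column",
) -> BinnedSeries:
    """Raw detection counts per calendar-aligned bin over [start, end)."""
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    freq = f"{bin_minutes}min"
    first = start.floor(freq)
    last = (end - pd.Timedelta(nanoseconds=1)).floor(freq)
    idx = pd.date_range(first, last, freq=freq)
    ts = pd.DatetimeIndex(timestamps)
    counts = pd.Series(0.0, index=idx)
    if len(ts):
        got = ts.floor(freq).value_counts()
        counts.loc[got.index.intersection(idx)] = got[got.index.intersection(idx)].astype(float)
    step = pd.Timedelta(minutes=bin_minutes)
    partial = pd.Series((idx < start) | (idx + step > end), index=idx)
    return BinnedSeries(values=counts, level=level, bin_minutes=bin_minutes, partial=partial)


def normalize_minmax(series: BinnedSeries) -> BinnedSeries:
    """Rescale to [0, 1] over the whole recording; a constant series maps to
    all zeros (degenerate range)."""
    v = series.values
    lo, hi = float(v.min()), float(v.max())
    if hi > lo:
        out = (v - lo) / (hi - lo)
    else:
        out = v * 0.0
    return replace(series, values=out, normalized=True, partial=series.partial.copy())


def smooth_centered(series: BinnedSeries, k: int = 6) -> BinnedSeries:
    """Centered moving average over ``k`` bins.

    Even ``k`` uses the left-heavy convention (for k = 6: three bins before
    through two after); windows shrink at the edges instead of emitting
    missing values.
    """
    if k <= 0:
        raise ValueError("window size k must be >= 1")
    out = series.values.rolling(window=k, center=True, min_periods=1).mean()
    return replace(series, values=out, smoothed=True, partial=series.partial.copy())


def module_series(
    records: pd.DataFrame,
    module_index: int,
    start=None,
    end=None,
    bin_minutes: int = 10,
    smooth_bins: int = 6,
) -> dict[str, BinnedSeries]:
    """Full per-module pipeline: events -> bins -> normalized -> smoothed."""
    minutes = minute_events(records, module_index, start=start, end=end)
    raw = bin_10min(minutes, bin_minutes=bin_minutes, level=f"module:{module_index}")
    norm = normalize_minmax(raw)
    return {"raw": raw, "normalized": norm, "smoothed": smooth_centered(norm, smooth_bins)}
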
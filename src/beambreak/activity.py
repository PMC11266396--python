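"""Upward-swimming activity metric.

In a confined column a negatively buoyant animal triggers beams by actively
ascending, passively sinking, or hovering at a detector, so raw beam breaks
confound baseline and elevated activity.  Restricting to detections whose
*immediately preceding* detection (all modules merged chronologically)
occurred at a module lower in the column isolates the upward-swimming
component as a conservative activity measure.  Module index 1 is the top, so
"lower in the column" means a larger module index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .events import BinnedSeries, count_bins, normalize_minmax, smooth_centered


def upward_mask(
    modules: np.ndarray, predecessor: str = "previous"
) -> np.ndarray:
    """Boolean retain-mask for a chronologically sorted module sequence.

    ``predecessor='previous'`` (default): a record is retained iff the
    record immediately before it sits at a larger module index; a repeat at
    the same module is not retained and becomes the new predecessor.
    ``predecessor='previous-distinct'``: same-module repeats are transparent
    and the comparison uses the last record at a *different* module.
    The first record is never retained.
    """
    m = np.asarray(modules)
    keep = np.zeros(m.shape, dtype=bool)
    if m.size < 2:
        return keep
    if predecessor == "previous":
        keep[1:] = m[:-1] > m[1:]
        return keep
    if predecessor != "previous-distinct":
        raise ValueError("predecessor must be 'previous' or 'previous-distinct'")
    last = m[0]
    for i in range(1, m.size):
        if m[i] != last:
            keep[i] = last > m[i]
            last = m[i]
    return keep


def upward_filter(
    records: pd.DataFrame,
    predecessor: str = "previous",
    tie_order: str = "bottom-first",
    time_column: str = "timestamp",
) -> pd.DataFrame:
    """Sort one column's records chronologically and flag upward detections.

    Returns a copy sorted by (timestamp, module, beam) — simultaneous
    records ordered bottom-module-first by default, so an ascending burst in
    one scan rotation counts as upward — with a boolean ``retained`` audit
    column marking the upward-swimming subset.
    """
    df = records.copy()
    key_mod = -df["module"] if tie_order == "bottom-first" else df["module"]
    order = np.lexsort((df["beam"].to_numpy(), key_mod.to_numpy(),
                        pd.DatetimeIndex(df[time_column]).asi8))
    df = df.iloc[order].reset_index(drop=True)
    df["retained"] = upward_mask(df["module"].to_numpy(), predecessor=predecessor)
    return df


def activity_series(
    records: pd.DataFrame,
    start=None,
    end=None,
    bin_minutes: int = 10,
    smooth_bins: int = 6,
    predecessor: str = "previous",
    tie_order: str = "bottom-first",
    time_column: str = "timestamp",
) -> dict[str, object]:
    """Column-level swimming-activity pipeline.

    Raw beam breaks (not 1-min events) are filtered to the upward subset,
    counted per calendar-aligned bin, min-max normalized per column and
    smoothed.  Returns the flagged records plus raw / normalized / smoothed
    :class:`BinnedSeries`.
    """
    flagged = upward_filter(
        records, predecessor=predecessor, tie_order=tie_order, time_column=time_column
    )
    ts = pd.DatetimeIndex(flagged[time_column])
    if start is None:
        start = ts.min() if len(ts) else None
    if end is None:
        end = ts.max() + pd.Timedelta(milliseconds=1) if len(ts) else None
    if start is None or end is None:
        raise ValueError("empty records need an explicit start/end span")
    raw = count_bins(
        ts[flagged["retained"].to_numpy()], start, end, bin_minutes=bin_minutes, level="column"
    )
    norm = normalize_minmax(raw)
    return {
        "records": flagged,
        "raw": raw,
        "normalized": norm,
        "smoothed": smooth_centered(norm, smooth_bins),
    }
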
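"""Light-phase statistics: phase labelling, Mann-Whitney U comparison of
lights-on vs lights-off bins, group aggregation, average-day profiles and
quality screening of columns.

The U test is implemented from rank sums with midranks; exact two-sided
p-values enumerate every labelling of the pooled sample (ties handled by
permuting the observed multiset), the large-sample mode uses the normal
approximation with tie-corrected variance and continuity correction.  Note
that binned behavioural series are serially correlated, which the U test's
exchangeability assumption ignores; comparisons therefore default to
unsmoothed bins (smoothing would add further autocorrelation) and no
block-resampling correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .events import BinnedSeries
from .geometry import DetectorGeometry, ScanParams
from .light import LightRegime, is_light

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def star_code(p: float) -> str:
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return "ns"


# --- phase labelling ------------------------------------------------------


def label_phases(bin_starts, regime: LightRegime, bin_minutes: int = 10):
    """Label bins lights-on/off by the light state at the bin start.

    Returns (on, straddle): ``on`` is True where the intensity at the bin
    start is positive; ``straddle`` flags bins containing a lights-on/off
    transition (labelled by their start, excluded from statistics).
    Accepts a DatetimeIndex of (local) bin starts or an array of day-hours.
    """
    if isinstance(bin_starts, BinnedSeries):
        bin_starts = bin_starts.bin_starts
    if isinstance(bin_starts, (pd.DatetimeIndex, pd.Series)):
        idx = pd.DatetimeIndex(bin_starts)
        hours = ((idx - idx.normalize()).total_seconds() / 3600.0).to_numpy()
    else:
        hours = np.asarray(bin_starts, dtype=float)
    on = np.asarray(is_light(regime, hours))
    end_hours = (hours + bin_minutes / 60.0 - 1e-9) % 24.0
    straddle = on != np.asarray(is_light(regime, end_hours))
    return on, straddle


# --- Mann-Whitney U -------------------------------------------------------


@dataclass(frozen=True)
class MannWhitneyResult:
    u_x: float
    u_y: float
    p_two_sided: float
    n_x: int
    n_y: int
    method: str


def _u_from_ranks(ranks: np.ndarray, n_x: int) -> float:
    r_x = float(ranks[:n_x].sum())
    return r_x - n_x * (n_x + 1) / 2.0


def mann_whitney_u(x, y, mode: str = "auto", max_exact: int = 12) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    ``mode='exact'`` enumerates all C(n_x+n_y, n_x) labelings of the pooled
    multiset (midranks for ties); ``'approx'`` uses the tie-corrected normal
    approximation with continuity correction; ``'auto'`` picks exact for
    n_x + n_y <= ``max_exact``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_x, n_y = x.size, y.size
    if n_x == 0 or n_y == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks
    u_x = _u_from_ranks(ranks, n_x)
    u_y = n_x * n_y - u_x
    mu = n_x * n_y / 2.0

    if mode not in ("auto", "exact", "approx"):
        raise ValueError("mode must be 'auto', 'exact' or 'approx'")
    exact = mode == "exact" or (mode == "auto" and n_x + n_y <= max_exact)

    if exact:
        n = n_x + n_y
        total = comb(n, n_x)
        obs_dev = abs(u_x - mu)
        hits = 0
        for c in combinations(range(n), n_x):
            u = float(ranks[list(c)].sum()) - n_x * (n_x + 1) / 2.0
            if abs(u - mu) >= obs_dev - 1e-9:
                hits += 1
        return MannWhitneyResult(u_x, u_y, hits / total, n_x, n_y, "exact")

    n = n_x + n_y
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n_x * n_y / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:  # all observations identical
        return MannWhitneyResult(u_x, u_y, 1.0, n_x, n_y, "approx")
    z = (abs(u_x - mu) - 0.5) / np.sqrt(sigma2)
    p = min(1.0, 2.0 * norm.sf(max(z, 0.0)))
    return MannWhitneyResult(u_x, u_y, p, n_x, n_y, "approx")


# --- phase comparison -----------------------------------------------------


@dataclass(frozen=True)
class PhaseComparison:
    """Lights-off vs lights-on comparison for one unit (module, column or
    group).  ``u`` is the U statistic of the lights-off sample; ``direction``
    is the sign of median(off) - median(on) (+1 = more activity in the
    dark)."""

    unit: str
    u: float
    p_two_sided: float
    n_on: int
    n_off: int
    direction: int
    stars: str
    testable: bool = True


def phase_comparison(
    series: BinnedSeries,
    on: np.ndarray,
    straddle: np.ndarray | None = None,
    unit: str = "column",
    mode: str = "approx",
) -> PhaseComparison:
    """Compare unsmoothed bin values between light phases.

    Partial and transition-straddling bins are excluded.  A phase with no
    usable bins yields a not-testable result; identical samples give p = 1
    and direction 0.
    """
    v = series.values.to_numpy(dtype=float)
    usable = ~series.partial.to_numpy()
    if straddle is not None:
        usable &= ~np.asarray(straddle)
    on = np.asarray(on, dtype=bool)
    off_vals = v[usable & ~on]
    on_vals = v[usable & on]
    if off_vals.size == 0 or on_vals.size == 0:
        return PhaseComparison(unit, np.nan, np.nan, on_vals.size, off_vals.size, 0, "ns", False)
    res = mann_whitney_u(off_vals, on_vals, mode=mode)
    direction = int(np.sign(np.median(off_vals) - np.median(on_vals)))
    return PhaseComparison(
        unit, res.u_x, res.p_two_sided, on_vals.size, off_vals.size,
        direction, star_code(res.p_two_sided),
    )


def group_phase_comparison(
    series_list: list[BinnedSeries],
    on: np.ndarray,
    straddle: np.ndarray | None = None,
    mode: str = "mean",
    test_mode: str = "approx",
) -> PhaseComparison:
    """Group-level lights-off vs lights-on comparison.

    ``mode='mean'`` (default) tests the per-bin group-mean series — one
    value per bin, individuals averaged first.  ``mode='pooled'`` pools
    every individual's usable bins into the two phase samples, weighting
    individuals by their bin counts.
    """
    if mode == "mean":
        g = group_series(series_list)
        return phase_comparison(g.mean, on, straddle, unit="group", mode=test_mode)
    if mode != "pooled":
        raise ValueError("mode must be 'mean' or 'pooled'")
    on = np.asarray(on, dtype=bool)
    off_vals, on_vals = [], []
    for s in series_list:
        usable = ~s.partial.to_numpy()
        if straddle is not None:
            usable &= ~np.asarray(straddle)
        v = s.values.to_numpy(dtype=float)
        off_vals.append(v[usable & ~on])
        on_vals.append(v[usable & on])
    off_all = np.concatenate(off_vals)
    on_all = np.concatenate(on_vals)
    if off_all.size == 0 or on_all.size == 0:
        return PhaseComparison("group", np.nan, np.nan, on_all.size, off_all.size, 0, "ns", False)
    res = mann_whitney_u(off_all, on_all, mode=test_mode)
    direction = int(np.sign(np.median(off_all) - np.median(on_all)))
    return PhaseComparison(
        "group", res.u_x, res.p_two_sided, on_all.size, off_all.size,
        direction, star_code(res.p_two_sided),
    )


# --- group aggregation ----------------------------------------------------


@dataclass
class GroupSeries:
    """Per-bin mean and s.e.m. across individuals on a shared grid."""

    mean: BinnedSeries
    sem: pd.Series
    n: int


def group_series(series_list: list[BinnedSeries]) -> GroupSeries:
    """Mean +/- s.e.m. across individuals (sample sd, n-1 denominator).

    All series must share the same bin grid; the s.e.m. is undefined
    (missing) for a single individual."""
    if not series_list:
        raise ValueError("need at least one series")
    idx = series_list[0].bin_starts
    for s in series_list[1:]:
        if not idx.equals(s.bin_starts):
            raise ValueError("series bins are not aligned on the same calendar grid")
    mat = np.vstack([s.values.to_numpy(dtype=float) for s in series_list])
    n = mat.shape[0]
    mean = pd.Series(mat.mean(axis=0), index=idx)
    if n > 1:
        sem = pd.Series(mat.std(axis=0, ddof=1) / np.sqrt(n), index=idx)
    else:
        sem = pd.Series(np.nan, index=idx)
    partial = series_list[0].partial.copy()
    for s in series_list[1:]:
        partial |= s.partial
    first = series_list[0]
    mean_bs = BinnedSeries(
        values=mean, level="group", bin_minutes=first.bin_minutes,
        normalized=first.normalized, smoothed=first.smoothed, partial=partial,
    )
    return GroupSeries(mean=mean_bs, sem=sem, n=n)


# --- average day ----------------------------------------------------------


@dataclass
class AverageDayProfile:
    """Time-of-day profile: mean, s.e.m. and contribution count per bin.

    ``minute_of_day`` holds bin starts (0, 10, ..., 1430 for 10-min bins);
    s.e.m. is reported missing where only one value contributes."""

    minute_of_day: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray
    bin_minutes: int = 10

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "minute_of_day": self.minute_of_day,
                "mean": self.mean,
                "sem": self.sem,
                "n": self.n,
            }
        )


def average_day(series, bin_minutes: int | None = None) -> AverageDayProfile:
    """Fold one or more binned series by time of day.

    Every usable (complete) bin of every series contributes one value to its
    time-of-day slot; mean and s.e.m. are taken across contributions
    (individuals x days).  Raises if the input does not cover a complete
    day."""
    if isinstance(series, BinnedSeries):
        series = [series]
    if not series:
        raise ValueError("need at least one series")
    bm = bin_minutes or series[0].bin_minutes
    n_bins = (24 * 60) // bm
    buckets: list[list[float]] = [[] for _ in range(n_bins)]
    for s in series:
        if s.bin_minutes != bm:
            raise ValueError("series bin widths differ")
        idx = s.bin_starts
        mins = ((idx - idx.normalize()).total_seconds() // 60).astype(int)
        usable = ~s.partial.to_numpy()
        for m, v, u in zip(mins, s.values.to_numpy(dtype=float), usable):
            if u:
                buckets[int(m) // bm].append(v)
    if any(len(b) == 0 for b in buckets):
        raise ValueError("input does not cover a complete day")
    mean = np.array([np.mean(b) for b in buckets])
    n = np.array([len(b) for b in buckets])
    sem = np.array(
        [np.std(b, ddof=1) / np.sqrt(len(b)) if len(b) > 1 else np.nan for b in buckets]
    )
    return AverageDayProfile(
        minute_of_day=np.arange(n_bins) * bm, mean=mean, sem=sem, n=n, bin_minutes=bm
    )


# --- quality screening ----------------------------------------------------


@dataclass(frozen=True)
class QCDecision:
    column_id: str
    keep: bool
    reasons: tuple[str, ...]


def qc_screen(
    records_by_column: dict[str, pd.DataFrame],
    geometry: DetectorGeometry | None = None,
    scan: ScanParams | None = None,
    duration_ms: float | None = None,
    min_detections: int = 10,
    stuck_fraction: float = 0.5,
) -> dict[str, QCDecision]:
    """Flag columns with technically faulty detector modules.

    A column is dropped when a module logged nothing over the whole
    recording while every other module logged at least ``min_detections``
    (dead module), or when a module fired in more than ``stuck_fraction`` of
    its scan rotations (stuck detector) — a healthy animal occludes a module
    only while passing or hovering at it, a shorted receiver fires in every
    rotation."""
    geometry = geometry or DetectorGeometry()
    scan = scan or ScanParams()
    out: dict[str, QCDecision] = {}
    for col, df in records_by_column.items():
        counts = df["module"].value_counts()
        per_module = np.array(
            [int(counts.get(m, 0)) for m in range(1, geometry.n_modules + 1)]
        )
        reasons: list[str] = []
        for m in range(1, geometry.n_modules + 1):
            others = np.delete(per_module, m - 1)
            if per_module[m - 1] == 0 and len(others) and (others >= min_detections).all():
                reasons.append(f"dead module {m}")
        if duration_ms is None and len(df):
            ts = pd.DatetimeIndex(df["timestamp"])
            dur = float((ts.max() - ts.min()).total_seconds() * 1000)
        else:
            dur = float(duration_ms or 0)
        if dur > 0:
            rotations = dur / scan.rotation_period_ms(geometry.beams_per_module)
            for m in range(1, geometry.n_modules + 1):
                if per_module[m - 1] > stuck_fraction * rotations:
                    reasons.append(f"stuck detector module {m}")
        out[col] = QCDecision(col, keep=not reasons, reasons=tuple(reasons))
    return out
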
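"""Replication experiments over the simulator and pipeline.

These drivers run the full chain — trajectory, beam scan, upward filter,
10-min binning, per-column normalization, phase labelling, Mann-Whitney
comparison — many times, so they work on the scanner's array output
directly instead of building timestamped DataFrames for every replicate.
Equivalence of this path with the timestamped pipeline is asserted in the
test suite.
"""

from __future__ import annotations

import numpy as np

from .activity import upward_mask
from .geometry import DetectorGeometry, ScanParams
from .light import LightRegime
from .simulate import AgentParams, scan_detectors, simulate_trajectory
from .stats import label_phases, mann_whitney_u

DEFAULT_PHOTOTAXIS_GAINS = (1.0, -1.0, 0.6, -0.6, 0.8, -0.8, 0.3, -0.3, 0.0)


def activity_bin_counts(
    agent: AgentParams,
    regime: LightRegime,
    days: int,
    seed_seq: np.random.SeedSequence,
    geometry: DetectorGeometry | None = None,
    scan: ScanParams | None = None,
    dt: float = 0.1,
    start_hour: float = 0.0,
    bin_minutes: int = 10,
) -> np.ndarray:
    """Upward-swimming counts per 10-min bin for one simulated individual."""
    geometry = geometry or DetectorGeometry()
    scan = scan or ScanParams()
    traj_seq, scan_seq = seed_seq.spawn(2)
    depth = simulate_trajectory(
        agent, regime, days * 86400.0, dt=dt, geometry=geometry,
        start_hour=start_hour, seed=traj_seq,
    )
    rec = scan_detectors(depth, geometry, scan, agent, dt=dt, seed=scan_seq)
    t_ms = rec["time_ms"].to_numpy()
    retained = upward_mask(rec["module"].to_numpy())
    bin_ms = bin_minutes * 60_000
    n_bins = int(days * 86400_000 // bin_ms)
    return np.bincount(t_ms[retained] // bin_ms, minlength=n_bins).astype(float)


def _normalize(counts: np.ndarray) -> np.ndarray:
    rng = counts.max() - counts.min()
    if rng <= 0:
        return counts * 0.0
    return (counts - counts.min()) / rng


def phase_labels(
    regime: LightRegime, days: int, start_hour: float = 0.0, bin_minutes: int = 10
):
    """(on, straddle) labels for a run of contiguous 10-min bins."""
    n_bins = int(days * 24 * 60 // bin_minutes)
    hours = (start_hour + np.arange(n_bins) * bin_minutes / 60.0) % 24.0
    return label_phases(hours, regime, bin_minutes=bin_minutes)


def group_phase_outcome(
    batch_seed_seq: np.random.SeedSequence,
    regime: LightRegime | None = None,
    n_individuals: int = 9,
    days: int = 5,
    dark_activity_gain: float = 3.0,
    phototaxis_gains=DEFAULT_PHOTOTAXIS_GAINS,
    bin_minutes: int = 10,
) -> tuple[float, int]:
    """One parameter-recovery batch: simulate a group, normalize each
    column's activity series, average across individuals and compare light
    phases.  Returns (two-sided p, direction) where direction +1 means more
    activity during lights-off."""
    regime = regime or LightRegime()
    children = batch_seed_seq.spawn(n_individuals)
    series = []
    for i in range(n_individuals):
        agent = AgentParams(
            phototaxis_gain=phototaxis_gains[i % len(phototaxis_gains)],
            dark_activity_gain=dark_activity_gain,
        )
        counts = activity_bin_counts(agent, regime, days, children[i],
                                     bin_minutes=bin_minutes)
        series.append(_normalize(counts))
    group_mean = np.vstack(series).mean(axis=0)
    on, straddle = phase_labels(regime, days, bin_minutes=bin_minutes)
    usable = ~straddle
    off_vals = group_mean[usable & ~on]
    on_vals = group_mean[usable & on]
    res = mann_whitney_u(off_vals, on_vals, mode="approx")
    direction = int(np.sign(np.median(off_vals) - np.median(on_vals)))
    return res.p_two_sided, direction


def group_recovery_rate(
    n_batches: int = 50,
    seed: int = 0,
    alpha: float = 0.05,
    **kwargs,
) -> float:
    """Fraction of simulated group experiments that detect the nocturnal
    activity increase (p < alpha with lights-off direction)."""
    root = np.random.SeedSequence([seed, 61])
    hits = 0
    for child in root.spawn(n_batches):
        p, direction = group_phase_outcome(child, **kwargs)
        if p < alpha and direction > 0:
            hits += 1
    return hits / n_batches


def null_rejection_rate(
    n_reps: int = 200,
    seed: int = 0,
    days: int = 5,
    alpha: float = 0.05,
    bin_minutes: int = 10,
) -> float:
    """Type-I calibration: per-individual phase comparison under the null
    (no nocturnal gain, no phototaxis); returns the rejection rate."""
    regime = LightRegime()
    agent = AgentParams(dark_activity_gain=1.0, phototaxis_gain=0.0)
    on, straddle = phase_labels(regime, days, bin_minutes=bin_minutes)
    usable = ~straddle
    root = np.random.SeedSequence([seed, 71])
    rejections = 0
    for child in root.spawn(n_reps):
        counts = _normalize(
            activity_bin_counts(agent, regime, days, child, bin_minutes=bin_minutes)
        )
        res = mann_whitney_u(counts[usable & ~on], counts[usable & on], mode="approx")
        if res.p_two_sided < alpha:
            rejections += 1
    return rejections / n_reps
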
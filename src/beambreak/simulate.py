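"""Agent-based swimmer in a vertical column and a virtual beam-barrier scanner.

The behavioural model is deliberately minimal: a negatively buoyant animal
sinks at a constant drift, jitters with Gaussian noise, is pulled toward the
surface (or pushed down) in proportion to the current light intensity, and
launches stochastic upward swimming bouts whose Poisson rate increases in
darkness.  Depth is one-dimensional (cm below the water surface) and clamped
to the water column; horizontal position is not modelled — the probability
that a vertically aligned body actually intersects an individual infrared
beam is collapsed into a single per-slot hit probability.

``scan_detectors`` converts a depth trajectory into detection records using
the monitor's scan timing: within each module one beam is lit at a time for
``slot_duration_ms``; modules scan concurrently.  Occlusion intervals (depth
within ``body_half_height`` of a module) are intersected analytically with
the slot grid, so the minimum-occlusion rule is applied exactly rather than
sampled, and each beam latches at most one detection per activation slot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernels import sample_runs, simulate_steps
from .geometry import DetectorGeometry, ScanParams
from .light import LightRegime

RECORD_COLUMNS = ["time_ms", "module", "beam"]


@dataclass(frozen=True)
class AgentParams:
    """Behavioural parameters of one simulated individual.

    Units: lengths cm, speeds cm s^-1, ``noise_sd`` cm s^-1/2 (random-walk
    scale), ``bout_rate_per_hour`` events h^-1.  ``phototaxis_gain`` is the
    upward swimming speed at peak irradiance in units of ``baseline_speed``
    (positive = surface-attracted, negative = depth-seeking).
    ``dark_activity_gain`` multiplies the upward-bout rate whenever the
    intensity is exactly zero; 1 means no nocturnal increase.
    ``beam_hit_prob`` is the per-slot probability that an occluding body
    actually intersects the active beam (horizontal beam-gap factor).
    """

    body_half_height: float = 2.5
    baseline_speed: float = 1.5
    sink_speed: float = 0.3
    noise_sd: float = 0.8
    phototaxis_gain: float = 0.0
    dark_activity_gain: float = 3.0
    beam_hit_prob: float = 0.15
    bout_rate_per_hour: float = 2.0
    bout_duration_s: float = 75.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("body_half_height", "baseline_speed", "sink_speed", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.beam_hit_prob <= 1.0):
            raise ValueError("beam_hit_prob must be in [0, 1]")
        if self.dark_activity_gain < 0:
            raise ValueError("dark_activity_gain must be >= 0")
        if self.bout_rate_per_hour < 0 or self.bout_duration_s <= 0:
            raise ValueError("bout rate must be >= 0 and bout duration > 0")


def _trajectory_seed(agent: AgentParams, seed) -> int:
    if seed is None:
        return int(np.random.SeedSequence(agent.seed).generate_state(1)[0])
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.generate_state(1)[0])
    return int(seed) % 2**32


def simulate_trajectory(
    agent: AgentParams,
    regime: LightRegime,
    duration_s: float,
    dt: float = 0.1,
    geometry: DetectorGeometry | None = None,
    start_hour: float = 0.0,
    start_depth: float | None = None,
    seed=None,
) -> np.ndarray:
    """Simulate a depth trajectory (cm below surface, one value per step).

    The per-step displacement combines sink drift, phototaxis proportional
    to the current light intensity, stochastic upward bouts (rate scaled by
    ``dark_activity_gain`` in darkness) and Gaussian noise; depth is clamped
    to [0, water_height].  Reproducible for a fixed seed, which may be an
    int or a ``numpy.random.SeedSequence`` (defaults to ``agent.seed``).
    """
    if dt <= 0 or duration_s <= 0:
        raise ValueError("dt and duration_s must be positive")
    if dt > 1.0:
        raise ValueError("dt must be <= 1 s to resolve the behavioural dynamics")
    n = int(round(duration_s / dt))
    if abs(n * dt - duration_s) > 1e-6 * max(1.0, duration_s):
        raise ValueError("duration_s must be a multiple of dt")
    geometry = geometry or DetectorGeometry()
    if start_depth is None:
        start_depth = geometry.water_height / 2.0

    base_rate = agent.bout_rate_per_hour / 3600.0
    dark_rate = base_rate * agent.dark_activity_gain
    if regime.peak_intensity > 0:
        rate_light = base_rate
        photo_speed = agent.phototaxis_gain * agent.baseline_speed
    else:  # constant darkness: dark rate everywhere, no light to steer by
        rate_light = dark_rate
        photo_speed = 0.0
    return simulate_steps(
        n,
        float(dt),
        float(start_depth),
        float(geometry.water_height),
        float(start_hour),
        float(regime.noon_hour),
        float(regime.photoperiod_h / 2.0),
        float(agent.sink_speed),
        float(agent.baseline_speed),
        float(photo_speed),
        float(rate_light),
        float(dark_rate),
        max(1, int(round(agent.bout_duration_s / dt))),
        float(agent.noise_sd * np.sqrt(dt)),
        _trajectory_seed(agent, seed),
    )


def scan_detectors(
    trajectory: np.ndarray,
    geometry: DetectorGeometry | None = None,
    scan: ScanParams | None = None,
    agent: AgentParams | None = None,
    dt: float = 0.1,
    seed=None,
    tie_order: str = "bottom-first",
) -> pd.DataFrame:
    """Convert a depth trajectory into beam-break records.

    The trajectory is piecewise-constant over steps of ``dt``; occlusion
    intervals (depth within ``body_half_height`` of a module) are
    intersected with the 10 ms slot grid analytically, a slot qualifying
    when the overlap reaches ``scan.min_occlusion_ms``.  Each qualifying
    slot yields at most one record, thinned by ``agent.beam_hit_prob``.

    Returns a DataFrame with columns ``time_ms`` (slot start, ms since
    trajectory start), ``module`` (1 = top) and ``beam``, chronologically
    sorted; simultaneous slots are ordered bottom-module-first by default so
    an ascending burst reads as upward movement.  ``seed`` (int or
    SeedSequence, default derived from ``agent.seed``) drives the thinning.
    """
    geometry = geometry or DetectorGeometry()
    scan = scan or ScanParams()
    agent = agent or AgentParams()
    depth = np.ascontiguousarray(trajectory, dtype=np.float64)
    empty = pd.DataFrame({c: pd.Series(dtype=np.int64) for c in RECORD_COLUMNS})
    if depth.size == 0:
        return empty
    if tie_order not in ("bottom-first", "top-first"):
        raise ValueError("tie_order must be 'bottom-first' or 'top-first'")
    if seed is None:
        seed = np.random.SeedSequence([agent.seed, 1])
    if isinstance(seed, np.random.SeedSequence):
        seed = int(seed.generate_state(1)[0])

    # occlusion runs per module: contiguous steps with the body overlapping
    # the detector plane (depth piecewise-constant over each dt step)
    dt_us = int(round(dt * 1e6))
    a_parts, b_parts, m_parts = [], [], []
    for m, depth_m in enumerate(geometry.module_depths, start=1):
        inband = np.abs(depth - depth_m) <= agent.body_half_height
        edges = np.diff(inband.view(np.int8))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1) + 1
        if inband[0]:
            starts = np.concatenate(([0], starts))
        if inband[-1]:
            ends = np.concatenate((ends, [depth.size]))
        if starts.size == 0:
            continue
        a_parts.append(starts.astype(np.int64) * dt_us)
        b_parts.append(ends.astype(np.int64) * dt_us)
        m_parts.append(np.full(starts.size, m, dtype=np.int64))
    if not a_parts:
        return empty
    t, mod, beam = sample_runs(
        np.concatenate(a_parts),
        np.concatenate(b_parts),
        np.concatenate(m_parts),
        int(round(scan.slot_duration_ms * 1000)),
        int(round(scan.min_occlusion_ms * 1000)),
        geometry.beams_per_module,
        float(agent.beam_hit_prob),
        int(seed) % 2**32,
    )
    if t.size == 0:
        return empty
    mod_key = -mod if tie_order == "bottom-first" else mod
    order = np.lexsort((beam, mod_key, t))
    return pd.DataFrame({"time_ms": t[order], "module": mod[order], "beam": beam[order]})


def count_upward_crossings(trajectory: np.ndarray, module_depths) -> int:
    """Number of upward passes of the trajectory through any module depth."""
    depth = np.asarray(trajectory, dtype=float)
    total = 0
    for md in module_depths:
        total += int(np.sum((depth[:-1] > md) & (depth[1:] <= md)))
    return total


def inject_dead_module(records: pd.DataFrame, module: int) -> pd.DataFrame:
    """Remove every detection of one module (emulates a failed detector)."""
    return records[records["module"] != module].reset_index(drop=True)


def inject_stuck_detector(
    records: pd.DataFrame,
    module: int,
    beam: int,
    duration_ms: int,
    geometry: DetectorGeometry | None = None,
    scan: ScanParams | None = None,
    start=None,
) -> pd.DataFrame:
    """Add a detection in every rotation of one beam (emulates a shorted
    receiver firing continuously).

    Works on both record schemas: raw scanner output (``time_ms``) and
    timestamped experiment records; ``start`` anchors the fault's clock for
    timestamped input (defaults to the first record).
    """
    geometry = geometry or DetectorGeometry()
    scan = scan or ScanParams()
    period = scan.rotation_period_ms(geometry.beams_per_module)
    t = np.arange(0, duration_ms, period, dtype=np.int64) + int(
        (beam - 1) * scan.slot_duration_ms
    )
    if "timestamp" in records.columns:
        if start is None:
            start = records["timestamp"].min() if len(records) else pd.Timestamp(0)
        extra = pd.DataFrame(
            {
                "timestamp": pd.Timestamp(start) + pd.to_timedelta(t, unit="ms"),
                "module": np.int64(module),
                "beam": np.int64(beam),
            }
        )
        if "column_id" in records.columns:
            extra["column_id"] = records["column_id"].iloc[0] if len(records) else "c??"
        merged = pd.concat([records, extra[records.columns]], ignore_index=True)
        merged = merged.sort_values(["timestamp", "module", "beam"], kind="mergesort")
        return merged.reset_index(drop=True)
    extra = pd.DataFrame(
        {"time_ms": t, "module": np.int64(module), "beam": np.int64(beam)}
    )
    merged = pd.concat([records[RECORD_COLUMNS], extra], ignore_index=True)
    merged = merged.sort_values(["time_ms", "module", "beam"], kind="mergesort")
    return merged.reset_index(drop=True)
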
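"""Numba kernels for the simulation inner loops.

The trajectory integration is inherently sequential (the clamp at the
surface and the floor couples each step to the previous one), so the whole
per-step update lives in one compiled pass; randomness comes from numba's
Mersenne Twister, seeded per call for reproducibility.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def clamped_cumsum(disp: np.ndarray, start: float, upper: float) -> np.ndarray:
    """Integrate per-step displacements, clamping to [0, upper]."""
    n = disp.shape[0]
    out = np.empty(n, dtype=np.float64)
    pos = start
    for i in range(n):
        pos += disp[i]
        if pos < 0.0:
            pos = 0.0
        elif pos > upper:
            pos = upper
        out[i] = pos
    return out


@njit(cache=True)
def sample_runs(
    a_us: np.ndarray,
    b_us: np.ndarray,
    run_module: np.ndarray,
    slot_us: int,
    min_us: int,
    beams: int,
    hit_prob: float,
    seed: int,
):
    """Occlusion intervals -> qualifying beam slots -> thinned detections.

    The qualifying slot range of an occlusion interval [a, b) is
    [ceil((a + min - slot)/slot), floor((b - min)/slot)] (overlap >= min,
    exactly).  Each qualifying slot survives independently with probability
    ``hit_prob`` (at most one detection per slot); survivors are drawn by
    geometric gap-sampling so the cost scales with detections, not
    candidate slots.  Returns (slot_start_ms, module, beam) in run order.
    """
    np.random.seed(seed)
    cap = 1024
    t_out = np.empty(cap, dtype=np.int64)
    m_out = np.empty(cap, dtype=np.int64)
    b_out = np.empty(cap, dtype=np.int64)
    cnt = 0
    take_all = hit_prob >= 1.0
    log_miss = 0.0 if take_all or hit_prob <= 0.0 else np.log(1.0 - hit_prob)
    for r in range(a_us.shape[0]):
        if hit_prob <= 0.0:
            break
        num = a_us[r] + min_us - slot_us
        js = -((-num) // slot_us)
        if js < 0:
            js = 0
        je = (b_us[r] - min_us) // slot_us
        m = run_module[r]
        j = js
        while j <= je:
            if not take_all:
                # gap to the next surviving slot ~ Geometric(hit_prob)
                u = np.random.random()
                j += np.int64(np.log(1.0 - u) / log_miss)
                if j > je:
                    break
            if cnt == cap:
                cap *= 2
                t_new = np.empty(cap, dtype=np.int64)
                m_new = np.empty(cap, dtype=np.int64)
                b_new = np.empty(cap, dtype=np.int64)
                t_new[:cnt] = t_out
                m_new[:cnt] = m_out
                b_new[:cnt] = b_out
                t_out, m_out, b_out = t_new, m_new, b_new
            t_out[cnt] = j * slot_us // 1000
            m_out[cnt] = m
            b_out[cnt] = j % beams + 1
            cnt += 1
            j += 1
    return t_out[:cnt], m_out[:cnt], b_out[:cnt]


@njit(cache=True)
def simulate_steps(
    n: int,
    dt: float,
    start_depth: float,
    water_height: float,
    start_hour: float,
    noon_hour: float,
    half_photoperiod: float,
    sink_speed: float,
    baseline_speed: float,
    photo_speed: float,
    rate_light: float,
    rate_dark: float,
    bout_steps: int,
    noise_step_sd: float,
    seed: int,
) -> np.ndarray:
    """One-pass depth simulation.

    Per step: light intensity fraction from the triangular regime; upward
    bout starts as Bernoulli(rate * dt) with the dark rate when intensity
    is zero; velocity = sink - baseline * bout_active - photo_speed *
    intensity_fraction; Gaussian noise on the displacement; clamp to the
    column.  Returns depth (cm below surface) at the end of each step.
    """
    np.random.seed(seed)
    out = np.empty(n, dtype=np.float64)
    pos = start_depth
    bout_left = 0
    dt_hours = dt / 3600.0
    for i in range(n):
        t = (start_hour + i * dt_hours) % 24.0
        x = (t - noon_hour + 12.0) % 24.0 - 12.0
        if x < 0.0:
            x = -x
        frac = 1.0 - x / half_photoperiod
        if frac < 0.0:
            frac = 0.0
        rate = rate_light if frac > 0.0 else rate_dark
        if np.random.random() < rate * dt:
            bout_left = bout_steps
        v = sink_speed - photo_speed * frac
        if bout_left > 0:
            v -= baseline_speed
            bout_left -= 1
        pos += v * dt + noise_step_sd * np.random.normal()
        if pos < 0.0:
            pos = 0.0
        elif pos > water_height:
            pos = water_height
        out[i] = pos
    return out
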
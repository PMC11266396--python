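"""Deterministic daily light regime: symmetric linear ramps around midday.

Intensity rises linearly from zero at lights-on to a peak at ``noon_hour``
and falls linearly back to zero at lights-off; outside the photoperiod it is
exactly zero.  Times are hours of the (local) day in [0, 24).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class LightRegime:
    """Triangular light-dark cycle.

    Parameters
    ----------
    photoperiod_h:
        Hours of light per 24 h day (support of the intensity function).
    peak_intensity:
        Irradiance at midday, mW m^-2.
    noon_hour:
        Time of day (hours) at which the peak occurs.
    """

    photoperiod_h: float = 15.5
    peak_intensity: float = 8.8
    noon_hour: float = 12.0

    def __post_init__(self) -> None:
        if not (0.0 < self.photoperiod_h <= 24.0):
            raise ValueError("photoperiod_h must be in (0, 24]")
        if self.peak_intensity < 0:
            raise ValueError("peak_intensity must be >= 0")

    @property
    def lights_on_hour(self) -> float:
        return (self.noon_hour - self.photoperiod_h / 2.0) % 24.0

    @property
    def lights_off_hour(self) -> float:
        return (self.noon_hour + self.photoperiod_h / 2.0) % 24.0


def light_intensity(regime: LightRegime, t_hours):
    """Irradiance (mW m^-2) at time-of-day ``t_hours`` (scalar or array).

    Piecewise linear and continuous; zero outside the photoperiod, peak at
    noon.  Total on valid input — no failure modes.
    """
    t = np.asarray(t_hours, dtype=float)
    # signed distance to noon, wrapped into [-12, 12)
    x = (t - regime.noon_hour + 12.0) % 24.0 - 12.0
    half = regime.photoperiod_h / 2.0
    out = regime.peak_intensity * np.maximum(0.0, 1.0 - np.abs(x) / half)
    if np.isscalar(t_hours):
        return float(out)
    return out


def is_light(regime: LightRegime, t_hours):
    """True where the lights are on (intensity strictly positive)."""
    inten = light_intensity(regime, t_hours)
    if isinstance(inten, float):
        return inten > 0.0
    return inten > 0.0
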
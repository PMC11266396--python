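"""Physical layout of an experimental column and beam-scan timing.

A column is a vertical acrylic tube filled with seawater; detector modules
(rings of paired infrared emitters/receivers) sit at fixed depths below the
water surface.  Module index 1 is the uppermost ring, index ``n_modules`` the
lowest.  The scan electronics activate one beam of a module at a time, in a
fixed rotation, so occlusions are only observable during the active slot of
the occluded beam.
"""

from __future__ import annotations

from dataclasses import dataclass, field


def _default_module_depths(
    water_height: float, n_modules: int, top_offset: float = 3.0, bottom_offset: float = 5.0
) -> tuple[float, ...]:
    """Equally spaced module depths from ``top_offset`` below the surface down
    to ``bottom_offset`` above the column floor."""
    if n_modules == 1:
        return (top_offset,)
    top = top_offset
    bottom = water_height - bottom_offset
    step = (bottom - top) / (n_modules - 1)
    return tuple(top + i * step for i in range(n_modules))


@dataclass(frozen=True)
class DetectorGeometry:
    """Column dimensions and detector-module placement (lengths in cm).

    Defaults describe a 75 cm water column with five modules of six beams,
    the top ring 3 cm below the surface (so surface swimmers still trigger
    it) and the bottom ring 5 cm above the floor (so a dead, settled animal
    triggers nothing).
    """

    water_height: float = 75.0
    inner_diameter: float = 9.0
    n_modules: int = 5
    beams_per_module: int = 6
    module_depths: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.water_height <= 0:
            raise ValueError("water_height must be positive")
        if self.n_modules < 1 or self.beams_per_module < 1:
            raise ValueError("n_modules and beams_per_module must be >= 1")
        if self.module_depths is None:
            object.__setattr__(
                self,
                "module_depths",
                _default_module_depths(self.water_height, self.n_modules),
            )
        depths = tuple(float(d) for d in self.module_depths)
        object.__setattr__(self, "module_depths", depths)
        if len(depths) != self.n_modules:
            raise ValueError("module_depths length must equal n_modules")
        if any(not (0.0 < d < self.water_height) for d in depths):
            raise ValueError("module depths must lie strictly inside the water column")
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise ValueError("module depths must be strictly increasing (1 = top)")

    @property
    def module_spacing(self) -> float:
        """Vertical distance between adjacent modules (uniform by default)."""
        if self.n_modules < 2:
            return 0.0
        return self.module_depths[1] - self.module_depths[0]


@dataclass(frozen=True)
class ScanParams:
    """Beam-scan timing: one beam active at a time within a module.

    ``slot_duration_ms`` is how long each beam is lit; a module with *b*
    beams completes one rotation every ``b * slot_duration_ms`` ms.  An
    occlusion registers only if it covers at least ``detect_fraction`` of an
    active slot.
    """

    slot_duration_ms: float = 10.0
    detect_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.slot_duration_ms <= 0:
            raise ValueError("slot_duration_ms must be positive")
        if not (0.0 < self.detect_fraction <= 1.0):
            raise ValueError("detect_fraction must be in (0, 1]")

    @property
    def min_occlusion_ms(self) -> float:
        """Shortest occlusion of an active slot that counts as a detection."""
        return self.slot_duration_ms * self.detect_fraction

    def rotation_period_ms(self, beams_per_module: int) -> float:
        return beams_per_module * self.slot_duration_ms

    def rotations_per_second(self, beams_per_module: int) -> float:
        return 1000.0 / self.rotation_period_ms(beams_per_module)
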
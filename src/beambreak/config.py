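"""Experiment configuration: column geometry, scan timing, light regime and
per-individual behavioural parameters, serialisable to a flat YAML file.

Timestamps in logfiles are UTC; the configuration carries the local-time
offset (the reference deployment ran at UTC-2) and the light regime is
expressed in local time of day, so analysis converts once and works in local
time throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .geometry import DetectorGeometry, ScanParams
from .light import LightRegime
from .simulate import AgentParams, scan_detectors, simulate_trajectory


@dataclass(frozen=True)
class Individual:
    column_id: str
    agent: AgentParams


@dataclass
class ExperimentConfig:
    """Everything needed to simulate and analyse one recording run."""

    geometry: DetectorGeometry = field(default_factory=DetectorGeometry)
    scan: ScanParams = field(default_factory=ScanParams)
    regime: LightRegime = field(default_factory=LightRegime)
    start_utc: pd.Timestamp = pd.Timestamp("2022-02-17 02:00:00")
    days: int = 5
    utc_offset_hours: float = -2.0
    dt: float = 0.1
    seed: int = 0
    individuals: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.start_utc = pd.Timestamp(self.start_utc)
        if self.days < 1:
            raise ValueError("days must be >= 1")

    @property
    def duration_s(self) -> float:
        return self.days * 86400.0

    @property
    def start_local(self) -> pd.Timestamp:
        return self.start_utc + pd.Timedelta(hours=self.utc_offset_hours)

    @property
    def end_local(self) -> pd.Timestamp:
        return self.start_local + pd.Timedelta(seconds=self.duration_s)

    def to_local(self, timestamps):
        """Convert UTC timestamps to experiment-local time."""
        return pd.DatetimeIndex(timestamps) + pd.Timedelta(hours=self.utc_offset_hours)

    @property
    def start_local_hour(self) -> float:
        t = self.start_local
        return t.hour + t.minute / 60.0 + t.second / 3600.0


def default_config(n_individuals: int = 10, days: int = 5, seed: int = 0) -> ExperimentConfig:
    """The reference study conditions: ~10 individuals recorded for 5 full
    days under a 15.5 h linear-ramp photoperiod peaking at 8.8 mW m^-2,
    with individual-specific phototaxis (alternating surface-attracted and
    depth-seeking animals of varying strength) and a threefold nocturnal
    increase in upward-bout rate."""
    gains = [1.0, -1.0, 0.6, -0.6, 0.8, -0.8, 0.3, -0.3, 0.0, 0.45]
    individuals = []
    for i in range(n_individuals):
        individuals.append(
            Individual(
                column_id=f"c{i + 1:02d}",
                agent=AgentParams(
                    phototaxis_gain=gains[i % len(gains)],
                    dark_activity_gain=3.0,
                    seed=seed * 1000 + i,
                ),
            )
        )
    return ExperimentConfig(days=days, seed=seed, individuals=individuals)


def simulate_column(config: ExperimentConfig, individual: Individual) -> pd.DataFrame:
    """Simulate one individual's full recording.

    Returns detections with columns ``timestamp`` (UTC, ms precision),
    ``column_id``, ``module``, ``beam``; deterministic in (config, agent
    seed)."""
    traj_seq, scan_seq = np.random.SeedSequence(
        [config.seed, individual.agent.seed]
    ).spawn(2)
    depth = simulate_trajectory(
        individual.agent,
        config.regime,
        config.duration_s,
        dt=config.dt,
        geometry=config.geometry,
        start_hour=config.start_local_hour,
        seed=traj_seq,
    )
    rec = scan_detectors(
        depth,
        config.geometry,
        config.scan,
        individual.agent,
        dt=config.dt,
        seed=scan_seq,
    )
    out = pd.DataFrame(
        {
            "timestamp": config.start_utc + pd.to_timedelta(rec["time_ms"], unit="ms"),
            "column_id": individual.column_id,
            "module": rec["module"].astype(np.int64),
            "beam": rec["beam"].astype(np.int64),
        }
    )
    return out


def simulate_experiment(config: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Simulate every configured column; returns {column_id: records}."""
    return {ind.column_id: simulate_column(config, ind) for ind in config.individuals}


def sensor_frame(config: ExperimentConfig, every_min: int = 5) -> pd.DataFrame:
    """Periodic housekeeping rows (temperature / ambient light / humidity)
    as a logger would interleave them; deterministic."""
    from .light import light_intensity

    t = pd.date_range(
        config.start_utc,
        config.start_utc + pd.Timedelta(seconds=config.duration_s),
        freq=f"{every_min}min",
        inclusive="left",
    )
    local_hours = (
        (t + pd.Timedelta(hours=config.utc_offset_hours)) - t.normalize()
    ).total_seconds() / 3600.0 % 24.0
    return pd.DataFrame(
        {
            "timestamp": t,
            "temperature": 0.8,
            "light": np.round(light_intensity(config.regime, local_hours), 3),
            "humidity": 30.0,
        }
    )


# --- YAML round trip ------------------------------------------------------


def config_to_dict(config: ExperimentConfig) -> dict:
    return {
        "geometry": {
            "water_height": config.geometry.water_height,
            "inner_diameter": config.geometry.inner_diameter,
            "n_modules": config.geometry.n_modules,
            "beams_per_module": config.geometry.beams_per_module,
            "module_depths": list(config.geometry.module_depths),
        },
        "scan": asdict(config.scan),
        "light": asdict(config.regime),
        "start_utc": config.start_utc.isoformat(),
        "days": config.days,
        "utc_offset_hours": config.utc_offset_hours,
        "dt": config.dt,
        "seed": config.seed,
        "individuals": [
            {"column_id": ind.column_id, **asdict(ind.agent)}
            for ind in config.individuals
        ],
    }


def config_from_dict(d: dict) -> ExperimentConfig:
    geo = d.get("geometry", {})
    if "module_depths" in geo:
        geo = dict(geo, module_depths=tuple(geo["module_depths"]))
    individuals = [
        Individual(
            column_id=e["column_id"],
            agent=AgentParams(**{k: v for k, v in e.items() if k != "column_id"}),
        )
        for e in d.get("individuals", [])
    ]
    return ExperimentConfig(
        geometry=DetectorGeometry(**geo),
        scan=ScanParams(**d.get("scan", {})),
        regime=LightRegime(**d.get("light", {})),
        start_utc=pd.Timestamp(d.get("start_utc", "2022-02-17 02:00:00")),
        days=int(d.get("days", 5)),
        utc_offset_hours=float(d.get("utc_offset_hours", -2.0)),
        dt=float(d.get("dt", 0.1)),
        seed=int(d.get("seed", 0)),
        individuals=individuals,
    )


def save_config(config: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
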
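"""Beam-break logfile format.

One append-only delimiter-separated text file per column, mirroring a
single-board logger.  A mandatory header line is followed by one row per
record; the first field distinguishes detections (``D``) from interleaved
sensor housekeeping rows (``S``).  Timestamps are ISO-8601 UTC with
millisecond precision (``2022-02-17T02:00:00.120Z``).  The real instrument's
schema is not public; this format is a synthetic stand-in with the same
information content.

Detection rows populate module/beam and leave the sensor fields empty;
sensor rows do the opposite.  ``read_log`` validates the header, parses
locale-independently and checks module/beam indices against the geometry.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .geometry import DetectorGeometry

HEADER = "record,timestamp,column_id,module,beam,temperature,light,humidity"
_TS_FORMAT = "%Y-%m-%dT%H:%M:%S.%f"


class BeamBreakRecord(NamedTuple):
    """One timestamped detection at (column, module, beam)."""

    timestamp: pd.Timestamp
    column_id: str
    module: int
    beam: int


class LogParseError(ValueError):
    """Malformed logfile; message names the offending line."""


def write_log(records: pd.DataFrame, path, sensors: pd.DataFrame | None = None) -> None:
    """Write detections (and optional sensor rows) to a logfile.

    ``records`` needs columns timestamp/column_id/module/beam and must be
    chronologically sorted; sensor rows are merged in timestamp order.
    """
    ts = pd.DatetimeIndex(records["timestamp"])
    if len(ts) > 1 and (np.diff(ts.asi8) < 0).any():
        raise ValueError("records must be sorted by timestamp")
    ts_str = pd.Series(ts.strftime(_TS_FORMAT), dtype="string").str[:-3] + "Z"
    det_lines = (
        "D," + ts_str + "," + pd.Series(records["column_id"].to_numpy(), dtype="string")
        + "," + records["module"].astype(str).to_numpy() + ","
        + records["beam"].astype(str).to_numpy() + ",,,"
    )
    keys = [ts.asi8]
    lines = [det_lines.to_numpy(dtype=object)]
    if sensors is not None:
        col = records["column_id"].iloc[0] if len(records) else str(
            sensors["column_id"].iloc[0] if "column_id" in sensors else "?"
        )
        sts = pd.DatetimeIndex(sensors["timestamp"])
        sts_str = pd.Series(sts.strftime(_TS_FORMAT), dtype="string").str[:-3] + "Z"
        sen_lines = (
            "S," + sts_str + f",{col},,,"
            + sensors["temperature"].astype(str).to_numpy() + ","
            + sensors["light"].astype(str).to_numpy() + ","
            + sensors["humidity"].astype(str).to_numpy()
        )
        keys.append(sts.asi8)
        lines.append(sen_lines.to_numpy(dtype=object))
    all_keys = np.concatenate(keys)
    all_lines = np.concatenate(lines)
    order = np.argsort(all_keys, kind="stable")
    with open(path, "w", newline="\n") as fh:
        fh.write(HEADER + "\n")
        if len(all_lines):
            fh.write("\n".join(all_lines[order]) + "\n")


def read_log(
    path, geometry: DetectorGeometry | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse a logfile back into (detections, sensor rows).

    Round-trips ``write_log`` exactly.  Raises :class:`LogParseError` naming
    the line number for malformed rows and out-of-range module/beam indices.
    """
    geometry = geometry or DetectorGeometry()
    det_rows: list[tuple] = []
    sen_rows: list[tuple] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != HEADER:
            raise LogParseError(f"{path}: line 1: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 8:
                raise LogParseError(
                    f"{path}: line {lineno}: expected 8 fields, got {len(parts)}"
                )
            kind, ts_s, col, mod_s, beam_s, temp_s, light_s, hum_s = parts
            try:
                if not ts_s.endswith("Z"):
                    raise ValueError("timestamp must end in Z")
                ts = pd.Timestamp(ts_s[:-1])
            except ValueError as exc:
                raise LogParseError(f"{path}: line {lineno}: bad timestamp: {exc}") from exc
            if kind == "D":
                try:
                    mod, beam = int(mod_s), int(beam_s)
                except ValueError as exc:
                    raise LogParseError(
                        f"{path}: line {lineno}: bad module/beam index"
                    ) from exc
                if not (1 <= mod <= geometry.n_modules):
                    raise LogParseError(
                        f"{path}: line {lineno}: module {mod} outside "
                        f"1..{geometry.n_modules}"
                    )
                if not (1 <= beam <= geometry.beams_per_module):
                    raise LogParseError(
                        f"{path}: line {lineno}: beam {beam} outside "
                        f"1..{geometry.beams_per_module}"
                    )
                det_rows.append((ts, col, mod, beam))
            elif kind == "S":
                try:
                    sen_rows.append(
                        (ts, col, float(temp_s), float(light_s), float(hum_s))
                    )
                except ValueError as exc:
                    raise LogParseError(
                        f"{path}: line {lineno}: bad sensor value"
                    ) from exc
            else:
                raise LogParseError(
                    f"{path}: line {lineno}: unknown record type {kind!r}"
                )
    detections = pd.DataFrame(
        det_rows, columns=["timestamp", "column_id", "module", "beam"]
    )
    if len(detections) == 0:
        detections = detections.astype(
            {"timestamp": "datetime64[ns]", "module": np.int64, "beam": np.int64}
        )
    sensors = pd.DataFrame(
        sen_rows, columns=["timestamp", "column_id", "temperature", "light", "humidity"]
    )
    return detections, sensors


def records_to_tuples(records: pd.DataFrame) -> list[BeamBreakRecord]:
    """DataFrame rows as atomic :class:`BeamBreakRecord` tuples."""
    return [
        BeamBreakRecord(pd.Timestamp(t), str(c), int(m), int(b))
        for t, c, m, b in zip(
            records["timestamp"], records["column_id"], records["module"], records["beam"]
        )
    ]
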
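"""Sensor time-series containers and the canonical delimited-text trace format.

A trace file is UTF-8, comma-delimited: ``#``-prefixed ``key: value`` header
lines carrying channel and experiment metadata, then a ``time_s,value`` column
header and one sample per row.  Times are seconds elapsed since the start of
the recording (all downstream quantities are elapsed-time based, so wall-clock
stamps are never stored).  Potentiostat vendors disagree on export formats and
sampling is not assumed uniform, hence explicit per-sample timestamps.
"""

from __future__ import annotations

import dataclasses
import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

__all__ = [
    "CHANNEL_UNITS",
    "TimeSeries",
    "ExperimentRecord",
    "TraceParseError",
    "TraceValidationError",
    "read_trace",
    "write_trace",
]

#: Channel kind -> canonical unit.  A series never mixes units.
CHANNEL_UNITS = {
    "impedance": "ohm",
    "ph_potential": "volt",
    "h2o2_current": "ampere",
    "concentration": "mol/L",
    "ph": "pH",
    "h2o2_concentration": "mol/L",
}

#: Fixed float formatting used by the writer so identical records produce
#: byte-identical files.
_FLOAT_FMT = "%.12g"


class TraceParseError(ValueError):
    """A trace file violated the dialect (malformed row, bad timestamps...)."""

    def __init__(self, message: str, line_no: Optional[int] = None):
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)
        self.line_no = line_no


class TraceValidationError(ValueError):
    """A record or header violated an invariant (missing unit, bad metadata)."""


@dataclass(frozen=True)
class TimeSeries:
    """One sensor channel: (time, value) samples plus the channel kind.

    ``times`` are seconds from the start of recording, non-negative and
    strictly increasing; ``values`` share the channel's unit throughout.
    """

    times: np.ndarray
    values: np.ndarray
    channel_kind: str

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1:
            raise TraceValidationError("times and values must be 1-D")
        if len(times) != len(values):
            raise TraceValidationError(
                f"times ({len(times)}) and values ({len(values)}) differ in length"
            )
        if len(times) == 0:
            raise TraceValidationError("empty series")
        if times[0] < 0:
            raise TraceValidationError("times must be non-negative")
        if np.any(np.diff(times) <= 0):
            raise TraceValidationError("times must be strictly increasing")
        if self.channel_kind not in CHANNEL_UNITS:
            raise TraceValidationError(
                f"unknown channel_kind {self.channel_kind!r}; "
                f"expected one of {sorted(CHANNEL_UNITS)}"
            )

    @property
    def unit(self) -> str:
        return CHANNEL_UNITS[self.channel_kind]

    def __len__(self) -> int:
        return len(self.times)

    @property
    def t_start(self) -> float:
        return float(self.times[0])

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def with_values(self, values, channel_kind: Optional[str] = None) -> "TimeSeries":
        """Same time base, new values (and optionally a new channel kind)."""
        return TimeSeries(self.times, values, channel_kind or self.channel_kind)

    def equals(self, other: "TimeSeries", rtol: float = 0.0, atol: float = 0.0) -> bool:
        return (
            self.channel_kind == other.channel_kind
            and len(self) == len(other)
            and np.allclose(self.times, other.times, rtol=rtol, atol=atol)
            and np.allclose(self.values, other.values, rtol=rtol, atol=atol)
        )


@dataclass(frozen=True)
class ExperimentRecord:
    """A single uptake experiment: one trace plus its design metadata.

    ``addition_time`` is the elapsed time at which salt solution was pipetted
    onto the substrate; runs without an addition leave it ``None``.  Plant-free
    control runs (``is_control``) carry ``n_plants = 0``.
    """

    trace: TimeSeries
    salt_name: str
    addition_time: Optional[float] = None
    addition_volume_ul: Optional[float] = None
    addition_concentration: Optional[float] = None
    is_control: bool = False
    n_plants: int = 0
    plant_age_days: Optional[int] = None

    def __post_init__(self):
        if self.addition_time is not None:
            t = float(self.addition_time)
            if not (self.trace.t_start <= t <= self.trace.t_end):
                raise TraceValidationError(
                    f"addition_time {t} s outside trace span "
                    f"[{self.trace.t_start}, {self.trace.t_end}] s"
                )
            object.__setattr__(self, "addition_time", t)
        if self.is_control and self.n_plants != 0:
            raise TraceValidationError("is_control=True requires n_plants=0")
        if self.n_plants < 0:
            raise TraceValidationError("n_plants must be >= 0")


# ---------------------------------------------------------------------------
# Reading / writing

_META_KEYS = (
    "salt_name",
    "addition_time_s",
    "addition_volume_ul",
    "addition_concentration_mol_per_l",
    "is_control",
    "n_plants",
    "plant_age_days",
)


def write_trace(record: ExperimentRecord, path: Union[str, Path]) -> Path:
    """Write ``record`` in the canonical dialect; byte-stable for fixed input."""
    path = Path(path)
    buf = io.StringIO()
    ts = record.trace
    buf.write(f"# channel_kind: {ts.channel_kind}\n")
    buf.write(f"# unit: {ts.unit}\n")
    buf.write(f"# salt_name: {record.salt_name}\n")
    if record.addition_time is not None:
        buf.write(f"# addition_time_s: {_FLOAT_FMT % record.addition_time}\n")
    if record.addition_volume_ul is not None:
        buf.write(f"# addition_volume_ul: {_FLOAT_FMT % record.addition_volume_ul}\n")
    if record.addition_concentration is not None:
        buf.write(
            "# addition_concentration_mol_per_l: "
            f"{_FLOAT_FMT % record.addition_concentration}\n"
        )
    buf.write(f"# is_control: {'true' if record.is_control else 'false'}\n")
    buf.write(f"# n_plants: {record.n_plants}\n")
    if record.plant_age_days is not None:
        buf.write(f"# plant_age_days: {record.plant_age_days}\n")
    buf.write("time_s,value\n")
    for t, v in zip(ts.times, ts.values):
        buf.write(f"{_FLOAT_FMT % t},{_FLOAT_FMT % v}\n")
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def read_trace(path: Union[str, Path]) -> ExperimentRecord:
    """Parse a canonical trace file into a validated :class:`ExperimentRecord`.

    Raises :class:`TraceParseError` (with the offending line number) on
    malformed rows or non-monotone/duplicated timestamps, and
    :class:`TraceValidationError` when the header is missing the channel kind
    or unit or the metadata violates a record invariant.  Samples are never
    silently reordered.
    """
    path = Path(path)
    meta: dict = {}
    times: list = []
    values: list = []
    channel_kind = None
    unit = None
    saw_column_header = False
    with path.open("r", encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" not in body:
                    raise TraceParseError(f"malformed header {body!r}", line_no)
                key, _, val = body.partition(":")
                key, val = key.strip(), val.strip()
                if key == "channel_kind":
                    channel_kind = val
                elif key == "unit":
                    unit = val
                else:
                    meta[key] = val
                continue
            if not saw_column_header:
                if line != "time_s,value":
                    raise TraceParseError(
                        f"expected column header 'time_s,value', got {line!r}", line_no
                    )
                saw_column_header = True
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise TraceParseError(f"expected 2 fields, got {len(parts)}", line_no)
            try:
                t, v = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise TraceParseError(f"non-numeric sample {line!r}", line_no) from exc
            if not (math.isfinite(t) and math.isfinite(v)):
                raise TraceParseError(f"non-finite sample {line!r}", line_no)
            if times:
                if t == times[-1]:
                    raise TraceParseError(f"duplicated timestamp {t}", line_no)
                if t < times[-1]:
                    raise TraceParseError(
                        f"non-monotone timestamp {t} after {times[-1]}", line_no
                    )
            times.append(t)
            values.append(v)

    if channel_kind is None:
        raise TraceValidationError(f"{path}: header missing channel_kind")
    if unit is None:
        raise TraceValidationError(f"{path}: header missing unit")
    expected_unit = CHANNEL_UNITS.get(channel_kind)
    if expected_unit is None:
        raise TraceValidationError(f"{path}: unknown channel_kind {channel_kind!r}")
    if unit != expected_unit:
        raise TraceValidationError(
            f"{path}: unit {unit!r} inconsistent with channel_kind "
            f"{channel_kind!r} (expected {expected_unit!r})"
        )
    if not times:
        raise TraceParseError("no samples found")

    ts = TimeSeries(np.array(times), np.array(values), channel_kind)

    def _opt_float(key):
        return float(meta[key]) if key in meta else None

    def _opt_int(key):
        return int(meta[key]) if key in meta else None

    return ExperimentRecord(
        trace=ts,
        salt_name=meta.get("salt_name", ""),
        addition_time=_opt_float("addition_time_s"),
        addition_volume_ul=_opt_float("addition_volume_ul"),
        addition_concentration=_opt_float("addition_concentration_mol_per_l"),
        is_control=meta.get("is_control", "false").lower() == "true",
        n_plants=_opt_int("n_plants") or 0,
        plant_age_days=_opt_int("plant_age_days"),
    )


def records_equal(a: ExperimentRecord, b: ExperimentRecord) -> bool:
    """Field-level equality; floats compared to the writer's precision."""
    for f in dataclasses.fields(ExperimentRecord):
        if f.name == "trace":
            continue
        va, vb = getattr(a, f.name), getattr(b, f.name)
        if isinstance(va, float) and isinstance(vb, float):
            if not math.isclose(va, vb, rel_tol=1e-11, abs_tol=1e-300):
                return False
        elif va != vb:
            return False
    return a.trace.equals(b.trace, rtol=1e-11)
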
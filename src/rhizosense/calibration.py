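"""Sensor calibration models and their inversions.

The salt-concentration sensor is a nonspecific impedance cell read at a fixed
2 kHz excitation: over its linear range, log10 of the impedance magnitude Z is
an affine function of log10 of the salt concentration c, with a negative slope
for conductive salts (more ions, lower impedance).  Each salt gets its own
line, fitted by ordinary least squares on (log10 c, log10 Z).  The pH channel
(open-circuit potential of a polyaniline electrode) and the H2O2 channel
(amperometric current on a Prussian-blue mediated electrode) are plain linear
sensors: output = gain * input + offset.

The fit is run on whatever points the caller supplies; restricting to the
linear range is the caller's job (point selection), not an automatic
breakpoint search.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .trace_io import TimeSeries

__all__ = [
    "CalibrationCurve",
    "LinearSensorCal",
    "CalibrationError",
    "fit_impedance_calibration",
    "impedance_from_concentration",
    "concentration_from_impedance",
    "convert_trace",
    "ph_from_potential",
    "h2o2_from_current",
    "save_calibration_table",
    "load_calibration_table",
]


class CalibrationError(ValueError):
    """Invalid calibration inputs (non-positive data, singular fit, zero gain)."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Per-salt log-log line: log10 Z = intercept + slope * log10 c.

    ``intercept`` is log10(ohm) at c = 1 mol/L; ``valid_c_range`` is the
    concentration span of the fitted points, outside which inversion flags
    extrapolation.
    """

    salt_name: str
    slope: float
    intercept: float
    c_min: float
    c_max: float
    fit_r2: float = float("nan")
    n_points: int = 0

    def __post_init__(self):
        if not np.isfinite(self.slope):
            raise CalibrationError("slope must be finite")
        if not (0 < self.c_min < self.c_max):
            raise CalibrationError("require 0 < c_min < c_max")


@dataclass(frozen=True)
class LinearSensorCal:
    """Linear sensor: output = gain * input + offset.

    For the pH channel the input is pH and the output electrode potential in
    volts (gain in V per pH unit, near-Nernstian ~ -0.059 V/pH); for the H2O2
    channel the input is concentration in mol/L and the output current in
    amperes.  ``valid_input_range`` bounds the characterized input span.
    """

    gain: float
    offset: float
    valid_input_range: Optional[Tuple[float, float]] = None

    def __post_init__(self):
        if self.gain == 0:
            raise CalibrationError("gain must be nonzero")


def fit_impedance_calibration(
    points: Iterable[Tuple[float, float]], salt_name: str
) -> CalibrationCurve:
    """OLS fit of log10 Z against log10 c for one salt.

    ``points`` are (concentration mol/L, impedance ohm) pairs, all strictly
    positive, at least two, spanning at least two distinct concentrations.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise CalibrationError("need >= 2 (c, Z) points")
    c, z = pts[:, 0], pts[:, 1]
    if np.any(c <= 0) or np.any(z <= 0):
        raise CalibrationError("all concentrations and impedances must be > 0")
    if np.all(c == c[0]):
        raise CalibrationError("all concentrations identical: singular fit")
    x, y = np.log10(c), np.log10(z)
    res = stats.linregress(x, y)
    # Two points define the line exactly; linregress reports r = nan there
    # when residuals vanish on some platforms, so pin r2 for exact fits.
    r2 = float(res.rvalue**2)
    if len(x) == 2:
        r2 = 1.0
    return CalibrationCurve(
        salt_name=salt_name,
        slope=float(res.slope),
        intercept=float(res.intercept),
        c_min=float(c.min()),
        c_max=float(c.max()),
        fit_r2=r2,
        n_points=len(x),
    )


def impedance_from_concentration(curve: CalibrationCurve, c) -> np.ndarray:
    """Forward map c -> Z (ohm).  Accepts scalars or arrays."""
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise CalibrationError("concentration must be > 0")
    return 10.0 ** (curve.intercept + curve.slope * np.log10(c))


def concentration_from_impedance(curve: CalibrationCurve, z):
    """Invert the log-log line: Z -> (c, extrapolation_flag).

    c = 10**((log10 Z - intercept) / slope).  The flag is True wherever the
    recovered concentration falls outside the curve's fitted range; the value
    is still returned.
    """
    if curve.slope == 0:
        raise CalibrationError("slope is zero: cannot invert")
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr <= 0):
        raise CalibrationError("impedance must be > 0")
    c = 10.0 ** ((np.log10(z_arr) - curve.intercept) / curve.slope)
    flag = (c < curve.c_min) | (c > curve.c_max)
    if np.isscalar(z) or z_arr.ndim == 0:
        return float(c), bool(flag)
    return c, flag


def convert_trace(series: TimeSeries, curve: CalibrationCurve) -> Tuple[TimeSeries, np.ndarray]:
    """Convert an impedance trace to concentration; returns (series, flags)."""
    if series.channel_kind != "impedance":
        raise CalibrationError(
            f"expected an impedance series, got {series.channel_kind!r}"
        )
    c, flags = concentration_from_impedance(curve, series.values)
    return series.with_values(c, channel_kind="concentration"), flags


def _invert_linear(cal: LinearSensorCal, output: float) -> Tuple[float, bool]:
    value = (float(output) - cal.offset) / cal.gain
    in_range = True
    if cal.valid_input_range is not None:
        lo, hi = cal.valid_input_range
        in_range = lo <= value <= hi
    return value, not in_range


def ph_from_potential(cal: LinearSensorCal, potential_v: float) -> Tuple[float, bool]:
    """pH = (E - offset)/gain; second element flags an out-of-range result."""
    return _invert_linear(cal, potential_v)


def h2o2_from_current(cal: LinearSensorCal, current_a: float) -> Tuple[float, bool]:
    """H2O2 concentration (mol/L) = (I - offset)/gain, with range flag."""
    return _invert_linear(cal, current_a)


# ---------------------------------------------------------------------------
# Persistence: one row per salt, plain CSV.

_TABLE_COLS = ["salt_name", "slope", "intercept", "c_min", "c_max", "r2", "n_points"]


def save_calibration_table(
    curves: Sequence[CalibrationCurve], path: Union[str, Path]
) -> Path:
    path = Path(path)
    rows = [
        {
            "salt_name": cv.salt_name,
            "slope": cv.slope,
            "intercept": cv.intercept,
            "c_min": cv.c_min,
            "c_max": cv.c_max,
            "r2": cv.fit_r2,
            "n_points": cv.n_points,
        }
        for cv in curves
    ]
    pd.DataFrame(rows, columns=_TABLE_COLS).to_csv(path, index=False, float_format="%.12g")
    return path


def load_calibration_table(path: Union[str, Path]) -> dict:
    """Load a calibration table as a dict keyed by exact salt name."""
    df = pd.read_csv(path)
    missing = set(_TABLE_COLS) - set(df.columns)
    if missing:
        raise CalibrationError(f"calibration table missing columns: {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        out[str(row["salt_name"])] = CalibrationCurve(
            salt_name=str(row["salt_name"]),
            slope=float(row["slope"]),
            intercept=float(row["intercept"]),
            c_min=float(row["c_min"]),
            c_max=float(row["c_max"]),
            fit_r2=float(row["r2"]),
            n_points=int(row["n_points"]),
        )
    return out
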
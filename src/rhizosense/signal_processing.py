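"""Smoothing, baseline estimation and post-addition peak detection.

Traces are smoothed with a rolling percentile filter (the 50th percentile is
a rolling median), counted in samples, centered, with truncated windows at
the series edges so the output keeps the input's length and time base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .trace_io import TimeSeries

__all__ = [
    "SmoothingSpec",
    "SignalError",
    "percentile_filter",
    "estimate_baseline",
    "find_post_addition_peak",
]


class SignalError(ValueError):
    pass


@dataclass(frozen=True)
class SmoothingSpec:
    """Rolling percentile filter parameters: percentile in (0, 100), window in samples."""

    percentile: float = 50.0
    window_points: int = 30

    def __post_init__(self):
        if not (0 < self.percentile < 100):
            raise SignalError("percentile must be in (0, 100)")
        if int(self.window_points) != self.window_points or self.window_points < 1:
            raise SignalError("window_points must be a positive integer")


def percentile_filter(series: TimeSeries, spec: SmoothingSpec) -> TimeSeries:
    """Centered rolling percentile; edge windows shrink (truncate) to the series.

    At index i with window w the window covers indices
    [i - (w-1)//2, i + w//2] clipped to the series; for odd w this is the
    usual symmetric window.  Output has the same times and length as input.
    """
    v = series.values
    n = len(v)
    w = int(spec.window_points)
    left, right = (w - 1) // 2, w // 2
    if w >= 2 * n:  # every window is the whole series
        out = np.full(n, np.percentile(v, spec.percentile))
        return series.with_values(out)
    out = np.empty(n)
    interior_lo, interior_hi = left, n - 1 - right
    if interior_lo <= interior_hi and w <= n:
        windows = np.lib.stride_tricks.sliding_window_view(v, w)
        out[interior_lo : interior_hi + 1] = np.percentile(windows, spec.percentile, axis=1)
    for i in range(min(interior_lo, n)):
        out[i] = np.percentile(v[max(0, i - left) : i + right + 1], spec.percentile)
    for i in range(max(interior_hi + 1, 0), n):
        out[i] = np.percentile(v[max(0, i - left) : min(n, i + right + 1)], spec.percentile)
    return series.with_values(out)


def estimate_baseline(conc: TimeSeries, window_hours: float = 2.0) -> float:
    """Mean concentration over the first ``window_hours`` of recording.

    The pre-addition baseline is the arithmetic mean of all samples with
    t < window_hours * 3600 s.  A trace shorter than the window is an error;
    the window is never silently shortened.
    """
    if window_hours <= 0:
        raise SignalError("window_hours must be > 0")
    horizon = window_hours * 3600.0
    if conc.t_end < horizon:
        raise SignalError(
            f"trace spans {conc.t_end:.0f} s < baseline window {horizon:.0f} s"
        )
    mask = conc.times < horizon
    if not mask.any():
        raise SignalError("no samples inside the baseline window")
    return float(conc.values[mask].mean())


def find_post_addition_peak(
    conc: TimeSeries, t_add: float, baseline: float
) -> Optional[Tuple[float, float]]:
    """Locate the concentration maximum at t >= t_add.

    Returns (t_peak, c_peak); ties are broken toward the earliest time.
    Returns ``None`` ("no peak") when the post-addition series never exceeds
    the pre-addition baseline — the degenerate case that downstream maps to
    zero uptake.
    """
    if t_add > conc.t_end:
        raise SignalError(f"t_add {t_add} s beyond trace end {conc.t_end} s")
    mask = conc.times >= t_add
    if not mask.any():
        raise SignalError("no samples at or after t_add")
    t_post = conc.times[mask]
    c_post = conc.values[mask]
    i = int(np.argmax(c_post))  # argmax returns the first maximum
    if c_post[i] <= baseline:
        return None
    return float(t_post[i]), float(c_post[i])
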
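"""Power-law ion-uptake estimation from concentration traces.

After a salt addition the measured concentration steps up and then decays
back toward the pre-addition baseline as the roots take the ions up.  The
decay is summarized by fitting c = B * tau^k between the post-addition
concentration maximum and the point where the trace first meets the initial
baseline within a relative tolerance (default 5 %); if it never does, the fit
runs to the end of the recording.  k ("k_uptake", dimensionless, negative for
decay) is the collective uptake-rate proxy.  Plant-free control runs are
processed with the identical pipeline; their exponent k_control captures
sensor drift and evaporation, and the normalized rate of uptake is
k_uptake / mean(k_control).  Values at or below 1 indicate net zero or
negative uptake.

Time origin: c = B*t^k is origin-sensitive and the addition instant is the
only physically distinguished time, so tau = t - t_add by default
(configurable to the peak time).  The fit is OLS on
(log10 tau, log10 c) by default; a nonlinear least-squares option in linear
space is available through the config.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .calibration import CalibrationCurve, convert_trace
from .config import RunConfig
from .signal_processing import (
    estimate_baseline,
    find_post_addition_peak,
    percentile_filter,
)
from .trace_io import ExperimentRecord, TimeSeries, read_trace

__all__ = [
    "UptakeResult",
    "NormalizedUptake",
    "UptakeError",
    "find_fit_window",
    "fit_power_law",
    "compute_uptake",
    "normalize_uptake",
    "run_batch",
]


class UptakeError(ValueError):
    pass


@dataclass(frozen=True)
class UptakeResult:
    """Fitted decay for one experiment; ``zero_uptake`` implies k_uptake = 0."""

    B: float
    k_uptake: float
    t_fit_start: Optional[float]
    t_fit_end: Optional[float]
    baseline: float
    reached_baseline: bool
    zero_uptake: bool
    r2: float = float("nan")
    n_fit: int = 0

    def __post_init__(self):
        if self.zero_uptake and self.k_uptake != 0:
            raise UptakeError("zero_uptake requires k_uptake = 0")
        if (
            self.t_fit_start is not None
            and self.t_fit_end is not None
            and not self.t_fit_start < self.t_fit_end
        ):
            raise UptakeError("fit window must satisfy t_fit_start < t_fit_end")


@dataclass(frozen=True)
class NormalizedUptake:
    """k_uptake divided by the mean control exponent."""

    ratio: float
    k_control_mean: float
    n_controls: int
    undefined: bool = False

    def __post_init__(self):
        if self.n_controls < 1:
            raise UptakeError("n_controls must be >= 1")


def find_fit_window(
    conc: TimeSeries, t_peak: float, baseline: float, tolerance: float = 0.05
) -> Tuple[float, bool]:
    """End of the fit window: first time after the peak at which the trace has
    come back to within ``tolerance`` of the baseline (c <= baseline*(1+tol)),
    applied one-sided from above since additions raise concentration.

    If the trace never reaches the band, the window runs to the last sample
    and ``reached_baseline`` is False.
    """
    if baseline <= 0:
        raise UptakeError("baseline must be > 0")
    if not (conc.t_start <= t_peak <= conc.t_end):
        raise UptakeError("t_peak outside trace span")
    if t_peak >= conc.t_end:
        raise UptakeError("t_peak at the last sample: no decay to fit")
    mask = conc.times > t_peak
    t_post, c_post = conc.times[mask], conc.values[mask]
    hits = np.nonzero(c_post <= baseline * (1.0 + tolerance))[0]
    if hits.size:
        return float(t_post[hits[0]]), True
    return float(conc.t_end), False


def fit_power_law(
    conc: TimeSeries,
    t_start: float,
    t_end: float,
    t_origin: float,
    method: str = "loglog",
) -> Tuple[float, float, float]:
    """Fit c = B * (t - t_origin)^k over samples with t in [t_start, t_end].

    Returns (B, k, r2).  Default is OLS on (log10 tau, log10 c); ``method=
    "nonlinear"`` refines by least squares in linear space starting from the
    log-log solution.  All concentrations in the window must be positive and
    all tau strictly positive; fewer than 3 samples is an error.
    """
    mask = (conc.times >= t_start) & (conc.times <= t_end)
    t = conc.times[mask]
    c = conc.values[mask]
    if len(t) < 3:
        raise UptakeError(f"fit window holds {len(t)} samples; need >= 3")
    tau = t - t_origin
    if np.any(tau <= 0):
        raise UptakeError("all samples must lie strictly after the time origin")
    if np.any(c <= 0):
        raise UptakeError("non-positive concentration inside the fit window")
    if np.all(c == c[0]):
        # flat trace: exact fit with k = 0
        return float(c[0]), 0.0, 1.0
    x, y = np.log10(tau), np.log10(c)
    res = stats.linregress(x, y)
    k = float(res.slope)
    b = float(10.0**res.intercept)
    r2 = float(res.rvalue**2)
    if method == "nonlinear":
        popt, _ = optimize.curve_fit(
            lambda tt, B, kk: B * tt**kk, tau, c, p0=[b, k], maxfev=10000
        )
        b, k = float(popt[0]), float(popt[1])
        resid = c - b * tau**k
        ss_tot = float(np.sum((c - c.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    elif method != "loglog":
        raise UptakeError(f"unknown fit method {method!r}")
    return b, k, r2


def _zero_result(baseline: float) -> UptakeResult:
    return UptakeResult(
        B=float("nan"),
        k_uptake=0.0,
        t_fit_start=None,
        t_fit_end=None,
        baseline=baseline,
        reached_baseline=False,
        zero_uptake=True,
    )


def compute_uptake(
    record: ExperimentRecord,
    curve: CalibrationCurve,
    config: Optional[RunConfig] = None,
) -> UptakeResult:
    """Full single-experiment pipeline: Z -> c, baseline, peak, window, fit.

    Peak and window detection run on the (optionally smoothed) concentration
    trace; the power-law fit runs on the raw concentrations unless
    ``config.fit_on_smoothed``.  The zero-uptake rule: when the post-addition
    concentration never exceeds the baseline, never decreases after the
    addition, or peaks only at the very last sample (no decay recorded),
    k_uptake is set to 0.
    """
    config = config or RunConfig()
    if record.addition_time is None:
        raise UptakeError("record has no addition_time")
    conc, _flags = convert_trace(record.trace, curve)
    baseline = estimate_baseline(conc, config.baseline_window_hours)
    detect = (
        percentile_filter(conc, config.smoothing) if config.smoothing else conc
    )
    peak = find_post_addition_peak(detect, record.addition_time, baseline)
    if peak is None:
        return _zero_result(baseline)
    t_peak, _c_peak = peak
    post = detect.values[detect.times >= record.addition_time]
    if len(post) >= 2 and np.all(np.diff(post) >= 0):
        # concentration never decreased after the addition
        return _zero_result(baseline)
    if t_peak >= detect.t_end:
        return _zero_result(baseline)
    t_end, reached = find_fit_window(detect, t_peak, baseline, config.tolerance)
    fit_series = detect if config.fit_on_smoothed else conc
    t_origin = record.addition_time if config.t_origin == "addition" else t_peak
    # keep tau strictly positive (a sample exactly at the origin is excluded)
    t_start = t_peak if t_peak > t_origin else np.nextafter(t_origin, np.inf)
    b, k, r2 = fit_power_law(
        fit_series, t_start, t_end, t_origin, method=config.fit_method
    )
    n_fit = int(np.sum((fit_series.times >= t_start) & (fit_series.times <= t_end)))
    return UptakeResult(
        B=b,
        k_uptake=k,
        t_fit_start=float(t_start),
        t_fit_end=float(t_end),
        baseline=baseline,
        reached_baseline=reached,
        zero_uptake=False,
        r2=r2,
        n_fit=n_fit,
    )


def normalize_uptake(
    k_uptake: float,
    control_results: Sequence[UptakeResult],
    epsilon: float = 1e-9,
) -> NormalizedUptake:
    """Normalized rate of uptake: k_uptake / mean(k_control).

    A near-zero control mean (|mean| < epsilon) flags the ratio as undefined
    rather than returning an infinity.
    """
    if len(control_results) == 0:
        raise UptakeError("need at least one control result")
    ks = np.array([r.k_uptake for r in control_results], dtype=float)
    mean_k = float(ks.mean())
    if abs(mean_k) < epsilon:
        return NormalizedUptake(
            ratio=float("nan"),
            k_control_mean=mean_k,
            n_controls=len(ks),
            undefined=True,
        )
    return NormalizedUptake(
        ratio=float(k_uptake) / mean_k,
        k_control_mean=mean_k,
        n_controls=len(ks),
    )


# ---------------------------------------------------------------------------
# Batch runner over a manifest of trace files.

MANIFEST_COLUMNS = ["path", "salt_name", "role"]


def run_batch(
    manifest: Union[str, Path, pd.DataFrame],
    calibrations: dict,
    config: Optional[RunConfig] = None,
    base_dir: Optional[Union[str, Path]] = None,
) -> pd.DataFrame:
    """Process every experiment in a manifest and normalize against controls.

    ``manifest`` is a CSV (or DataFrame) with columns path, salt_name and
    role ("plant" or "control"), plus an optional condition column.
    ``calibrations`` maps salt name -> :class:`CalibrationCurve`.  Controls
    are matched to plant runs of the same condition (same salt when no
    condition column is given).  Returns one row per experiment with the
    fitted k, flags and, for plant runs, the normalized ratio.
    """
    config = config or RunConfig()
    if isinstance(manifest, (str, Path)):
        base_dir = base_dir or Path(manifest).parent
        manifest = pd.read_csv(manifest)
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise UptakeError(f"manifest missing columns: {sorted(missing)}")
    if len(manifest) == 0:
        raise UptakeError("empty manifest")
    base_dir = Path(base_dir) if base_dir is not None else Path(".")

    rows = []
    results: dict = {}
    for pos, (_, m) in enumerate(manifest.iterrows()):
        salt = str(m["salt_name"])
        if salt not in calibrations:
            raise UptakeError(f"no calibration curve for salt {salt!r}")
        p = Path(m["path"])
        if not p.is_absolute():
            p = base_dir / p
        record = read_trace(p)
        res = compute_uptake(record, calibrations[salt], config)
        results[pos] = res
        rows.append(
            {
                "path": str(m["path"]),
                "salt_name": salt,
                "condition": str(m["condition"]) if "condition" in manifest else salt,
                "role": str(m["role"]),
                "k": res.k_uptake,
                "B": res.B,
                "baseline": res.baseline,
                "r2": res.r2,
                "reached_baseline": res.reached_baseline,
                "zero_uptake": res.zero_uptake,
            }
        )
    out = pd.DataFrame(rows)

    out["ratio"] = np.nan
    out["ratio_undefined"] = False
    out["k_control_mean"] = np.nan
    out["n_controls"] = 0
    for cond, grp in out.groupby("condition"):
        ctrl_idx = grp.index[grp["role"] == "control"]
        plant_idx = grp.index[grp["role"] == "plant"]
        if len(plant_idx) == 0:
            continue
        if len(ctrl_idx) == 0:
            raise UptakeError(f"no control runs for condition {cond!r}")
        controls = [results[i] for i in ctrl_idx]
        for i in plant_idx:
            norm = normalize_uptake(
                out.at[i, "k"], controls, epsilon=config.control_epsilon
            )
            out.at[i, "ratio"] = norm.ratio
            out.at[i, "ratio_undefined"] = norm.undefined
            out.at[i, "k_control_mean"] = norm.k_control_mean
            out.at[i, "n_controls"] = norm.n_controls
    return out
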
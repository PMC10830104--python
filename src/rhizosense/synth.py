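"""Synthetic sensor-trace and dataset generation.

Emulates the phenomenology of impedance uptake experiments: a flat
pre-addition baseline of at least 3 h, a step concentration increase when the
salt solution is added, a power-law decay c = c_peak * (tau/tau_1)^k back
toward baseline for plant runs (k = 0 for plant-free controls), a slow upward
impedance drift (default 100 ohm/h, the magnitude seen on plant-free paper
from electrode wetting), and multiplicative lognormal measurement noise on
the impedance (electrochemical noise scales with signal magnitude; default
0.5 % relative).  Drift acts in impedance space (it is an electrode artifact)
while uptake acts in concentration space, which is what makes normalizing
plant exponents by control exponents meaningful downstream.

The power law is anchored at the first sample strictly after the addition
(tau_1 = its lag), which both avoids the tau = 0 singularity and pins
c(first post-addition sample) = c_peak.

What the generator does not emulate: electrode physics (double layers,
diffusion), plant-to-plant biological variability structure, or dynamic
pH/H2O2 responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationCurve,
    LinearSensorCal,
    impedance_from_concentration,
)
from .config import RunConfig
from .trace_io import ExperimentRecord, TimeSeries, write_trace
from .uptake import compute_uptake

__all__ = [
    "TraceSpec",
    "Cohort",
    "SynthError",
    "BLOCKER_RATIO_PRESETS",
    "synthetic_calibration",
    "example_ph_cal",
    "example_h2o2_cal",
    "generate_trace",
    "generate_cohort",
    "write_cohort",
    "MLDataset",
    "generate_ml_dataset",
]


class SynthError(ValueError):
    pass


#: Normalized-uptake targets from the channel-blocker experiment design,
#: usable as simulation presets: untreated plants, then pretreatments with
#: deionized water, NaCl, or the Ca2+ channel blocker LaCl3 for 4.5 or 24 h
#: before Ca(NO3)2 addition.
BLOCKER_RATIO_PRESETS: Dict[str, float] = {
    "untreated": 6.1,
    "water_4.5h": 5.8,
    "NaCl_4.5h": 6.0,
    "LaCl3_4.5h": 4.0,
    "NaCl_24h": 4.7,
    "LaCl3_24h": 3.1,
}


def synthetic_calibration(
    salt_name: str, slope: float = -0.5, intercept: float = 3.2
) -> CalibrationCurve:
    """A plausible log-log impedance calibration (synthetic stand-in).

    Slope -0.5 per decade; the intercept places the sensor at ~5 kOhm in
    0.1 M and ~16 kOhm at the 10 mM post-addition level (plant-free paper
    discs sit below ~20 kOhm after a salt addition, rising from ~160 kOhm at
    the 0.1 mM background), valid over the extended characterization span
    0.01 uM - 0.1 M."""
    return CalibrationCurve(
        salt_name=salt_name,
        slope=slope,
        intercept=intercept,
        c_min=1e-8,
        c_max=0.1,
        fit_r2=1.0,
        n_points=15,
    )


def example_ph_cal() -> LinearSensorCal:
    """Synthetic near-Nernstian pH calibration: -59 mV per pH unit."""
    return LinearSensorCal(gain=-0.059, offset=0.65, valid_input_range=(2.0, 12.0))


def example_h2o2_cal() -> LinearSensorCal:
    """Synthetic amperometric H2O2 calibration over the 2-100 uM span."""
    return LinearSensorCal(gain=0.5, offset=2e-8, valid_input_range=(2e-6, 100e-6))


@dataclass(frozen=True)
class TraceSpec:
    """Parameters of one simulated impedance experiment.

    Defaults are the study conditions: >= 3 h pre-addition rest, a 30 uL
    addition of 0.1 M salt stepping the paper-disc concentration to ~10 mM
    over a 0.1 mM residual background, ~100 ohm/h control drift, 0.5 %
    multiplicative noise, 24 h of recording at 30 s sampling.
    """

    salt_name: str
    calibration: CalibrationCurve
    c0: float = 1e-4
    t_add: Optional[float] = 3.0 * 3600.0
    c_peak: float = 1e-2
    k_true: float = 0.0
    drift_rate: float = 100.0  # ohm per hour
    noise_sd: float = 0.005  # relative (lognormal sigma) on impedance
    duration_s: float = 24.0 * 3600.0
    dt_s: float = 30.0
    seed: int = 0
    n_plants: int = 30
    plant_age_days: int = 9
    addition_volume_ul: float = 30.0
    addition_concentration: float = 0.1

    def __post_init__(self):
        if self.c0 <= 0:
            raise SynthError("c0 must be > 0")
        if self.dt_s <= 0:
            raise SynthError("dt_s must be > 0")
        if self.t_add is not None:
            if self.duration_s <= self.t_add:
                raise SynthError("duration must exceed t_add")
            if self.c_peak <= self.c0:
                raise SynthError("c_peak must exceed c0 for addition runs")
        if self.noise_sd < 0:
            raise SynthError("noise_sd must be >= 0")


def generate_trace(spec: TraceSpec) -> ExperimentRecord:
    """Simulate one impedance-channel experiment record.

    Concentration is c0 up to (and including) the addition time, then
    max(c0, c_peak * (tau/tau_1)^k_true); impedance is the calibration
    forward map plus drift_rate * t, under multiplicative lognormal noise.
    All randomness flows from ``spec.seed``.
    """
    times = np.arange(0.0, spec.duration_s + spec.dt_s / 2, spec.dt_s)
    c = np.full_like(times, spec.c0)
    if spec.t_add is not None:
        post = times > spec.t_add
        if not post.any():
            raise SynthError("no samples after t_add")
        tau = times[post] - spec.t_add
        tau1 = tau[0]
        decay = spec.c_peak * (tau / tau1) ** spec.k_true
        c[post] = np.maximum(spec.c0, decay)
    z = impedance_from_concentration(spec.calibration, c)
    z = z + (spec.drift_rate / 3600.0) * times
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        z = z * np.exp(spec.noise_sd * rng.standard_normal(times.shape))
    trace = TimeSeries(times, z, "impedance")
    return ExperimentRecord(
        trace=trace,
        salt_name=spec.salt_name,
        addition_time=spec.t_add,
        addition_volume_ul=spec.addition_volume_ul if spec.t_add is not None else None,
        addition_concentration=(
            spec.addition_concentration if spec.t_add is not None else None
        ),
        is_control=spec.n_plants == 0,
        n_plants=spec.n_plants,
        plant_age_days=spec.plant_age_days,
    )


# ---------------------------------------------------------------------------
# Cohorts with closed-loop ratio targets


@dataclass
class Cohort:
    """Generated experiments plus their ground truth and calibrations."""

    records: List[Tuple[str, str, ExperimentRecord]]  # (condition, role, record)
    ground_truth: pd.DataFrame
    calibrations: Dict[str, CalibrationCurve]  # keyed by salt name


def _pipeline_k(spec: TraceSpec, config: RunConfig) -> float:
    return compute_uptake(generate_trace(spec), spec.calibration, config).k_uptake


#: internal replicates used when calibrating k_true under measurement noise
_N_CAL_REPS = 3


def _mean_pipeline_k(spec: TraceSpec, config: RunConfig, cal_seed: int) -> float:
    """Expected pipeline exponent under the spec's noise (noiseless: exact)."""
    if spec.noise_sd == 0:
        return _pipeline_k(spec, config)
    rng = np.random.default_rng(cal_seed)
    ks = [
        _pipeline_k(replace(spec, seed=int(rng.integers(0, 2**31 - 1))), config)
        for _ in range(_N_CAL_REPS)
    ]
    return float(np.mean(ks))


def calibrate_k_true(
    base_spec: TraceSpec,
    target_ratio: float,
    k_control_eff: float,
    config: RunConfig,
    tol: Optional[float] = None,
    max_iter: int = 25,
    cal_seed: int = 0,
) -> float:
    """Choose k_true so the pipeline-recovered ratio hits ``target_ratio``.

    The closed loop runs under the cohort's own noise conditions: the window
    the pipeline fits over depends on where the detected peak lands, which
    differs between noiseless and noisy traces, so the first-order guess
    target_ratio * k_control_eff is refined by a secant iteration against the
    pipeline evaluated at the spec's noise level (averaging a few internal
    replicates when noisy) until the recovered ratio is within ``tol``.
    """

    if tol is None:
        tol = 1e-3 if base_spec.noise_sd == 0 else 2e-2

    def ratio_of(k_true: float) -> float:
        spec = replace(base_spec, k_true=k_true)
        return _mean_pipeline_k(spec, config, cal_seed) / k_control_eff

    k0 = target_ratio * k_control_eff
    r0 = ratio_of(k0)
    if abs(r0 - target_ratio) <= tol:
        return k0
    k1 = k0 * (1.0 + 0.1) if k0 != 0 else k_control_eff
    r1 = ratio_of(k1)
    for _ in range(max_iter):
        if r1 == r0:
            break
        k2 = k1 - (r1 - target_ratio) * (k1 - k0) / (r1 - r0)
        r2 = ratio_of(k2)
        if abs(r2 - target_ratio) <= tol:
            return k2
        k0, r0, k1, r1 = k1, r1, k2, r2
    raise SynthError(
        f"could not reach target ratio {target_ratio} (last ratio {r1:.4f})"
    )


def generate_cohort(
    salt_panel: Sequence[str],
    n_plant_reps: int,
    n_control_reps: int,
    target_ratios: Union[Dict[str, float], Sequence[float]],
    seed: int = 0,
    config: Optional[RunConfig] = None,
    condition_names: Optional[Sequence[str]] = None,
    **spec_overrides,
) -> Cohort:
    """Generate a panel of plant + control experiments hitting ratio targets.

    ``target_ratios`` maps each entry of ``salt_panel`` (by name, or
    positionally as a sequence) to the normalized uptake ratio the pipeline
    should recover.  Per condition, the control-equivalent exponent is
    measured by running the pipeline on control traces generated under the
    cohort's own noise conditions; plant k_true is then calibrated
    closed-loop against that (see :func:`calibrate_k_true`).  Controls share
    the drift and noise parameters.  A condition whose control-equivalent
    exponent is ~0 (no drift) cannot realize a finite target and raises.
    """
    if len(salt_panel) == 0:
        raise SynthError("empty salt panel")
    if n_control_reps < 1:
        raise SynthError("need n_control_reps >= 1 (normalization needs controls)")
    if n_plant_reps < 1:
        raise SynthError("need n_plant_reps >= 1")
    if isinstance(target_ratios, dict):
        ratios = [target_ratios[s] for s in salt_panel]
    else:
        ratios = list(target_ratios)
        if len(ratios) != len(salt_panel):
            raise SynthError("target_ratios must match salt_panel")
    if condition_names is None:
        condition_names = [f"c{i:02d}_{s}" for i, s in enumerate(salt_panel)]
    if len(set(condition_names)) != len(condition_names):
        raise SynthError("condition names must be unique")

    config = config or RunConfig()
    rng = np.random.default_rng(seed)
    records: List[Tuple[str, str, ExperimentRecord]] = []
    gt_rows = []
    calibrations: Dict[str, CalibrationCurve] = {}
    for cond, salt, target in zip(condition_names, salt_panel, ratios):
        calib = calibrations.setdefault(salt, synthetic_calibration(salt))
        base = TraceSpec(salt_name=salt, calibration=calib, **spec_overrides)
        cal_seed = int(rng.integers(0, 2**31 - 1))
        ctrl = replace(base, k_true=0.0, n_plants=0)
        k_ctrl_eff = _mean_pipeline_k(ctrl, config, cal_seed)
        if abs(k_ctrl_eff) < 1e-12:
            raise SynthError(
                f"condition {cond!r}: control-equivalent k ~ 0, "
                f"target ratio {target} unreachable (add drift)"
            )
        k_true = calibrate_k_true(
            base, target, k_ctrl_eff, config, cal_seed=cal_seed
        )
        for j in range(n_plant_reps):
            s = int(rng.integers(0, 2**31 - 1))
            rec = generate_trace(replace(base, k_true=k_true, seed=s))
            records.append((cond, "plant", rec))
            gt_rows.append(
                dict(condition=cond, salt_name=salt, role="plant", rep=j,
                     k_true=k_true, target_ratio=target,
                     k_control_eff=k_ctrl_eff, seed=s)
            )
        for j in range(n_control_reps):
            s = int(rng.integers(0, 2**31 - 1))
            rec = generate_trace(replace(base, k_true=0.0, n_plants=0, seed=s))
            records.append((cond, "control", rec))
            gt_rows.append(
                dict(condition=cond, salt_name=salt, role="control", rep=j,
                     k_true=0.0, target_ratio=target,
                     k_control_eff=k_ctrl_eff, seed=s)
            )
    return Cohort(
        records=records,
        ground_truth=pd.DataFrame(gt_rows),
        calibrations=calibrations,
    )


def write_cohort(cohort: Cohort, out_dir: Union[str, Path]) -> Tuple[Path, Path]:
    """Write trace files, a batch manifest and the ground-truth sidecar.

    Returns (manifest_path, ground_truth_path).  The manifest carries a
    ``condition`` column so the batch runner normalizes within conditions even
    when several conditions share a salt.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    counters: Dict[Tuple[str, str], int] = {}
    for cond, role, rec in cohort.records:
        j = counters.get((cond, role), 0)
        counters[(cond, role)] = j + 1
        fname = f"{cond}_{role}{j:02d}.csv"
        write_trace(rec, out_dir / fname)
        rows.append(
            dict(path=fname, salt_name=rec.salt_name, role=role, condition=cond)
        )
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    gt_path = out_dir / "ground_truth.csv"
    cohort.ground_truth.to_csv(gt_path, index=False, float_format="%.12g")
    return manifest_path, gt_path


# ---------------------------------------------------------------------------
# Salt descriptor datasets for the range classifier


@dataclass
class MLDataset:
    features: pd.DataFrame
    ratios: np.ndarray
    labels: np.ndarray


#: Class-conditional latent ratio means at unit signal strength, reflecting
#: the observed pattern: nutrient-cation salts high, heavy-metal salts ~1.
_CLASS_RATIO_MEANS = {
    "macronutrient": 6.0,
    "secondary_nutrient": 5.0,
    "sodium": 5.5,
    "heavy_metal": 1.0,
}
_RATIO_CENTER = 3.5
_RATIO_NOISE_SD = 0.8


def generate_ml_dataset(
    n_salts: int,
    class_signal_strength: float = 1.0,
    n_ranges: int = 2,
    seed: int = 0,
) -> MLDataset:
    """Draw salts from the bundled panel and attach latent uptake ratios.

    Ratios are class-conditional normals whose means are pulled away from a
    common center in proportion to ``class_signal_strength`` (0 means the
    labels carry no information about the features); labels come from
    :func:`rhizosense.ml.bin_uptake`.
    """
    from . import ions, ml

    if class_signal_strength < 0:
        raise SynthError("class_signal_strength must be >= 0")
    if n_salts < n_ranges:
        raise SynthError("need n_salts >= n_ranges")
    rng = np.random.default_rng(seed)
    names = list(rng.choice(np.array(ions.SALT_PANEL, dtype=object), size=n_salts))
    features = ml.build_feature_table(names)
    base = np.array(
        [
            _CLASS_RATIO_MEANS[ions.CATIONS[ions.parse_salt(s)[0]].nutrient_class]
            for s in names
        ]
    )
    means = _RATIO_CENTER + class_signal_strength * (base - _RATIO_CENTER)
    ratios = means + rng.normal(0.0, _RATIO_NOISE_SD, size=n_salts)
    ratios = np.maximum(ratios, 0.01)
    labels = ml.bin_uptake(ratios, n_ranges)
    return MLDataset(features=features, ratios=ratios, labels=labels)
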
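"""Run configuration: one small object, YAML round-trippable, hashable.

Defaults follow the analysis protocol: 2 h baseline window, 5 % baseline
tolerance, 50th-percentile smoothing, 5 cross-validation folds.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import yaml

from .signal_processing import SmoothingSpec

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    #: rolling-percentile smoothing used for peak/window detection and display
    #: (100-point median: the window used when smoothing uptake traces)
    smoothing: Optional[SmoothingSpec] = field(
        default_factory=lambda: SmoothingSpec(50.0, 100)
    )
    #: hours of recording averaged for the pre-addition baseline
    baseline_window_hours: float = 2.0
    #: relative tolerance for "the decay has met the baseline"
    tolerance: float = 0.05
    #: power-law time origin: "addition" (tau = t - t_add) or "peak"
    t_origin: str = "addition"
    #: fit the power law on the smoothed rather than raw concentrations
    fit_on_smoothed: bool = False
    #: "loglog" OLS on logged data, or "nonlinear" least squares in linear space
    fit_method: str = "loglog"
    #: |mean control k| below this makes the normalized ratio undefined
    control_epsilon: float = 1e-9
    #: cross-validation settings
    cv_folds: int = 5
    n_ranges: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.t_origin not in ("addition", "peak"):
            raise ValueError("t_origin must be 'addition' or 'peak'")
        if self.fit_method not in ("loglog", "nonlinear"):
            raise ValueError("fit_method must be 'loglog' or 'nonlinear'")
        if not (0 < self.tolerance < 1):
            raise ValueError("tolerance must be in (0, 1)")
        if self.baseline_window_hours <= 0:
            raise ValueError("baseline_window_hours must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["smoothing"] = None if self.smoothing is None else asdict(self.smoothing)
        return d

    def to_yaml(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8")
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sm = d.get("smoothing")
        if isinstance(sm, dict):
            d["smoothing"] = SmoothingSpec(**sm)
        return cls(**d)

    def config_hash(self) -> str:
        """Stable short hash of the canonical YAML form, for run logs."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: Union[str, Path]) -> RunConfig:
    with Path(path).open("r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)
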
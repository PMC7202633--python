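"""Pipeline configuration: analysis settings shared by every stage.

One flat dataclass keeps the knobs that the protocol does not fix —
window fractions, thresholds, fitter settings — with the defaults used
throughout the package.  A SHA-256 hash of the canonical JSON form is
stamped onto every output row for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis settings.

    Attributes
    ----------
    cycle_index : which cycle of a cyclic test is parameterized (protocol
        uses the 20th, after preconditioning).
    frequency : cyclic test frequency, Hz.
    stiffness_window_fraction : fraction of the load range, measured from
        each extreme, over which the limb stiffness line is fitted.
    nz_fraction : |load| threshold for the neutral zone, as a fraction of
        the load amplitude.
    nz_method : "threshold" (default) or "intersection" (dual-line).
    smoothing_window_s : centered moving-average window for failure
        detection, seconds; 0 disables smoothing.
    drop_fraction : post-peak torque drop (fraction of peak) required to
        call a failure event rather than test truncation.
    fit_tau_bounds / fit_k_bounds : box bounds for the creep fitter.
    fit_seed : seed for multi-start jitter in the creep fitter.
    alpha : significance level for the statistics stage.
    ss_type : ANOVA sums-of-squares type (2 handles unbalanced cells).
    """

    cycle_index: int = 20
    frequency: float = 1.0
    stiffness_window_fraction: float = 0.2
    nz_fraction: float = 0.1
    nz_method: str = "threshold"
    smoothing_window_s: float = 0.5
    drop_fraction: float = 0.2
    fit_tau_bounds: tuple = (0.1, 1e5)
    fit_k_bounds: tuple = (1e-3, 1e4)
    fit_seed: int = 0
    alpha: float = 0.05
    ss_type: int = 2

    def __post_init__(self):
        if not (0.0 < self.stiffness_window_fraction < 1.0):
            raise ValueError("stiffness_window_fraction must be in (0, 1)")
        if not (0.0 < self.nz_fraction < 1.0):
            raise ValueError("nz_fraction must be in (0, 1)")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.nz_method not in {"threshold", "intersection"}:
            raise ValueError("nz_method must be 'threshold' or 'intersection'")
        if self.drop_fraction < 0 or self.smoothing_window_s < 0:
            raise ValueError("drop_fraction and smoothing_window_s must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fit_tau_bounds"] = list(self.fit_tau_bounds)
        d["fit_k_bounds"] = list(self.fit_k_bounds)
        return d

    @property
    def hash(self) -> str:
        """Short hex digest identifying this configuration."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("fit_tau_bounds", "fit_k_bounds"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)
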
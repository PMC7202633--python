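"""Five-parameter viscoelastic solid: forward creep simulation and fitting.

The motion segment under a constant compressive step load F is modelled as a
spring of stiffness ``k0`` in series with two Kelvin–Voigt arms (spring ``k1``
with time constant ``tau1``; spring ``k2`` with ``tau2``), giving the creep
displacement response

    d(t) = F/k0 + (F/k1)(1 - exp(-t/tau1)) + (F/k2)(1 - exp(-t/tau2))

The instantaneous elastic displacement is ``F/k0``; the asymptotic (t -> inf)
creep displacement is ``F (1/k1 + 1/k2)``; their sum is the total
displacement.  ``tau1 < tau2`` by convention, so arm 1 is the fast response
and arm 2 the slow response.

Fitting is nonlinear least squares in log-parameter space (which removes the
positivity constraints and tames the tau1/tau2 exchange symmetry) with a
deterministic multi-start grid seeded from endpoint heuristics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .config import PipelineConfig
from .errors import FitFailureError, InvalidModelError, ProtocolMismatchError
from .recording import TimeSeriesRecording

__all__ = [
    "FiveParamModel",
    "CreepFitResult",
    "simulate_creep",
    "derive_creep_quantities",
    "fit_creep",
]


@dataclass(frozen=True)
class FiveParamModel:
    """Parameter vector of the 5-parameter viscoelastic solid.

    k0 : elastic stiffness, N/mm.
    k1, k2 : fast- and slow-response arm stiffnesses, N/mm.
    tau1, tau2 : fast and slow time constants, s (tau1 < tau2; arms are
        sorted on construction so labelling is canonical).
    """

    k0: float
    k1: float
    k2: float
    tau1: float
    tau2: float

    def __post_init__(self):
        for name in ("k0", "k1", "k2", "tau1", "tau2"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise InvalidModelError(
                    f"{name} must be strictly positive and finite, got {value!r}"
                )
        if self.tau1 > self.tau2:  # canonical arm order: fast first
            k1, tau1 = self.k1, self.tau1
            object.__setattr__(self, "k1", self.k2)
            object.__setattr__(self, "tau1", self.tau2)
            object.__setattr__(self, "k2", k1)
            object.__setattr__(self, "tau2", tau1)

    def as_array(self) -> np.ndarray:
        return np.array([self.k0, self.k1, self.k2, self.tau1, self.tau2])


@dataclass(frozen=True)
class CreepFitResult:
    """Fitted model plus the derived displacement quantities.

    Invariants (held to numerical tolerance): ``total = elastic + creep``,
    ``elastic = F/k0``, ``creep = F (1/k1 + 1/k2)`` (asymptotic convention).
    """

    model: FiveParamModel
    applied_force: float
    elastic_displacement: float
    creep_displacement: float
    total_displacement: float
    residual_rms: float
    converged: bool


def simulate_creep(model: FiveParamModel, force: float, times) -> np.ndarray:
    """Displacement response (mm) of the 5-parameter solid to a step load.

    ``times`` must be non-negative and non-decreasing; ``force`` (N) is the
    magnitude of the compressive step.  ``d(0) = force/k0``; the series is
    monotone non-decreasing and bounded by ``force (1/k0 + 1/k1 + 1/k2)``.
    """
    if not isinstance(model, FiveParamModel):
        model = FiveParamModel(*model)
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return np.empty(0)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be non-decreasing")
    if force < 0:
        raise ValueError("step load must be >= 0")
    return (
        force / model.k0
        + (force / model.k1) * (1.0 - np.exp(-times / model.tau1))
        + (force / model.k2) * (1.0 - np.exp(-times / model.tau2))
    )


def derive_creep_quantities(model: FiveParamModel, force: float) -> dict:
    """Closed-form elastic, asymptotic creep and total displacements (mm)."""
    if not isinstance(model, FiveParamModel):
        model = FiveParamModel(*model)
    if force <= 0:
        raise ValueError("force must be > 0")
    elastic = force / model.k0
    creep = force * (1.0 / model.k1 + 1.0 / model.k2)
    return {
        "elastic_displacement": elastic,
        "creep_displacement": creep,
        "total_displacement": elastic + creep,
    }


def _creep_residual_and_jac(logp, t, d_obs, force):
    k0, k1, k2, tau1, tau2 = np.exp(logp)
    e1 = np.exp(-t / tau1)
    e2 = np.exp(-t / tau2)
    pred = force / k0 + (force / k1) * (1 - e1) + (force / k2) * (1 - e2)
    res = pred - d_obs
    jac = np.empty((t.size, 5))
    jac[:, 0] = -force / k0
    jac[:, 1] = -(force / k1) * (1 - e1)
    jac[:, 2] = -(force / k2) * (1 - e2)
    jac[:, 3] = -(force / k1) * (t / tau1) * e1
    jac[:, 4] = -(force / k2) * (t / tau2) * e2
    return res, jac


def _trim_to_step(time, load, deformation, force, level=0.95):
    """Drop samples before the load reaches ``level`` of the target step.

    Creep models assume a step; data logged during the loading ramp is
    discarded and time is re-zeroed at the first retained sample.
    """
    at_load = np.abs(load) >= level * abs(force)
    if not np.any(at_load):
        raise ProtocolMismatchError(
            f"load never reaches {level:.0%} of the target step {force} N"
        )
    start = int(np.argmax(at_load))
    t = time[start:] - time[start]
    return t, load[start:], deformation[start:]


def fit_creep(
    recording: TimeSeriesRecording,
    force: float | None = None,
    cfg: PipelineConfig | None = None,
) -> CreepFitResult:
    """Fit the 5-parameter solid to a creep recording by least squares.

    The recording must be a creep segment: after trimming the loading ramp
    the load channel has to be approximately constant (within 5% RMS of the
    step).  ``force`` defaults to the median absolute load.  The fit runs a
    deterministic multi-start (tau grid x stiffness-split heuristics, 8
    starts) of `scipy.optimize.least_squares` in log-parameter space with
    analytic Jacobian; arms are sorted so ``tau1 < tau2`` on output.

    Raises
    ------
    ProtocolMismatchError : load channel not an approximately constant step.
    FitFailureError : no start converged; carries the best-so-far result.
    """
    cfg = cfg or PipelineConfig()
    load = np.abs(recording.load)
    if force is None:
        force = float(np.median(load[load > 0])) if np.any(load > 0) else 0.0
    if force <= 0:
        raise ProtocolMismatchError("creep fit needs a positive step load")

    t, load_t, d = _trim_to_step(recording.time, load, np.abs(recording.deformation), force)
    rel_dev = np.sqrt(np.mean((load_t - force) ** 2)) / force
    if rel_dev > 0.05:
        raise ProtocolMismatchError(
            f"load channel deviates {rel_dev:.1%} RMS from the step {force} N; "
            "not a creep segment"
        )
    if t.size < 50:
        warnings.warn(
            f"only {t.size} samples after ramp trim; identifiability is poor",
            UserWarning,
            stacklevel=2,
        )

    # Endpoint heuristics for stiffness starts: d(0) ~ F/k0, the end-of-test
    # displacement approximates the asymptote, and the creep compliance
    # 1/k1 + 1/k2 is split between the arms two ways.
    d0 = max(float(d[0]), 1e-9)
    d_end = max(float(d[-1]), d0 * (1 + 1e-9))
    k0_start = force / d0
    c_creep = max((d_end - d0) / force, 1e-9)
    tau_lo, tau_hi = cfg.fit_tau_bounds
    k_lo, k_hi = cfg.fit_k_bounds

    starts = []
    for tau1_0 in (10.0, 60.0):
        for tau2_0 in (300.0, 1500.0):
            for frac in (0.5, 0.25):  # share of creep compliance in arm 1
                starts.append(
                    (
                        k0_start,
                        1.0 / (frac * c_creep),
                        1.0 / ((1 - frac) * c_creep),
                        tau1_0,
                        tau2_0,
                    )
                )

    lb = np.log([k_lo, k_lo, k_lo, tau_lo, tau_lo])
    ub = np.log([k_hi, k_hi, k_hi, tau_hi, tau_hi])
    rng = np.random.default_rng(cfg.fit_seed)

    best = None
    best_cost = np.inf
    any_converged = False
    for i, p0 in enumerate(starts):
        logp0 = np.clip(np.log(p0), lb, ub)
        if i >= 8:  # jittered restarts beyond the deterministic grid
            logp0 = np.clip(logp0 + rng.normal(0, 0.3, 5), lb, ub)
        sol = least_squares(
            lambda p: _creep_residual_and_jac(p, t, d, force)[0],
            logp0,
            jac=lambda p: _creep_residual_and_jac(p, t, d, force)[1],
            bounds=(lb, ub),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if sol.cost < best_cost:
            best_cost = sol.cost
            best = sol
        any_converged = any_converged or sol.success

    k0, k1, k2, tau1, tau2 = np.exp(best.x)
    model = FiveParamModel(k0=k0, k1=k1, k2=k2, tau1=tau1, tau2=tau2)
    quantities = derive_creep_quantities(model, force)
    result = CreepFitResult(
        model=model,
        applied_force=force,
        residual_rms=float(np.sqrt(2 * best.cost / t.size)),
        converged=bool(any_converged),
        **quantities,
    )
    if not any_converged:
        raise FitFailureError(
            "creep fit did not converge from any start", best_result=result
        )
    return result
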
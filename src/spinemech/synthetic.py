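"""Synthetic recordings and factorial cohorts for exercising the pipeline.

No raw data accompany the study, so this module inverts the analysis
operators: it builds recordings whose noiseless analysis returns a known
*truth* exactly, and whole 2 (genotype) x 2 (diet) x sex cohorts whose
per-specimen truths are drawn from the published group means ± SDs.

Cyclic loops use a piecewise-linear limb construction with a low-stiffness
central zone, so the default threshold definitions of stiffness, range of
motion and neutral zone recover the truth exactly on clean data (a smooth
tanh-blended alternative is available for robustness testing, where recovery
is only approximate by design).  Creep recordings follow the 5-parameter
solid forward model; failure ramps rise linearly to the truth peak and then
drop by a configured fraction.  Noise is additive white Gaussian on the
measured (response) channel; the servo-controlled channel is clean.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import reference_values as ref
from .creep import FiveParamModel, simulate_creep
from .errors import DesignWarning, GeneratorContractError
from .morphometry import HistoAreas, cell_density, compute_dhi, notochordal_band_fraction
from .recording import TimeSeriesRecording, write_recording

__all__ = [
    "RecordingProtocol",
    "SpecimenTruth",
    "CohortDesign",
    "CohortResult",
    "DEFAULT_NOISE_SD",
    "generate_recording",
    "generate_cohort",
]

# plausible bench-sensor noise levels (not study-derived)
DEFAULT_NOISE_SD = {
    "force": 0.005,        # N
    "torque": 1e-4,        # N·m
    "displacement": 0.002,  # mm
    "rotation": 0.001,     # rad
}

_RESPONSE_CHANNEL = {
    "axial_cyclic": "displacement",
    "creep": "displacement",
    "torsional_cyclic": "torque",
    "torsion_to_failure": "torque",
}

_TRUNCATION_FACTOR = 0.05  # positive parameters truncated at 0.05 x mean


@dataclass(frozen=True)
class RecordingProtocol:
    """Test-protocol description for the generator.

    kind : axial_cyclic | creep | torsional_cyclic | torsion_to_failure.
    amplitude : ±N (axial), ±rad (torsional) or step load N (creep).
    frequency : cyclic frequency, Hz.
    n_cycles : cyclic cycle count.
    duration : creep hold, s.
    sampling_rate : Hz.
    rate : failure-ramp rotation rate, rad/s.
    drop_fraction : post-peak torque drop the failure ramp exhibits.
    post_peak_span_fraction : rotation past the peak, as a fraction of the
        angle-to-failure, over which the drop develops.
    ramp_duration : loading-ramp length prepended to a creep hold, s.
    loop_shape : "piecewise" (exact truths) or "sigmoid" (smooth blend).
    """

    kind: str
    amplitude: float = 0.5
    frequency: float = 1.0
    n_cycles: int = 20
    duration: float = 2700.0
    sampling_rate: float = 1000.0
    rate: float = math.radians(1.0)
    drop_fraction: float = 0.5
    post_peak_span_fraction: float = 0.3
    ramp_duration: float = 0.0
    loop_shape: str = "piecewise"

    def __post_init__(self):
        if self.kind not in _RESPONSE_CHANNEL:
            raise GeneratorContractError(f"unknown protocol kind {self.kind!r}")
        if self.kind.endswith("cyclic") and self.sampling_rate < 20 * self.frequency:
            raise GeneratorContractError(
                "sampling_rate must be at least 20x the cyclic frequency"
            )
        if self.loop_shape not in {"piecewise", "sigmoid"}:
            raise GeneratorContractError("loop_shape must be piecewise|sigmoid")
        if self.amplitude <= 0 or self.sampling_rate <= 0:
            raise GeneratorContractError("amplitude and sampling_rate must be > 0")

    @classmethod
    def axial_cyclic(cls, **kw):
        """±0.5 N tension–compression at 1 Hz, 20 cycles."""
        return cls(kind="axial_cyclic", amplitude=0.5, **kw)

    @classmethod
    def creep(cls, **kw):
        """0.5 N compressive hold for 45 min, sampled at 10 Hz."""
        kw.setdefault("sampling_rate", 10.0)
        return cls(kind="creep", amplitude=0.5, duration=kw.pop("duration", 2700.0), **kw)

    @classmethod
    def torsional_cyclic(cls, **kw):
        """±10° rotation at 1 Hz, 20 cycles."""
        return cls(kind="torsional_cyclic", amplitude=math.radians(10.0), **kw)

    @classmethod
    def torsion_to_failure(cls, **kw):
        """1°/s ramp to failure."""
        kw.setdefault("sampling_rate", 100.0)
        return cls(kind="torsion_to_failure", **kw)


@dataclass
class SpecimenTruth:
    """Generating parameters of one specimen, with its group labels."""

    specimen_id: str = "specimen"
    sex: str | None = None
    genotype: str | None = None
    diet: str | None = None
    creep_model: FiveParamModel | None = None
    compressive_stiffness: float | None = None
    tensile_stiffness: float | None = None
    rom: float | None = None
    neutral_zone: float | None = None
    torsional_stiffness: float | None = None
    torque_range: float | None = None
    torsional_neutral_zone: float | None = None
    failure_strength: float | None = None
    angle_to_failure: float | None = None

    def __post_init__(self):
        for name in (
            "compressive_stiffness", "tensile_stiffness", "rom", "neutral_zone",
            "torsional_stiffness", "torque_range", "torsional_neutral_zone",
            "failure_strength", "angle_to_failure",
        ):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise GeneratorContractError(f"{name} must be positive, got {value}")
        if (
            self.neutral_zone is not None
            and self.rom is not None
            and self.neutral_zone > self.rom
        ):
            raise GeneratorContractError("neutral zone cannot exceed range of motion")

    @classmethod
    def from_cell_means(cls, sex="female", genotype="Control", diet="CD",
                        specimen_id=None, **overrides):
        """Truth set at the published group means for one factorial cell."""
        dist = ref.MECHANICS_DISTRIBUTIONS[(sex, genotype, diet)]
        means = {k: v[0] for k, v in dist.items()}
        means.update(overrides)
        # the published torsional NZ can exceed the ±10° span; keep it
        # feasible for loop construction (see generate_recording)
        theta0 = math.radians(10.0)
        nz_max = 2.0 * (theta0 - 0.2 * (means["torque_range"] / 2.0)
                        / means["torsional_stiffness"])
        tors_nz = min(means["torsional_neutral_zone"], 0.8 * nz_max)
        return cls(
            specimen_id=specimen_id or f"{sex}-{genotype}-{diet}-mean",
            sex=sex, genotype=genotype, diet=diet,
            creep_model=FiveParamModel(
                k0=means["k0"], k1=means["k1"], k2=means["k2"],
                tau1=means["tau1"], tau2=means["tau2"],
            ),
            compressive_stiffness=means["compressive_stiffness"],
            tensile_stiffness=means["tensile_stiffness"],
            rom=means["rom"],
            neutral_zone=means["neutral_zone"],
            torsional_stiffness=means["torsional_stiffness"],
            torque_range=means["torque_range"],
            torsional_neutral_zone=tors_nz,
            failure_strength=means["failure_strength"],
            angle_to_failure=means["angle_to_failure"],
        )


# ---------------------------------------------------------------------------
# load/deformation curve constructions

def _axial_curve_knots(f0, kc, kt, rom, nz, nz_fraction=0.1, window_fraction=0.2):
    """Piecewise-linear displacement-vs-force knots for an axial loop.

    Limb compliances 1/kt (tension) and 1/kc (compression) over the extreme
    ``window_fraction`` of the load range, a central zone of span ``nz``
    over |F| <= nz_fraction*f0, and a free middle compliance chosen so the
    end-to-end span equals ``rom``.
    """
    f1 = nz_fraction * f0
    f2 = (1.0 - window_fraction) * f0
    limb_span = (f0 - f2) * (1.0 / kt + 1.0 / kc)
    c_mid = (rom - nz - limb_span) / (2.0 * (f2 - f1))
    if c_mid < 0:
        raise GeneratorContractError(
            f"infeasible axial truth: rom={rom}, nz={nz}, kc={kc}, kt={kt} "
            "leave negative mid-zone compliance"
        )
    d1 = nz / 2.0
    d2 = d1 + c_mid * (f2 - f1)
    d_pos = d2 + (f0 - f2) / kt
    d_neg = -(d2 + (f0 - f2) / kc)
    forces = np.array([-f0, -f2, -f1, 0.0, f1, f2, f0])
    disps = np.array([d_neg, -d2, -d1, 0.0, d1, d2, d_pos])
    return forces, disps


def _torsional_curve_knots(theta0, k, torque_range, nz,
                           nz_fraction=0.1, window_fraction=0.2):
    """Piecewise-linear torque-vs-rotation knots for a torsional loop."""
    t0 = torque_range / 2.0
    t1 = nz_fraction * t0
    t2 = (1.0 - window_fraction) * t0
    th1 = nz / 2.0
    th2 = theta0 - (t0 - t2) / k
    if th2 <= th1:
        raise GeneratorContractError(
            f"infeasible torsional truth: neutral zone {nz} rad plus limb "
            f"span exceeds the ±{theta0:.4f} rad rotation range"
        )
    thetas = np.array([-theta0, -th2, -th1, 0.0, th1, th2, theta0])
    torques = np.array([-t0, -t2, -t1, 0.0, t1, t2, t0])
    return thetas, torques


def _sigmoid_axial(force, f0, kc, kt, nz, nz_fraction=0.1):
    """Smooth alternative loop: linear limbs blended with a tanh neutral zone."""
    f1 = nz_fraction * f0
    limb = np.where(force >= 0, force / kt, force / kc)
    amp = (nz - f1 * (1.0 / kt + 1.0 / kc)) / (2.0 * math.tanh(1.0))
    return limb + max(amp, 0.0) * np.tanh(force / f1)


def _triangle(phase):
    """Unit triangle wave: 0 at phase 0 rising to +1 at 1/4, -1 at 3/4."""
    p = np.mod(phase, 1.0)
    return np.where(p < 0.25, 4 * p, np.where(p < 0.75, 2 - 4 * p, 4 * p - 4))


def generate_recording(
    protocol: RecordingProtocol,
    truth: SpecimenTruth,
    noise_sd: float | None = None,
    seed: int = 0,
) -> TimeSeriesRecording:
    """Build one recording whose noiseless analysis returns ``truth``.

    ``noise_sd`` is the white-noise SD on the measured channel
    (displacement for load-controlled tests, torque for rotation-controlled
    ones); ``None`` selects the bench default, 0 disables noise.  The same
    seed always produces byte-identical output.
    """
    rng = np.random.default_rng(seed)
    if noise_sd is None:
        noise_sd = DEFAULT_NOISE_SD[_RESPONSE_CHANNEL[protocol.kind]]
    fs = protocol.sampling_rate
    kind = protocol.kind

    if kind == "axial_cyclic":
        _require(truth, "compressive_stiffness", "tensile_stiffness", "rom",
                 "neutral_zone")
        t = np.arange(round(protocol.n_cycles / protocol.frequency * fs) + 1) / fs
        load = protocol.amplitude * _triangle(t * protocol.frequency)
        if protocol.loop_shape == "piecewise":
            knots_f, knots_d = _axial_curve_knots(
                protocol.amplitude, truth.compressive_stiffness,
                truth.tensile_stiffness, truth.rom, truth.neutral_zone,
            )
            deformation = np.interp(load, knots_f, knots_d)
        else:
            deformation = _sigmoid_axial(
                load, protocol.amplitude, truth.compressive_stiffness,
                truth.tensile_stiffness, truth.neutral_zone,
            )
        deformation = deformation + rng.normal(0.0, noise_sd, t.size)
        return TimeSeriesRecording(
            time=t, load=load, deformation=deformation,
            load_unit="N", deformation_unit="mm",
            specimen_id=truth.specimen_id, test_kind=kind,
            metadata={"load_limit": protocol.amplitude},
        )

    if kind == "torsional_cyclic":
        _require(truth, "torsional_stiffness", "torque_range",
                 "torsional_neutral_zone")
        t = np.arange(round(protocol.n_cycles / protocol.frequency * fs) + 1) / fs
        rotation = protocol.amplitude * _triangle(t * protocol.frequency)
        knots_th, knots_tq = _torsional_curve_knots(
            protocol.amplitude, truth.torsional_stiffness,
            truth.torque_range, truth.torsional_neutral_zone,
        )
        torque = np.interp(rotation, knots_th, knots_tq)
        torque = torque + rng.normal(0.0, noise_sd, t.size)
        return TimeSeriesRecording(
            time=t, load=torque, deformation=rotation,
            load_unit="Nm", deformation_unit="rad",
            specimen_id=truth.specimen_id, test_kind=kind,
            metadata={"rotation_limit": protocol.amplitude},
        )

    if kind == "creep":
        if truth.creep_model is None:
            raise GeneratorContractError("creep recording needs a creep_model truth")
        force = protocol.amplitude
        total = protocol.ramp_duration + protocol.duration
        t = np.arange(round(total * fs) + 1) / fs
        if protocol.ramp_duration > 0:
            load = np.minimum(t / protocol.ramp_duration, 1.0) * force
            deformation = np.where(
                t < protocol.ramp_duration,
                load / truth.creep_model.k0,  # quasi-static loading ramp
                simulate_creep(truth.creep_model, force,
                               np.maximum(t - protocol.ramp_duration, 0.0)),
            )
        else:
            load = np.full(t.size, force)
            deformation = simulate_creep(truth.creep_model, force, t)
        deformation = deformation + rng.normal(0.0, noise_sd, t.size)
        return TimeSeriesRecording(
            time=t, load=load, deformation=deformation,
            load_unit="N", deformation_unit="mm",
            specimen_id=truth.specimen_id, test_kind=kind,
            metadata={"step_load": force},
        )

    # torsion_to_failure
    _require(truth, "failure_strength", "angle_to_failure")
    theta_f = truth.angle_to_failure
    strength = truth.failure_strength
    post_span = protocol.post_peak_span_fraction * theta_f
    theta_end = theta_f + (post_span if protocol.drop_fraction > 0 else 0.0)
    duration = theta_end / protocol.rate
    t = np.arange(round(duration * fs) + 1) / fs
    rotation = protocol.rate * t
    if protocol.drop_fraction > 0:
        torque = np.where(
            rotation <= theta_f,
            strength * rotation / theta_f,
            strength * (1.0 - protocol.drop_fraction
                        * np.clip((rotation - theta_f) / post_span, 0.0, 1.0)),
        )
    else:
        torque = strength * rotation / theta_f
    torque = torque + rng.normal(0.0, noise_sd, t.size)
    return TimeSeriesRecording(
        time=t, load=torque, deformation=rotation,
        load_unit="Nm", deformation_unit="rad",
        specimen_id=truth.specimen_id, test_kind=kind,
        metadata={"rotation_rate": protocol.rate},
    )


def _require(truth: SpecimenTruth, *names):
    missing = [n for n in names if getattr(truth, n) is None]
    if missing:
        raise GeneratorContractError(f"truth is missing {missing}")


# ---------------------------------------------------------------------------
# cohort generation

@dataclass
class CohortDesign:
    """Factorial cohort layout and sampling distributions.

    ``cells`` is a list of (sex, genotype, diet, n).  Distributions default
    to the published group means ± SDs; positive parameters are sampled from
    normals truncated at 0.05 x mean.  ``noise_sd`` overrides the per-channel
    bench defaults.
    """

    cells: list
    mech_distributions: dict = field(
        default_factory=lambda: ref.MECHANICS_DISTRIBUTIONS
    )
    morph_distributions: dict = field(
        default_factory=lambda: ref.MORPHOMETRY_DISTRIBUTIONS
    )
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    protocols: dict = field(default_factory=dict)

    def __post_init__(self):
        for cell in self.cells:
            sex, genotype, diet, n = cell
            if n < 1:
                raise GeneratorContractError(f"cell {cell} has n < 1")
            if (sex, genotype, diet) not in self.mech_distributions:
                raise GeneratorContractError(f"no distributions for cell {cell}")
        defaults = {
            "axial_cyclic": RecordingProtocol.axial_cyclic(),
            "creep": RecordingProtocol.creep(),
            "torsional_cyclic": RecordingProtocol.torsional_cyclic(),
            "torsion_to_failure": RecordingProtocol.torsion_to_failure(),
        }
        defaults.update(self.protocols)
        self.protocols = defaults

    @classmethod
    def reference(cls, sexes=("female",), n_per_cell=10, **kw):
        """The study's 2x2 layout with published distributions."""
        cells = [
            (sex, genotype, diet, n_per_cell)
            for sex in sexes
            for genotype in ref.GENOTYPES
            for diet in ref.DIETS
        ]
        return cls(cells=cells, **kw)


@dataclass
class CohortResult:
    """Everything generate_cohort produced, in memory."""

    truths: pd.DataFrame
    outcomes: pd.DataFrame
    recordings: list  # (specimen_id, kind, TimeSeriesRecording)
    manifest: pd.DataFrame
    n_clipped: int


def _draw_positive(rng, mean, sd, n=None):
    """Truncated-normal draw bounded below at 0.05 x mean."""
    if sd == 0:
        return np.full(n, float(mean)) if n is not None else float(mean)
    lo = _TRUNCATION_FACTOR * mean
    if mean - lo < 0.5 * sd:  # truncation will distort the distribution badly
        warnings.warn(f"mean {mean} is close to the truncation bound {lo}",
                      DesignWarning, stacklevel=2)
    a = (lo - mean) / sd
    out = truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                        size=n if n is not None else 1, random_state=rng)
    return out if n is not None else float(out[0])


def _sample_truth(rng, cell_key, dist, specimen_id, protocols):
    """Draw one specimen's mechanics truth, clipped to generator feasibility."""
    sex, genotype, diet = cell_key
    d = {k: _draw_positive(rng, *dist[k]) for k in ref.MECHANICS_OUTCOMES}
    clipped = 0
    # creep arms: fast one labelled first
    if d["tau1"] >= d["tau2"]:
        d["tau1"], d["tau2"] = d["tau2"], d["tau1"]
        d["k1"], d["k2"] = d["k2"], d["k1"]
        clipped += 1
    # axial feasibility: mid-zone compliance must be non-negative.
    # Jointly infeasible (stiffness, ROM) draws are redrawn; the borderline
    # NZ is clipped.  Both events are counted as clips.
    f0 = protocols["axial_cyclic"].amplitude
    for attempt in range(100):
        limb_span = 0.2 * f0 * (1.0 / d["tensile_stiffness"]
                                + 1.0 / d["compressive_stiffness"])
        nz_max = d["rom"] - limb_span
        if nz_max > 0:
            break
        for key in ("compressive_stiffness", "tensile_stiffness", "rom"):
            d[key] = _draw_positive(rng, *dist[key])
        clipped += 1
    else:
        raise GeneratorContractError(
            f"{specimen_id}: cannot draw a feasible axial parameter set "
            f"(ROM persistently below the stiffness-window span)"
        )
    if d["neutral_zone"] > 0.95 * nz_max:
        d["neutral_zone"] = 0.95 * nz_max
        clipped += 1
    # torsional feasibility: NZ plus limb span must fit the ±10° sweep
    theta0 = protocols["torsional_cyclic"].amplitude
    for attempt in range(100):
        t0 = d["torque_range"] / 2.0
        tors_nz_max = 2.0 * (theta0 - 0.2 * t0 / d["torsional_stiffness"])
        if tors_nz_max > 0:
            break
        for key in ("torsional_stiffness", "torque_range"):
            d[key] = _draw_positive(rng, *dist[key])
        clipped += 1
    else:
        raise GeneratorContractError(
            f"{specimen_id}: torsional limb span persistently exceeds the "
            f"rotation range"
        )
    if d["torsional_neutral_zone"] > 0.8 * tors_nz_max:
        d["torsional_neutral_zone"] = 0.8 * tors_nz_max
        clipped += 1
    truth = SpecimenTruth(
        specimen_id=specimen_id, sex=sex, genotype=genotype, diet=diet,
        creep_model=FiveParamModel(
            k0=d["k0"], k1=d["k1"], k2=d["k2"], tau1=d["tau1"], tau2=d["tau2"]
        ),
        compressive_stiffness=d["compressive_stiffness"],
        tensile_stiffness=d["tensile_stiffness"],
        rom=d["rom"],
        neutral_zone=d["neutral_zone"],
        torsional_stiffness=d["torsional_stiffness"],
        torque_range=d["torque_range"],
        torsional_neutral_zone=d["torsional_neutral_zone"],
        failure_strength=d["failure_strength"],
        angle_to_failure=d["angle_to_failure"],
    )
    return truth, clipped


def _truth_row(truth: SpecimenTruth, force: float = 0.5) -> dict:
    m = truth.creep_model
    return {
        "specimen_id": truth.specimen_id,
        "sex": truth.sex,
        "genotype": truth.genotype,
        "diet": truth.diet,
        "compressive_stiffness": truth.compressive_stiffness,
        "tensile_stiffness": truth.tensile_stiffness,
        "rom": truth.rom,
        "neutral_zone": truth.neutral_zone,
        "k0": m.k0, "k1": m.k1, "k2": m.k2, "tau1": m.tau1, "tau2": m.tau2,
        "creep_displacement": force * (1.0 / m.k1 + 1.0 / m.k2),
        "total_displacement": force * (1.0 / m.k0 + 1.0 / m.k1 + 1.0 / m.k2),
        "torsional_stiffness": truth.torsional_stiffness,
        "torque_range": truth.torque_range,
        "torsional_neutral_zone": truth.torsional_neutral_zone,
        "failure_strength": truth.failure_strength,
        "angle_to_failure": truth.angle_to_failure,
    }


def _sample_morphometry(rng, dist) -> dict:
    """Direct outcome draws routed through the morphometry operators."""
    np_area = _draw_positive(rng, 1.0, 0.2)
    frac = min(_draw_positive(rng, *dist["noto_band_fraction"]), 100.0)
    areas = HistoAreas(
        notochordal_band_area=frac / 100.0 * np_area,
        np_area=np_area,
        cell_count=0,
        counted_area=1.0,
    )
    counted_area = _draw_positive(rng, 0.05, 0.01)
    density = _draw_positive(rng, *dist["cells_per_mm2"])
    count = int(round(density * counted_area))
    dh = _draw_positive(rng, *dist["ivd_height"], n=3)
    a = _draw_positive(rng, *dist["vertebral_length"], n=3)
    return {
        "noto_band_fraction": notochordal_band_fraction(areas),
        "cells_per_mm2": cell_density(count, counted_area),
        "ivd_height": float(np.mean(dh)),
        "vertebral_length": float(np.mean(a)),
        "dhi": compute_dhi(dh, a),
    }


def generate_cohort(
    design: CohortDesign,
    seed: int = 0,
    out_dir=None,
) -> CohortResult:
    """Draw a full cohort: truths, recordings, morphometry outcome table.

    With ``out_dir`` the recordings are written as commented-header CSVs
    alongside ``manifest.csv``, ``truths.csv``, ``truths.json`` and
    ``outcomes.csv`` — the exact inputs the analysis pipeline reads.
    Deterministic for a given (design, seed).
    """
    master = np.random.default_rng(seed)
    truth_rows, outcome_rows, recordings, manifest_rows = [], [], [], []
    n_clipped = 0

    for sex, genotype, diet, n in design.cells:
        cell_key = (sex, genotype, diet)
        mech = design.mech_distributions[cell_key]
        morph = design.morph_distributions.get(cell_key)
        for i in range(n):
            specimen_id = f"{sex[0].upper()}-{genotype}-{diet}-{i + 1:02d}"
            truth, clipped = _sample_truth(master, cell_key, mech,
                                           specimen_id, design.protocols)
            n_clipped += clipped
            truth_rows.append(
                _truth_row(truth, force=design.protocols["creep"].amplitude)
            )
            if morph is not None:
                outcome_rows.append(
                    {"specimen_id": specimen_id, "sex": sex,
                     "genotype": genotype, "diet": diet,
                     **_sample_morphometry(master, morph)}
                )
            for kind, protocol in design.protocols.items():
                rec_seed = int(master.integers(0, 2**31 - 1))
                rec = generate_recording(
                    protocol, truth,
                    noise_sd=design.noise_sd.get(_RESPONSE_CHANNEL[kind]),
                    seed=rec_seed,
                )
                recordings.append((specimen_id, kind, rec))
                manifest_rows.append(
                    {"specimen_id": specimen_id, "sex": sex,
                     "genotype": genotype, "diet": diet, "kind": kind,
                     "path": f"recordings/{specimen_id}_{kind}.csv"}
                )

    truths = pd.DataFrame(truth_rows)
    outcomes = pd.DataFrame(outcome_rows)
    manifest = pd.DataFrame(manifest_rows)
    if n_clipped:
        warnings.warn(
            f"{n_clipped} sampled parameters clipped to generator feasibility",
            DesignWarning,
            stacklevel=2,
        )

    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        (out / "recordings").mkdir(parents=True, exist_ok=True)
        for specimen_id, kind, rec in recordings:
            write_recording(rec, out / "recordings" / f"{specimen_id}_{kind}.csv")
        manifest.to_csv(out / "manifest.csv", index=False)
        truths.to_csv(out / "truths.csv", index=False, float_format="%.12g")
        outcomes.to_csv(out / "outcomes.csv", index=False, float_format="%.12g")
        with open(out / "truths.json", "w", encoding="utf-8") as fh:
            json.dump(truths.to_dict(orient="records"), fh, indent=1,
                      sort_keys=True, default=float)
    return CohortResult(
        truths=truths, outcomes=outcomes, recordings=recordings,
        manifest=manifest, n_clipped=n_clipped,
    )
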
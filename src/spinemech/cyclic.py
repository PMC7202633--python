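"""Hysteresis-loop extraction and parameterization for cyclic tests.

The cyclic protocols are 20 cycles of ±0.5 N tension–compression (axial,
load-controlled) or ±10° rotation (torsional, rotation-controlled) at 1 Hz.
The designated cycle (the 20th by default, after preconditioning) is cut out
of the recording, re-phased to the rising zero-crossing of the load channel,
and summarized as:

* limb stiffnesses — slope of a line fitted over the extreme
  ``stiffness_window_fraction`` (default 20%) of the load range on each limb
  of the loading branch;
* range of motion — deformation span between the attained load limits on the
  loading branch;
* neutral zone — deformation span over which |load| stays below
  ``nz_fraction`` (default 10%) of the load amplitude, averaged over the
  loading and unloading branches;
* load range — max minus min of the load channel over the loop.

Regressions always use the servo-controlled channel as the regressor (load
for axial, rotation for torsional) so that sensor noise on the measured
channel does not attenuate the slope (errors-in-variables).  On exactly
linear limbs every definition reduces to the two-point slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .errors import (
    CycleOutOfRangeError,
    LoopClosureWarning,
    PartialProtocolError,
    ProtocolMismatchError,
    ProtocolWarning,
)
from .recording import TimeSeriesRecording

__all__ = ["HysteresisLoop", "LoopMetrics", "extract_cycle", "axial_metrics",
           "torsional_metrics"]

MIN_LOOP_SAMPLES = 40
CLOSURE_TOLERANCE = 0.05


@dataclass
class HysteresisLoop:
    """One extracted cycle in load–deformation space.

    ``mode`` is "axial" (force vs displacement) or "torsional" (torque vs
    rotation).  Loops are expected to close: first and last points within 5%
    of the channel spans (violations warn, they do not raise, because sensor
    noise can open a small gap at low signal amplitudes).
    """

    deformation: np.ndarray
    load: np.ndarray
    mode: str
    cycle_index: int

    def __post_init__(self):
        self.deformation = np.asarray(self.deformation, dtype=float)
        self.load = np.asarray(self.load, dtype=float)
        if self.mode not in {"axial", "torsional"}:
            raise ValueError(f"mode must be axial|torsional, got {self.mode!r}")
        if len(self.deformation) != len(self.load):
            raise ValueError("deformation and load must have equal length")
        if len(self.load) < MIN_LOOP_SAMPLES:
            raise ProtocolMismatchError(
                f"loop has {len(self.load)} samples; need >= {MIN_LOOP_SAMPLES}"
            )
        err = max(self.closure_error())
        if err > CLOSURE_TOLERANCE:
            warnings.warn(
                f"loop endpoints differ by {err:.1%} of the channel span",
                LoopClosureWarning,
                stacklevel=2,
            )

    def closure_error(self) -> tuple:
        """(deformation, load) endpoint gaps as fractions of channel spans."""
        d_span = np.ptp(self.deformation) or 1.0
        l_span = np.ptp(self.load) or 1.0
        return (
            abs(self.deformation[-1] - self.deformation[0]) / d_span,
            abs(self.load[-1] - self.load[0]) / l_span,
        )


@dataclass(frozen=True)
class LoopMetrics:
    """Quantities extracted from one hysteresis cycle.

    Stiffness units are N/mm (axial) or N·m/rad (torsional); deformation
    spans are mm or rad; ``load_range`` is N or N·m.  ``stiffness_mean`` is
    the clockwise/counterclockwise average and is populated for torsional
    loops only.
    """

    stiffness_positive: float
    stiffness_negative: float
    stiffness_mean: float | None
    range_of_motion: float
    neutral_zone_length: float
    load_range: float
    mode: str


def extract_cycle(
    recording: TimeSeriesRecording,
    cycle_index: int = 20,
    frequency: float = 1.0,
) -> HysteresisLoop:
    """Cut the ``cycle_index``-th cycle out of a cyclic recording.

    The nominal window is ``[(i-1)/f, i/f]``; its start is re-phased to the
    rising zero-crossing of the load channel nearest the window start (falling
    back to the minimum-load sample when the load never crosses zero, e.g.
    offset load).  Raises CycleOutOfRangeError when the recording is shorter
    than ``cycle_index`` cycles; warns when the load channel's dominant
    spectral component is far from ``frequency``.
    """
    if cycle_index < 1:
        raise CycleOutOfRangeError("cycle_index must be >= 1")
    if recording.duration + 1e-9 < cycle_index / frequency:
        raise CycleOutOfRangeError(
            f"recording spans {recording.duration:.3f} s < "
            f"{cycle_index}/{frequency} s needed for cycle {cycle_index}"
        )
    t = recording.time
    load = recording.load
    period = 1.0 / frequency
    t0_nominal = t[0] + (cycle_index - 1) * period

    # dominant-frequency sanity check
    if len(load) > 16:
        spec = np.abs(np.fft.rfft(load - load.mean()))
        freqs = np.fft.rfftfreq(len(load), d=float(np.median(np.diff(t))))
        f_dom = freqs[int(np.argmax(spec))]
        if abs(f_dom - frequency) > 0.1 * frequency:
            warnings.warn(
                f"dominant load frequency {f_dom:.3f} Hz differs from the "
                f"declared {frequency} Hz; load may not be periodic",
                ProtocolWarning,
                stacklevel=2,
            )

    # rising zero-crossings of the load channel near the nominal start
    window = (t >= t0_nominal - 0.5 * period) & (t <= t0_nominal + 0.5 * period)
    idx = np.flatnonzero(window)
    start = None
    if idx.size:
        lo, hi = idx[0], min(idx[-1] + 1, len(load) - 1)
        seg = slice(lo, hi)
        cross = np.flatnonzero((load[lo:hi] <= 0) & (load[lo + 1 : hi + 1] > 0)) + lo
        if cross.size:
            # sample-level start: the crossing sample itself if it sits at
            # zero, else the first positive sample after it
            cands = np.where(load[cross] == 0.0, cross, cross + 1)
            start = int(cands[np.argmin(np.abs(t[cands] - t0_nominal))])
    if start is None:  # offset load: fall back to minimum-load sample
        fallback = idx if idx.size else np.arange(len(load))
        start = int(fallback[np.argmin(load[fallback])])

    t_end = t[start] + period
    sel = (t >= t[start] - 1e-12) & (t <= t_end + 1e-9)
    mode = "torsional" if recording.deformation_unit == "rad" else "axial"
    return HysteresisLoop(
        deformation=recording.deformation[sel],
        load=load[sel],
        mode=mode,
        cycle_index=cycle_index,
    )


# ---------------------------------------------------------------------------
# branch bookkeeping

def _branches(loop: HysteresisLoop):
    """Split the loop at its deformation extremes.

    Returns (loading, unloading) index arrays: loading runs from the minimum
    to the maximum deformation (increasing), unloading back down.  Ties are
    broken by first occurrence.  The loop is treated as cyclic.
    """
    d = loop.deformation
    n = len(d)
    imin = int(np.argmin(d))
    imax = int(np.argmax(d))
    order = np.roll(np.arange(n), -imin)
    pos = int(np.flatnonzero(order == imax)[0])
    loading = order[: pos + 1]
    unloading = np.concatenate([order[pos:], order[:1]])
    return loading, unloading


def _fit_line(x, y):
    if len(x) < 3:
        raise ProtocolMismatchError(
            f"only {len(x)} samples in the fit window; cannot fit a line"
        )
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


_SMOOTH_SAMPLES = 11  # selection smoother for the noisy torque channel


def _branch_smooth(y, n=_SMOOTH_SAMPLES):
    """Centered moving average along a branch with renormalized edges.

    Used only to *select* fit windows on the noisy torque channel; the line
    fits themselves always use the raw samples, so the smoother cannot bias
    a slope — it only stabilizes which samples enter the window.
    """
    if len(y) < n:
        return y
    kernel = np.ones(n)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y), kernel, mode="same")
    return num / den


def _masked_line(x, y, mask, fallback_mask=None):
    if mask.sum() < 3 and fallback_mask is not None:
        mask = fallback_mask
    if mask.sum() < 3:
        raise ProtocolMismatchError("too few samples in torsional fit window")
    return _fit_line(x[mask], y[mask])


def _limb_fit_torsional(rotation, torque, torque_smooth, wf, sign):
    """One torsional limb line over the extreme ``wf`` of its torque range.

    ``sign`` +1 selects the positive (clockwise) limb, -1 the negative one.
    The window threshold anchors on the raw torque extreme (exact on clean
    loops; under noise the inflated extreme only shrinks the window, never
    drags middle-zone samples in) and selection applies to the smoothed
    torque so single noisy samples cannot enter or leave the window.
    Returns (slope, intercept, predicted torque at the rotation extreme).
    """
    s_tq = sign * torque
    s_sm = sign * torque_smooth
    threshold = (1 - wf) * s_tq.max()
    mask = s_sm >= threshold
    slope, intercept = _masked_line(
        rotation, torque, mask, fallback_mask=s_sm >= (1 - wf) * s_sm.max()
    )
    theta_ext = rotation[np.argmax(sign * rotation)]
    return slope, intercept, float(slope * theta_ext + intercept)


def _interp_on_branch(x, y, targets):
    """Interpolate y at x=targets along a branch, sorting by x."""
    order = np.argsort(x, kind="stable")
    return np.interp(targets, x[order], y[order])


def _nz_intersection(center_line, pos_line, neg_line):
    """Dual-line NZ: deformation span between the intersections of the
    central low-stiffness line with the two limb lines.

    All three lines are (slope, intercept) pairs in deformation-on-load
    space (axial) or load-on-deformation space (torsional); in either space
    the span of the independent variable converts to a deformation span by
    the central slope (axial) or directly (torsional).
    """
    c, c0 = center_line
    out = []
    for slope, intercept in (pos_line, neg_line):
        if c == slope:
            return np.nan
        out.append((intercept - c0) / (c - slope))
    return out[0], out[1]


def _loop_metrics(loop: HysteresisLoop, cfg: PipelineConfig,
                  load_limit: float | None) -> LoopMetrics:
    axial = loop.mode == "axial"
    load = loop.load
    d = loop.deformation
    if load.max() <= 0 or load.min() >= 0:
        raise ProtocolMismatchError("load channel must span both signs")
    if load_limit is not None:
        attained = min(load.max(), -load.min())
        if attained < 0.95 * load_limit:
            raise PartialProtocolError(
                f"load never reached ±{load_limit}; attained "
                f"[{load.min():.4g}, {load.max():.4g}]",
                attained_min=float(load.min()),
                attained_max=float(load.max()),
            )

    loading, unloading = _branches(loop)
    wf = cfg.stiffness_window_fraction
    lmax, lmin = load.max(), load.min()

    if axial:
        pos_mask = load[loading] >= (1 - wf) * lmax
        neg_mask = load[loading] <= (1 - wf) * lmin
        if pos_mask.sum() < 3 or neg_mask.sum() < 3:
            raise ProtocolMismatchError("too few samples in a stiffness window")
        # compliance regressions d ~ F (load is the clean controlled channel)
        pos_line = _fit_line(load[loading][pos_mask], d[loading][pos_mask])
        neg_line = _fit_line(load[loading][neg_mask], d[loading][neg_mask])
        if pos_line[0] == 0 or neg_line[0] == 0:
            raise ProtocolMismatchError("flat limb: zero compliance slope")
        stiff_pos = 1.0 / pos_line[0]
        stiff_neg = 1.0 / neg_line[0]
        amplitude = (lmax - lmin) / 2.0
    else:
        rot_l, tq_l = d[loading], load[loading]
        tq_sm = _branch_smooth(tq_l)
        slope_pos, int_pos, tmax_hat = _limb_fit_torsional(rot_l, tq_l, tq_sm, wf, +1)
        slope_neg, int_neg, tmin_hat = _limb_fit_torsional(rot_l, tq_l, tq_sm, wf, -1)
        stiff_pos, stiff_neg = slope_pos, slope_neg
        # amplitude from the limb-line predictions at the rotation extremes:
        # unbiased under torque noise, exact on clean piecewise-linear loops
        amplitude = (tmax_hat - tmin_hat) / 2.0

    # range of motion between the attained load limits, loading branch
    rom = float(
        _interp_on_branch(load[loading], d[loading], [lmax])[0]
        - _interp_on_branch(load[loading], d[loading], [lmin])[0]
    )

    # neutral zone, averaged over branches
    thr = cfg.nz_fraction * amplitude
    spans = []
    for idx in (loading, unloading):
        if axial:
            mask = np.abs(load[idx]) <= thr
            if mask.sum() < 3:
                raise ProtocolMismatchError("too few samples in the neutral zone")
            center = _fit_line(load[idx][mask], d[idx][mask])
            if cfg.nz_method == "intersection":
                f_pos, f_neg = _nz_intersection(center, pos_line, neg_line)
                spans.append(abs(center[0] * (f_pos - f_neg)))
            else:
                spans.append(abs(2.0 * thr * center[0]))
        else:
            smooth = _branch_smooth(load[idx])
            center = _masked_line(
                d[idx], load[idx], np.abs(smooth) <= thr,
                fallback_mask=np.abs(load[idx]) <= thr,
            )
            if center[0] == 0:
                raise ProtocolMismatchError("flat neutral zone: zero slope")
            if cfg.nz_method == "intersection":
                th_pos, th_neg = _nz_intersection(
                    center, (slope_pos, int_pos), (slope_neg, int_neg)
                )
                spans.append(abs(th_pos - th_neg))
            else:
                spans.append(abs(2.0 * thr / center[0]))
    nz = float(np.mean(spans))

    return LoopMetrics(
        stiffness_positive=float(stiff_pos),
        stiffness_negative=float(abs(stiff_neg)),
        stiffness_mean=(float((stiff_pos + abs(stiff_neg)) / 2.0)
                        if not axial else None),
        range_of_motion=rom,
        neutral_zone_length=nz,
        load_range=float(lmax - lmin),
        mode=loop.mode,
    )


def axial_metrics(
    loop: HysteresisLoop,
    cfg: PipelineConfig | None = None,
    load_limit: float | None = None,
) -> LoopMetrics:
    """Stiffnesses, ROM, neutral zone and load range of an axial loop.

    ``stiffness_positive`` is the tensile limb, ``stiffness_negative`` the
    compressive limb (reported as a positive number).  ``load_limit`` (N),
    when given, asserts the protocol amplitude was reached.
    """
    if loop.mode != "axial":
        raise ProtocolMismatchError("axial_metrics requires an axial loop")
    return _loop_metrics(loop, cfg or PipelineConfig(), load_limit)


def torsional_metrics(
    loop: HysteresisLoop,
    cfg: PipelineConfig | None = None,
    load_limit: float | None = None,
) -> LoopMetrics:
    """Torsional loop metrics; ``stiffness_mean`` averages the CW/CCW limbs."""
    if loop.mode != "torsional":
        raise ProtocolMismatchError("torsional_metrics requires a torsional loop")
    return _loop_metrics(loop, cfg or PipelineConfig(), load_limit)
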
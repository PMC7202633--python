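"""Failure strength and angle-to-failure from a torsion-to-failure ramp.

The protocol rotates the motion segment at 1°/s until it fails.  Failure
strength is the maximum of the (optionally smoothed) torque signal and
angle-to-failure is the rotation at that maximum — a deterministic surrogate
for picking the peak off the loading profile by eye.  A specimen only counts
as *failed* when the torque subsequently drops by at least ``drop_fraction``
of the peak; otherwise the ramp was truncated before failure and the metrics
are reported as censored (``failed=False``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .errors import DegenerateInputError, ProtocolMismatchError
from .recording import TimeSeriesRecording

__all__ = ["FailureMetrics", "detect_failure"]


@dataclass(frozen=True)
class FailureMetrics:
    """Peak torque (N·m), rotation at the peak (rad) and the failure flag.

    ``post_peak_drop_fraction`` is the observed fractional torque loss after
    the peak; ``failed`` is True when it reaches the configured threshold.
    """

    failure_strength: float
    angle_to_failure: float
    failed: bool
    post_peak_drop_fraction: float


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    # normalized edges: divide by the actual number of samples in the window
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def detect_failure(
    recording: TimeSeriesRecording,
    cfg: PipelineConfig | None = None,
) -> FailureMetrics:
    """Locate the torque peak of a monotone rotation ramp.

    The rotation channel must be a monotone ramp (small servo jitter is
    tolerated: back-steps up to 1% of the rotation range).  Smoothing is a
    centered moving average of ``cfg.smoothing_window_s`` seconds at the
    recording's sampling rate; set it to 0 for raw-peak mode.

    Raises
    ------
    ProtocolMismatchError : rotation is not monotone beyond tolerance.
    DegenerateInputError : torque channel is identically zero.
    """
    cfg = cfg or PipelineConfig()
    theta = recording.deformation
    torque = recording.load
    if len(theta) < 3:
        raise DegenerateInputError("ramp too short to analyze")
    rot_range = float(np.ptp(theta))
    if rot_range == 0:
        raise ProtocolMismatchError("rotation channel is constant; not a ramp")
    back_steps = np.diff(theta)
    if np.any(back_steps < -0.01 * rot_range):
        raise ProtocolMismatchError(
            "rotation channel is non-monotone beyond servo-jitter tolerance"
        )
    if np.all(torque == 0):
        raise DegenerateInputError("torque channel is identically zero")

    fs = recording.sampling_rate or 1.0 / float(np.median(np.diff(recording.time)))
    window = int(round(cfg.smoothing_window_s * fs))
    if window % 2 == 0:
        window += 1  # keep the average centered
    smoothed = _moving_average(torque, max(window, 1))

    peak = int(np.argmax(smoothed))
    strength = float(smoothed[peak])
    if strength <= 0:
        raise DegenerateInputError("peak torque is not positive")
    after = smoothed[peak:]
    drop = float((strength - after.min()) / strength) if after.size else 0.0
    return FailureMetrics(
        failure_strength=strength,
        angle_to_failure=float(theta[peak]),
        failed=drop >= cfg.drop_fraction,
        post_peak_drop_fraction=drop,
    )
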
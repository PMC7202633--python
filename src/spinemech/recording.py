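"""Time-series recordings of mechanical tests and their delimited-text I/O.

A recording holds one test segment for one specimen: a time channel, a load
channel (force in N or torque in N·m) and a deformation channel (displacement
in mm or rotation in rad).  Files are plain CSV/TSV with a header row naming
the columns; metadata (units, test kind, specimen id, protocol limits) is
declared in ``# key: value`` comment lines at the top of the file or passed
explicitly, never guessed.  Rotations declared in degrees are converted to
radians on read.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import RecordingParseError

LOAD_UNITS = {"N", "Nm"}
DEFORMATION_UNITS = {"mm", "rad"}
_DEGREE_ALIASES = {"deg", "degree", "degrees", "°"}

_TIME_NAMES = {"time", "t", "time_s", "seconds"}
_LOAD_NAMES = {"load", "force", "torque", "force_n", "torque_nm"}
_DEFORMATION_NAMES = {
    "deformation", "displacement", "disp", "rotation", "angle",
    "displacement_mm", "rotation_rad", "rotation_deg",
}

TEST_KINDS = {"axial_cyclic", "creep", "torsional_cyclic", "torsion_to_failure"}


@dataclass
class TimeSeriesRecording:
    """Sampled channels of one mechanical test segment.

    Parameters
    ----------
    time : array of sample times, seconds, strictly increasing.
    load : force (N) or torque (N·m) channel.
    deformation : displacement (mm) or rotation (rad) channel.
    load_unit, deformation_unit : declared units, from {"N", "Nm"} and
        {"mm", "rad"}.
    specimen_id, test_kind : provenance labels; ``test_kind`` is one of
        ``axial_cyclic | creep | torsional_cyclic | torsion_to_failure`` or
        ``None`` when unknown.
    sampling_rate : Hz; inferred from the median time step when omitted.
    metadata : free-form protocol annotations (limits, failure location, ...).
    """

    time: np.ndarray
    load: np.ndarray
    deformation: np.ndarray
    load_unit: str = "N"
    deformation_unit: str = "mm"
    specimen_id: str | None = None
    test_kind: str | None = None
    sampling_rate: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.load = np.asarray(self.load, dtype=float)
        self.deformation = np.asarray(self.deformation, dtype=float)
        if not (self.time.ndim == self.load.ndim == self.deformation.ndim == 1):
            raise RecordingParseError("channels must be one-dimensional")
        if not (len(self.time) == len(self.load) == len(self.deformation)):
            raise RecordingParseError(
                f"channel lengths differ: time={len(self.time)}, "
                f"load={len(self.load)}, deformation={len(self.deformation)}"
            )
        if len(self.time) >= 2 and not np.all(np.diff(self.time) > 0):
            raise RecordingParseError("time channel must be strictly increasing")
        if self.load_unit not in LOAD_UNITS:
            raise RecordingParseError(
                f"load unit {self.load_unit!r} not in {sorted(LOAD_UNITS)}"
            )
        if self.deformation_unit not in DEFORMATION_UNITS:
            raise RecordingParseError(
                f"deformation unit {self.deformation_unit!r} not in "
                f"{sorted(DEFORMATION_UNITS)}"
            )
        if self.test_kind is not None and self.test_kind not in TEST_KINDS:
            raise RecordingParseError(f"unknown test kind {self.test_kind!r}")
        if self.sampling_rate is None and len(self.time) >= 2:
            self.sampling_rate = 1.0 / float(np.median(np.diff(self.time)))

    def __len__(self):
        return len(self.time)

    @property
    def duration(self) -> float:
        """Time span covered by the recording, seconds."""
        if len(self.time) == 0:
            return 0.0
        return float(self.time[-1] - self.time[0])


def read_recording(
    path,
    *,
    load_unit: str | None = None,
    deformation_unit: str | None = None,
    specimen_id: str | None = None,
    test_kind: str | None = None,
    max_nan_fraction: float = 0.01,
) -> TimeSeriesRecording:
    """Read a delimited time-series file into a validated recording.

    Units may be declared either in ``# load_unit: N`` style comment lines in
    the file header or via keyword arguments (arguments win).  A declared
    degree unit is converted to radians.  NaN fractions above
    ``max_nan_fraction`` per channel are a parse error; isolated NaNs below
    that are linearly interpolated.
    """
    meta: dict = {}
    header_lines = 0
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    for line in text.splitlines():
        if not line.startswith("#"):
            break
        header_lines += 1
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, value = body.partition(":")
            meta[key.strip().lower()] = value.strip()

    body_lines = text.splitlines()[header_lines:]
    if not body_lines:
        raise RecordingParseError(f"{path}: file has no data rows")
    sep = "\t" if "\t" in body_lines[0] else ","
    try:
        df = pd.read_csv(io.StringIO(text), sep=sep, comment="#",
                         float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise RecordingParseError(f"{path}: cannot parse delimited text: {exc}") from exc

    cols = {c.strip().lower(): c for c in df.columns}

    def _find(names, role):
        for name in names:
            if name in cols:
                return cols[name]
        raise RecordingParseError(
            f"{path}: no {role} column among {list(df.columns)}"
        )

    tcol = _find(_TIME_NAMES, "time")
    lcol = _find(_LOAD_NAMES, "load")
    dcol = _find(_DEFORMATION_NAMES, "deformation")

    def _channel(col):
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        n_nan = int(np.isnan(vals).sum())
        if n_nan:
            if n_nan > max_nan_fraction * len(vals):
                raise RecordingParseError(
                    f"{path}: column {col!r} has {n_nan}/{len(vals)} NaNs "
                    f"(> {max_nan_fraction:.0%} allowed)"
                )
            idx = np.arange(len(vals))
            ok = ~np.isnan(vals)
            vals = np.interp(idx, idx[ok], vals[ok])
        return vals

    lu = load_unit or meta.get("load_unit")
    du = deformation_unit or meta.get("deformation_unit")
    if lu is None or du is None:
        raise RecordingParseError(
            f"{path}: units must be declared (header comments or arguments); "
            f"got load_unit={lu!r}, deformation_unit={du!r}"
        )
    lu = lu.replace("·", "").replace("*", "").replace("N.m", "Nm").strip()
    du = du.strip()

    deformation = _channel(dcol)
    if du.lower() in _DEGREE_ALIASES:
        deformation = deformation * math.pi / 180.0
        du = "rad"

    sid = specimen_id or meta.get("specimen") or meta.get("specimen_id")
    kind = test_kind or meta.get("kind") or meta.get("test_kind")
    extra = {
        k: v
        for k, v in meta.items()
        if k not in {"load_unit", "deformation_unit", "specimen", "specimen_id",
                     "kind", "test_kind"}
    }
    return TimeSeriesRecording(
        time=_channel(tcol),
        load=_channel(lcol),
        deformation=deformation,
        load_unit=lu,
        deformation_unit=du,
        specimen_id=sid,
        test_kind=kind,
        metadata=extra,
    )


def write_recording(recording: TimeSeriesRecording, path) -> None:
    """Write a recording as commented-header CSV, full float precision."""
    dname = "displacement" if recording.deformation_unit == "mm" else "rotation"
    lname = "force" if recording.load_unit == "N" else "torque"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if recording.specimen_id is not None:
            fh.write(f"# specimen: {recording.specimen_id}\n")
        if recording.test_kind is not None:
            fh.write(f"# kind: {recording.test_kind}\n")
        fh.write(f"# load_unit: {recording.load_unit}\n")
        fh.write(f"# deformation_unit: {recording.deformation_unit}\n")
        for key, value in sorted(recording.metadata.items()):
            fh.write(f"# {key}: {value}\n")
        fh.write(f"time,{lname},{dname}\n")
        for t, f, d in zip(recording.time, recording.load, recording.deformation):
            fh.write(f"{float(t)!r},{float(f)!r},{float(d)!r}\n")
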
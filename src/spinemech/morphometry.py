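"""Disc height index and histomorphometric ratios.

The disc height index (DHI) compares intervertebral disc height between
animals of different body size: three disc-height measurements across the
disc are summed and divided by the sum of three length measurements on the
adjacent vertebra,

    DHI = (DH1 + DH2 + DH3) / (A1 + A2 + A3)

Histomorphometry reduces manually outlined areas and manually counted cells
to two ratios: the notochordal band area as a percentage of the nucleus
pulposus area, and the cell density normalized to the area counted.
Landmarking, outlining and counting are upstream manual steps; this module
takes their numeric output.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DegenerateInputError, InvalidMeasurementError

__all__ = [
    "DHIMeasurement",
    "HistoAreas",
    "compute_dhi",
    "notochordal_band_fraction",
    "cell_density",
]


def compute_dhi(disc_heights, vertebral_lengths) -> float:
    """Disc height index from three disc-height and three vertebral-length
    measurements (mm).  Dimensionless; invariant to a common scale factor
    and to permutations within each triple."""
    dh = tuple(float(v) for v in disc_heights)
    a = tuple(float(v) for v in vertebral_lengths)
    if len(dh) != 3 or len(a) != 3:
        raise InvalidMeasurementError("DHI needs exactly three measurements per triple")
    if any(v <= 0 for v in dh + a):
        raise InvalidMeasurementError("all DHI inputs must be strictly positive")
    return sum(dh) / sum(a)


@dataclass(frozen=True)
class DHIMeasurement:
    """One specimen's landmark-derived heights/lengths and the resulting DHI."""

    disc_heights: tuple
    vertebral_lengths: tuple
    dhi: float = None

    def __post_init__(self):
        object.__setattr__(self, "disc_heights", tuple(self.disc_heights))
        object.__setattr__(self, "vertebral_lengths", tuple(self.vertebral_lengths))
        object.__setattr__(
            self, "dhi", compute_dhi(self.disc_heights, self.vertebral_lengths)
        )


@dataclass(frozen=True)
class HistoAreas:
    """Outlined areas (mm²) and cell count for one mid-sagittal section."""

    notochordal_band_area: float
    np_area: float
    cell_count: int
    counted_area: float

    def __post_init__(self):
        if self.np_area < 0 or self.notochordal_band_area < 0:
            raise InvalidMeasurementError("areas must be non-negative")
        if self.notochordal_band_area > self.np_area:
            raise InvalidMeasurementError(
                "notochordal band cannot exceed the NP that contains it"
            )
        if self.counted_area <= 0:
            raise InvalidMeasurementError("counted_area must be positive")
        if self.cell_count < 0:
            raise InvalidMeasurementError("cell_count must be non-negative")


def notochordal_band_fraction(areas: HistoAreas) -> float:
    """Notochordal band area as a percentage of NP area, in [0, 100]."""
    if areas.np_area == 0:
        raise DegenerateInputError("NP area is zero")
    return 100.0 * areas.notochordal_band_area / areas.np_area


def cell_density(cell_count: int, counted_area: float) -> float:
    """Cells per mm²: manual count normalized to the area counted."""
    if counted_area <= 0:
        raise DegenerateInputError("counted area must be positive")
    if cell_count < 0:
        raise InvalidMeasurementError("cell count must be non-negative")
    return cell_count / counted_area
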
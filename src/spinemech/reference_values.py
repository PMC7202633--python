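"""Published group means ± SDs used as default sampling distributions.

Keys are (sex, genotype, diet) with sex in {"female", "male"}, genotype in
{"Control", "DbDb"} and diet in {"CD", "WD"}.  Each entry maps an outcome
name to (mean, sd).  Mechanics outcomes (stiffnesses N/mm, displacements mm,
time constants s, torsional quantities N·m·rad⁻¹ / N·m / rad) parameterize
the recording generator; morphometry outcomes (notochordal band % of NP,
cells/mm², vertebral length mm, disc height mm, DHI) are sampled directly
into the outcome table.
"""

from __future__ import annotations

SEXES = ("female", "male")
GENOTYPES = ("Control", "DbDb")
DIETS = ("CD", "WD")

# Table of biomechanical group values: row order per cell —
# (compressive_stiffness, tensile_stiffness, rom, neutral_zone, tau1, tau2,
#  k0, k1, k2, torsional_stiffness, failure_strength, angle_to_failure,
#  torque_range, torsional_neutral_zone)
_MECH_KEYS = (
    "compressive_stiffness", "tensile_stiffness", "rom", "neutral_zone",
    "tau1", "tau2", "k0", "k1", "k2", "torsional_stiffness",
    "failure_strength", "angle_to_failure", "torque_range",
    "torsional_neutral_zone",
)

_MECH = {
    ("female", "Control", "CD"): [
        (16.59, 4.98), (9.15, 3.89), (0.19, 0.04), (0.07, 0.03),
        (51.71, 27.13), (739.0, 255.8), (11.66, 2.47), (12.64, 2.00),
        (3.15, 0.94), (0.016, 0.004), (0.005, 0.002), (1.013, 0.246),
        (0.003, 0.001), (0.39, 0.04),
    ],
    ("female", "DbDb", "CD"): [
        (14.32, 3.65), (12.10, 4.10), (0.19, 0.03), (0.05, 0.02),
        (54.75, 12.16), (900.8, 92.1), (12.56, 2.39), (14.94, 2.73),
        (2.75, 0.31), (0.014, 0.004), (0.003, 0.001), (0.664, 0.145),
        (0.003, 0.001), (0.37, 0.03),
    ],
    ("female", "Control", "WD"): [
        (15.68, 3.09), (11.61, 4.12), (0.17, 0.02), (0.06, 0.02),
        (41.85, 13.84), (707.7, 242.7), (13.06, 3.11), (17.53, 4.44),
        (3.31, 0.50), (0.020, 0.005), (0.007, 0.001), (1.10, 0.218),
        (0.004, 0.002), (0.39, 0.04),
    ],
    ("female", "DbDb", "WD"): [
        (17.38, 3.68), (13.31, 6.77), (0.20, 0.03), (0.07, 0.02),
        (37.68, 16.55), (669.0, 194.4), (13.08, 3.18), (15.10, 3.43),
        (3.12, 0.79), (0.010, 0.005), (0.004, 0.001), (0.69, 0.201),
        (0.003, 0.002), (0.40, 0.07),
    ],
    ("male", "Control", "CD"): [
        (19.05, 5.08), (12.81, 4.17), (0.17, 0.04), (0.06, 0.02),
        (45.13, 9.83), (724.7, 182.8), (14.65, 4.19), (17.01, 6.96),
        (3.27, 0.93), (0.020, 0.004), (0.005, 0.001), (0.87, 0.212),
        (0.003, 0.002), (0.34, 0.06),
    ],
    ("male", "DbDb", "CD"): [
        (18.95, 3.81), (12.06, 4.40), (0.18, 0.05), (0.07, 0.03),
        (41.79, 21.00), (746.2, 134.8), (16.57, 3.91), (19.44, 9.51),
        (3.73, 0.93), (0.010, 0.005), (0.004, 0.001), (1.05, 0.332),
        (0.003, 0.001), (0.38, 0.08),
    ],
    ("male", "Control", "WD"): [
        (18.83, 7.42), (11.92, 4.15), (0.16, 0.04), (0.06, 0.02),
        (32.51, 14.78), (453.1, 37.8), (16.03, 4.53), (27.17, 10.17),
        (4.08, 0.97), (0.018, 0.007), (0.007, 0.001), (0.889, 0.300),
        (0.004, 0.002), (0.36, 0.07),
    ],
    ("male", "DbDb", "WD"): [
        (17.32, 4.54), (11.84, 3.52), (0.18, 0.04), (0.07, 0.02),
        (53.22, 20.41), (806.0, 171.8), (14.12, 3.02), (17.22, 5.31),
        (2.99, 0.89), (0.012, 0.006), (0.005, 0.001), (1.185, 0.421),
        (0.003, 0.001), (0.39, 0.04),
    ],
}

# Morphometry group values: (notochordal band % of NP, cells per mm²,
# vertebral length mm, disc height mm, DHI)
_MORPH_KEYS = ("noto_band_fraction", "cells_per_mm2", "vertebral_length",
               "ivd_height", "dhi")

_MORPH = {
    ("female", "Control", "CD"): [(23.77, 14.06), (9977, 2517), (2.965, 0.084),
                                  (0.307, 0.031), (0.103, 0.010)],
    ("female", "DbDb", "CD"): [(49.24, 23.92), (2752, 907), (2.848, 0.143),
                               (0.310, 0.010), (0.109, 0.007)],
    ("female", "Control", "WD"): [(16.05, 5.52), (9275, 2230), (3.079, 0.155),
                                  (0.333, 0.038), (0.108, 0.009)],
    ("female", "DbDb", "WD"): [(50.53, 19.95), (4378, 2874), (2.729, 0.214),
                               (0.308, 0.010), (0.116, 0.013)],
    ("male", "Control", "CD"): [(16.47, 6.29), (6952, 1390), (3.077, 0.085),
                                (0.323, 0.018), (0.105, 0.006)],
    ("male", "DbDb", "CD"): [(19.39, 7.15), (5385, 2325), (2.889, 0.117),
                             (0.311, 0.036), (0.108, 0.010)],
    ("male", "Control", "WD"): [(17.17, 3.989), (8633, 3538), (3.179, 0.134),
                                (0.357, 0.022), (0.112, 0.007)],
    ("male", "DbDb", "WD"): [(22.38, 8.954), (5762, 2597), (3.127, 0.081),
                             (0.325, 0.016), (0.104, 0.004)],
}

MECHANICS_DISTRIBUTIONS = {
    cell: dict(zip(_MECH_KEYS, vals)) for cell, vals in _MECH.items()
}
MORPHOMETRY_DISTRIBUTIONS = {
    cell: dict(zip(_MORPH_KEYS, vals)) for cell, vals in _MORPH.items()
}

MECHANICS_OUTCOMES = _MECH_KEYS
MORPHOMETRY_OUTCOMES = _MORPH_KEYS
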
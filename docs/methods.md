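# Methods

This note documents the models, estimators, numerical choices and known
limitations of spinemech, in the order the pipeline runs them.

## Creep: 5-parameter viscoelastic solid

The creep response of a motion segment to a compressive step load *F* is
modelled as a spring (elastic stiffness *k₀*, N/mm) in series with two
Kelvin–Voigt arms — springs *k₁*, *k₂* (N/mm) with time constants *τ₁*, *τ₂*
(s):

    d(t) = F/k₀ + (F/k₁)(1 − e^(−t/τ₁)) + (F/k₂)(1 − e^(−t/τ₂))

Arms are labelled so that *τ₁ < τ₂* (fast response first); the constructor
sorts them, which also makes the fit invariant to the τ₁/τ₂ exchange
symmetry. Derived quantities use the **asymptotic convention**: elastic
displacement *F/k₀*, creep displacement *F(1/k₁ + 1/k₂)* (the t → ∞ limit,
not the 45-minute value), total displacement their sum. The asymptotic
convention is the only one under which the closed-form identities reproduce
published group tables of this assay within rounding.

**Fitting.** Nonlinear least squares (`scipy.optimize.least_squares`, trf)
in log-parameter space, which removes the positivity constraints, with an
analytic Jacobian. Multi-start over a deterministic grid: τ₁ ∈ {10, 60} s ×
τ₂ ∈ {300, 1500} s × two splits of the creep compliance between the arms,
with stiffness starts seeded from endpoint heuristics (*k₀ ≈ F/d(0)*, creep
compliance ≈ (d(end) − d(0))/F). Bounds τ ∈ [0.1, 10⁵] s, k ∈ [10⁻³, 10⁴]
N/mm; tolerances 10⁻¹⁴ on cost, step and gradient. The best start by cost
wins. Additional jittered restarts (seeded, configurable via
`PipelineConfig.fit_seed`) only occur beyond the 8 deterministic starts, so
default fits are seed-independent.

**Ramp handling.** Samples before the load reaches 95% of the target step
are trimmed and time is re-zeroed at the first retained sample; creep models
assume a step, and data logged during the loading ramp would otherwise bias
τ₁. After trimming, the load channel must be constant within 5% RMS of the
step or the segment is rejected as a protocol mismatch. Identifiability
needs roughly ≥ 50 samples spanning several τ₁; shorter segments warn but
are fitted.

## Cyclic hysteresis loops

`extract_cycle` takes the nominal window [(i−1)/f, i/f] of the designated
cycle (default: the 20th, after 19 preconditioning cycles) and re-phases its
start to the rising zero-crossing of the load channel nearest the window
start; if the load never crosses zero (offset load) it falls back to the
minimum-load sample. A loop must have ≥ 40 samples; loops whose endpoints
differ by more than 5% of the channel spans warn (sensor noise can open a
small gap at the low torque amplitudes of this assay, so closure is a
warning, not an error). A dominant-frequency check warns when the load
channel's spectral peak is more than 10% away from the declared frequency.

Branches split at the deformation extremes (ties by first occurrence):
loading runs from minimum to maximum deformation, unloading back.

Definitions (all window fractions configurable in `PipelineConfig`):

* **Limb stiffness** — slope of a line fitted on the loading branch over the
  extreme 20% of the load range per limb (tension/clockwise and
  compression/counterclockwise). Reported positive.
* **Range of motion** — deformation at the attained +limit minus deformation
  at the attained −limit, interpolated on the loading branch.
* **Neutral zone** — deformation span over which |load| ≤ 10% of the load
  amplitude, computed from a line fitted to the central zone and averaged
  over the loading and unloading branches. A dual-line intersection variant
  (central line vs limb lines) is available via `nz_method="intersection"`.
* **Load range** — max − min of the raw load channel over the loop.
* **Torsional stiffness** — mean of the clockwise and counterclockwise limb
  slopes.

**Regression direction.** Fits always use the servo-controlled channel as
the regressor: load for the force-controlled axial test (the line is a
compliance, inverted to a stiffness), rotation for the rotation-controlled
torsional test. Regressing on the noisy measured channel instead would
attenuate slopes (errors-in-variables); with the controlled channel as
regressor the estimates are unbiased under additive response noise.

**Window selection at low torque SNR.** The torsional torque amplitude of
murine caudal segments (≈ 1.5 mN·m) is only ~15× the bench torque noise, so
thresholding raw samples to pick fit windows would randomly admit or exclude
samples near the window boundaries. Selection therefore applies to a short
(11-sample) centered moving average of the torque, while the line fits
themselves always use raw samples — the smoother decides only *which*
samples enter a window and cannot bias a slope. Limb windows anchor on the
raw torque extreme: on clean data this is exact, and under noise the
slightly inflated extreme only shrinks the window within the linear limb,
never drags in central-zone samples. The neutral-zone threshold uses the
amplitude predicted by the limb lines at the rotation extremes, which is
unbiased, rather than the noise-inflated raw extremes.

On exactly linear limbs every definition reduces to the two-point slope, and
on the generator's piecewise-linear loops all metrics recover the generating
truth to machine precision (tested at 10⁻⁹ relative).

## Torsion-to-failure

Failure strength is the maximum of the torque signal after an optional
centered moving average (default window 0.5 s at the declared sampling rate;
0 disables smoothing), and angle-to-failure is the rotation at that maximum —
a deterministic surrogate for reading the peak off the curve by eye. A
specimen is *failed* only if the torque subsequently drops by ≥ 20% of the
peak; otherwise the ramp is treated as truncated and the metrics are
censored. The rotation channel must be monotone within 1% of its range
(servo jitter tolerance). Where the segment failed (growth plate vs disc) is
a manual annotation passed through metadata, never inferred from the signal.

## Morphometry

DHI = (DH₁+DH₂+DH₃)/(A₁+A₂+A₃) from three disc-height and three
vertebral-length measurements; notochordal band fraction = 100 × band
area / NP area; cell density = count / counted area. Landmarking, outlining
and counting are upstream manual steps — the module validates and reduces
their numeric output (positivity, band ⊆ NP, non-zero areas) and is exactly
scale-invariant / permutation-symmetric where the definitions imply it.

## Group statistics

Per sex (a stratifier, never a factor): fixed-effects 2×2 ANOVA with
interaction via `statsmodels` OLS, Type II sums of squares by default (equal
to Type I on balanced designs; appropriate for the mildly unbalanced cell
counts of animal cohorts), α = 0.05, no multiplicity correction across
outcomes. Cells must be non-empty with ≥ 2 observations. When the residual
variance is numerically zero, F and p are reported as limit values (F = 0,
p = 1 for null effects; F = ∞, p = 0 otherwise) with an exact-separation
warning. Tukey HSD all-pairs adjusted p values come from
`scipy.stats.tukey_hsd` (studentized-range distribution, Tukey–Kramer for
unequal n); the test suite checks them against an independent permutation
max-|t| reference and verifies the F = t² identity on collapsed two-group
data.

## Synthetic data

The generator inverts the analysis operators so that every stage can be
exercised without raw data.

* **Protocols** default to the bench protocol: ±0.5 N at 1 Hz × 20 cycles;
  0.5 N × 45 min creep; ±10° at 1 Hz × 20 cycles; 1°/s failure ramp.
  Sampling rates are the package's choice: 1000 Hz for the cyclic tests
  (typical logging for a 1 Hz protocol, and enough samples in the 20%
  stiffness windows at realistic noise), 10 Hz for creep, 100 Hz for the
  ramp.
* **Cyclic loops** are piecewise-linear in load–deformation space: limbs at
  the truth stiffnesses over the stiffness windows, a central zone spanning
  exactly the truth neutral zone over the NZ threshold band, and a middle
  segment chosen so the end-to-end span equals the truth ROM. Under the
  default analyzer definitions the clean loop therefore analyzes back to the
  truth exactly. A smooth tanh-blended alternative (`loop_shape="sigmoid"`)
  is a genuinely different functional form for robustness testing; recovery
  on it is approximate by design.
* **Creep** recordings follow the forward model (optionally with a
  quasi-static loading ramp); **failure** ramps rise linearly to the truth
  peak and drop by a configured fraction (default 50%) over 30% of the
  failure angle.
* **Noise** is additive white Gaussian on the measured (response) channel
  only — displacement 0.002 mm, torque 10⁻⁴ N·m, with force 0.005 N and
  rotation 0.001 rad available for completeness. These are plausible bench
  values, not study-derived; the servo-controlled channel is clean. Real
  sensor noise is neither white nor purely additive, and real loops have
  hysteresis the zero-loss generator lacks — so passing round-trip tests
  demonstrates correctness of the estimators under the stated model, not
  robustness to every bench artifact.
* **Cohorts** draw per-specimen truths from published group means ± SDs via
  normals truncated below at 0.05 × mean (`scipy.stats.truncnorm`). Draws
  are made mutually consistent: τ pairs are ordered (fast arm first);
  jointly infeasible (stiffness, ROM) combinations are redrawn; the axial
  neutral zone is clipped to 95% of what the drawn ROM and stiffnesses
  admit. The published torsional neutral zone (≈ 0.39 rad) exceeds the total
  ±10° rotation span (0.349 rad), which no threshold-style definition on
  such a loop can produce, so torsional NZ draws are clipped to 80% of the
  feasible bound — 80% rather than 95% keeps the loop's middle segment from
  becoming near-vertical, which would make the NZ window fits ill-posed at
  realistic noise. All clips are counted and reported with a design warning.
  Morphometry outcomes are drawn directly and routed through the morphometry
  operators (areas → fraction, count/area → density, six landmark lengths →
  DHI). Randomness uses `numpy.random.default_rng` (PCG64) throughout, so a
  (design, seed) pair is byte-reproducible across platforms.

## Pipeline and I/O

Recordings are delimited text (comma or tab) with a header row and
`# key: value` metadata comments; units are always declared (file header or
argument), never guessed; degree-declared rotations convert to radians on
read. Isolated NaNs (< 1% per channel) are linearly interpolated, more is a
parse error. The batch analyzer isolates failures per specimen, writes wide
per-specimen metrics plus a per-file status table and a JSON run report, and
stamps every output row with a SHA-256 hash of the configuration. Outputs
contain no timestamps, so identical inputs + config + seed reproduce
byte-identical files.

## Problem sizes used by the test suite

The acceptance-style tests run the protocol at full length (2700 s × 10 Hz
creep; 20-cycle loops at 1000 Hz), 100 noise replicates for the creep
recovery study, 2000 null replicates for the ANOVA type-I calibration,
10 000 permutations for the Tukey reference, and a 2×2 female cohort of
n = 10/cell for the end-to-end recovery check — sizes at which the checks
are statistically meaningful while the suite stays fast on one CPU. The
end-to-end check compares each recovered per-cell mean against the mean of
the drawn generating parameters for that cell (what the recordings actually
encode) within two standard errors of the recovered mean; sampling
fluctuation of a 10-animal draw around the population mean is not something
the analysis can remove, so it is not charged to the pipeline.

## Known limitations

* The 5-parameter solid is linear viscoelasticity; poroelastic or nonlinear
  behavior, frequency-domain properties and stress normalization by disc
  geometry are out of scope.
* Neutral-zone and stiffness-window definitions are declared conventions
  (threshold/window fractions configurable), not reconstructions of any
  particular lab's unpublished code; absolute NZ values are only comparable
  within one convention.
* Failure detection reports the first global peak; energy-to-failure,
  post-failure residual strength and failure-mode classification are not
  attempted.
* Statistics are fixed-effects only: no mixed models or repeated-measures
  handling, and no multiplicity correction across outcomes.
* Group means ± SDs do not determine within-animal correlations, so the
  cohort generator draws outcomes independently within a specimen.
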
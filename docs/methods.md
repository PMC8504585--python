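# Methods

This note documents the models behind `geldose`, the parameters that matter,
the numerical choices, and what the synthetic-data generator does and does not
emulate.

## Coordinate and unit conventions

Grids are axis-aligned with anisotropic voxels. Indices are 0-based and a
voxel's world coordinate is its **center**; center-based coordinates are what
makes distance-to-agreement computations geometrically correct. All distances
are mm, times seconds, dose Gy, R2 s⁻¹; unit conversion happens only at I/O
boundaries. Oblique/rotated grids are out of scope — measured and planned
volumes are assumed resampled into one common axis-aligned frame, which
`dose_mapping` provides via rigid registration.

NIfTI is the volume interchange format; because the NIfTI header stores the
affine in float32, the JSON sidecar carries the exact spacing/origin (plus the
normalization flags), and the reader prefers it. DICOM RT-Dose import is a
read-only convenience; `.npz` is the self-contained fixture format.

## R2 relaxometry

The spin-echo magnitude decay is modelled mono-exponentially,
`S(TE) = S0·exp(−TE·R2)`. The default estimator is weighted log-linear least
squares — regressing `ln S` on `−TE` with weights `S²`, which undoes the
variance distortion of the log transform and is exact on noiseless data. A
nonlinear least-squares option (Levenberg–Marquardt on the exponential itself,
initialized from the log-linear solution) is provided; which fit a given gel
study used is generally not reported, so both are first-class and the default
is the fast closed form. Goodness of fit is reported in each model's native
domain (log domain for the log-linear fit, signal domain for the nonlinear
one).

Voxels with fewer than `min_echoes` (default 2) samples above `min_signal`
are flagged invalid — NaN in memory, R2 = 0 plus `valid_mask = False` in
files — rather than raising. An `exclude_first_echo` flag covers protocols
whose first echo is corrupted by stimulated echoes; it is off by default.

No Rician noise-floor correction is applied. This is a documented limitation:
at the SNR of the emulated protocol (≥ 20 at the latest echo for the default
`s0 = 1000`, σ ≤ 50) the nonlinear estimator's median bias stays below 2 % of
R2 (checked by Monte Carlo in the test suite), but the estimators should not
be trusted at substantially lower SNR.

## Dose calibration

Gel: `R2 = a + b·D`, fitted by weighted least squares with weights `1/sd²`
when per-tube standard deviations are available (unweighted otherwise).
With supplied sds the standard errors come from `(XᵀWX)⁻¹` treating the sds
as known measurement errors; unweighted fits scale `(XᵀX)⁻¹` by the residual
variance. The fit accepts two points (standard errors are then undefined,
NaN). Slope units are s⁻¹·Gy⁻¹ — the only unit under which `R2 = a + b·D` is
dimensionally consistent, even though such slopes are sometimes printed as
"Gy/s". Inverting the curve, `D = (R2 − a)/b`, maps an R2 volume to dose;
negative doses (R2 below the intercept, i.e. noise) are clamped to zero by
default, and doses beyond the calibrated range are allowed but logged, since
real gel response saturates outside it. Requesting unclamped negatives raises
rather than emitting an unphysical dose grid.

TLD: a through-origin linear response, `sensitivity = Σ(r·d)/Σ(d²)` — the
physically motivated model (zero reading at zero dose). Per-chip sensitivity
factors default to 1 and divide into the dose on conversion.

## Registration and normalization

Rigid-only registration (the gel vial is rigid inside the phantom): the
closed-form least-squares solution from labelled fiducial correspondences —
centroid alignment plus the rotation from the SVD of the cross-covariance,
reflection-corrected (Kabsch). Collinear fiducials leave the rotation
undetermined and raise. The fiducial registration error (FRE) is the RMS
residual in mm. Resampling is trilinear; target voxels falling outside the
source grid are masked out of downstream analysis rather than treated as zero
dose.

Both distributions are normalized by their isocenter dose before comparison.
The normalization value is the mean dose within `averaging_radius` (default
3 mm, ≈ one DTA) of the isocenter rather than a single voxel — a neighborhood
mean stabilizes the normalization against single-voxel noise; whether a given
study used one voxel or a neighborhood is typically unstated, so the radius is
a parameter (0 reproduces single-voxel behavior). Normalization is idempotent
and records the Gy value it divided by.

## Gamma analysis

For each reference voxel above the low-dose threshold,

γ(r) = min over e of √( |e−r|²/DTA² + (D_eval(e) − D_ref(r))²/ΔD² ),

with defaults 3 % / 3 mm / 15 % threshold. Conventions:

* **Reference = planned (TPS) dose, evaluated = gel measurement.** The
  threshold applies to the reference dose — the common convention. Direction
  is configurable; the summary records it.
* **Global normalization** scales ΔD by the reference grid's normalization
  dose (1.0 in the grid's own units once isocenter-normalized; the recorded
  Gy isocenter dose, falling back to the grid maximum, for raw grids). Local
  (per-voxel) normalization is available but non-default.
* The minimization samples the evaluated grid by trilinear interpolation on a
  cubic offset lattice of pitch `interp_step_mm` (default DTA/10) centered on
  each reference voxel, visiting offsets by increasing length, dropping a
  voxel as soon as the distance term alone exceeds its running minimum, and
  capping the search at `search_cap_mm` (default 3·DTA, beyond which γ > 3
  regardless of dose). Within the cap the early exit is lossless: the result
  equals the exhaustive minimum over the same lattice.
* Distances are physical mm throughout, so anisotropic voxels are handled
  correctly (a one-voxel shift along a 2 mm axis costs 2 mm of DTA).
* Excluded voxels (below threshold, outside validity masks, or with no valid
  evaluated sample in range) are NaN in the map and excluded from the
  pass-rate denominator, which is reported as `n_evaluated`.
* A voxel passes at γ ≤ 1 (+1e−9 float guard, so an exact-boundary voxel
  counts as the conventional boundary pass).

`gamma_brute_force` is the validation oracle: it interpolates the evaluated
volume on a fine lattice of the same pitch spanning the whole grid (anchored
at the reference origin so it contains the optimized search's candidates) and
minimizes exhaustively, with no cap and no early exit. When the grid spacing
is an integer multiple of the pitch the two searches share their candidate
set exactly and agree to machine precision wherever γ is within the cap; the
test suite exercises this on 50 random grid pairs. Note the oracle quantizes
to its absolute lattice: on grids whose spacing the pitch does not divide,
agreement is only O(pitch/DTA).

`gamma_pass_rate_curve` scales the dose and DTA criteria (and the search
lattice with them) by a set of factors; γ then scales exactly as 1/factor, so
pass rates are provably non-decreasing — a useful sensitivity report and a
strong property test.

## The synthetic phantom

The generator reproduces the *statistical structure* of a gel-dosimetry
verification study of a four-field-box pelvic treatment, not its physics:

* **Planned dose** — a pedagogical broad-beam model per beam: linear build-up
  from the body surface to `dmax_depth` (15 mm), exponential attenuation
  `exp(−mu_water·(d − dmax))` beyond it (`mu_water` = 0.005 mm⁻¹), and a
  lateral profile that is the product of two erf-smoothed top-hat edges
  (`penumbra_sigma` = 3 mm) with an 8.8 × 11.5 cm aperture. These are
  6-MV-scale values chosen to give box-like distributions; the model is
  **not** a TPS emulator and carries no heterogeneity correction — matching
  the workflow it emulates, where the planned dose is deliberately computed
  without one. The four gantry angles (0/90/180/270) and the final rescaling
  to put the prescription (2 Gy) exactly at the isocenter voxel stand in for
  the planner's beam-weight tuning.
* **Metal prostheses** — phenomenological cylinders: rays crossing one are
  attenuated by `transmission^(chord/2r)`, and voxels within `boost_range` of
  the surface on the beam-entry side gain `1 + boost·exp(−s/boost_range)`
  (electron-scatter enhancement). Magnitudes are user parameters sized so
  synthetic point-dose deviations can span roughly −9 % to +12 %; they are
  inputs, not physics claims.
* **Gel MRI** — `S = s0·exp(−TE·(a + b·D))` on the 8-echo, 35 ms-spaced
  protocol, with the calibration line `R2 = 2.21 + 0.75·D` as the generating
  truth and Rician (magnitude of a complex Gaussian perturbation) or additive
  Gaussian noise. Default `s0 = 1000`; σ = 20 gives SNR 50 at the first echo.
* **Calibration tubes** — 8 tubes, 0–3 Gy, means on the line plus Gaussian
  scatter of sd 0.04 s⁻¹ (the between-slice ROI spread such curves report).
* **TLD** — readings `sensitivity·D·(1 + N(0, relative_sd))`, linear to the
  10 Gy calibration ceiling.

All randomness flows from one explicit integer seed per call; there is no
global random state, and identical seeds give bit-identical outputs.

What the generator does **not** emulate — and hence what passing tests do not
show about real data: MRI susceptibility artifacts near container edges and
metal (only unstructured noise is modelled), B0/B1 inhomogeneity and gradient
nonlinearity, gel response saturation and temporal instability, scatter and
beam-hardening physics of real implants, TPS dose-calculation algorithms, and
setup/positioning error beyond what the rigid-registration stage represents.
Published pass rates and correlation coefficients from physical measurements
(e.g. a 93 % clinical gamma pass rate) depend on those effects and on
unreleased measured data; the pipeline's synthetic end-to-end expectations
(100 % pass noiseless, ≥ 95 % at SNR 50) are fixture properties of this
generator, not claims about any physical experiment.

## Problem sizes

Tests and the reproduction script run at desk scale: the default phantom is
64 × 64 × 32 at 3 mm (the full 224 × 224 × 60 @ 0.6 × 0.6 × 2.0 mm
acquisition geometry is available by passing that shape/spacing), gamma
oracle comparisons use ≤ 12³ grids at 2 mm with 0.5 mm interpolation pitch
(an integer divisor of the spacing, making oracle agreement exact), and
Monte-Carlo checks use 200–1000 replicates. These sizes make the full suite
run in about a minute while leaving every estimator and search path
exercised at realistic anisotropy and SNR.

## TLD reporting choices

Regional means average the per-dosimeter **percent deviations**, not the
deviation of mean doses — the standard reading of "mean variation" in such
tables. Absent measurements (a compromised chip) are first-class `None`
values excluded from every mean and count. When rebuilding a published table,
`tabulated=True` uses the printed deviations as-is; the default recomputes
from doses at full precision. `check_table_consistency` flags rows whose
printed deviation cannot be reproduced from the printed one-decimal doses
(published deviations are typically computed from unrounded values); such
rows are preserved verbatim, never "corrected".
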
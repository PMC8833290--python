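# Methods

This note documents the models, conventions and numerical choices behind
`cbctqa`, and what the synthetic test bed does and does not establish
about real scanner data.

## Spatial data model

Volumes are `(slice, row, column)` HU grids with spacing `(dx, dy, dz)` in
mm (`dx` = in-plane column pitch, `dy` = row pitch, `dz` = slice pitch)
and the origin at the *center* of voxel (0, 0, 0). All ROI coordinates are
mm in this frame. Two conventions are fixed deliberately, because QA
statistics must be bit-reproducible:

* a pixel belongs to a circular ROI iff its center lies strictly inside
  the circle (membership is then monotone in the radius);
* ROI standard deviations are population SDs (divide by n). ROIs contain
  thousands of pixels, so the n vs n−1 difference is negligible, but the
  choice must be fixed for exact regression tests.

HU values are floating point throughout; quantization to integers happens
only on DICOM export (NIfTI and the raw+JSON fallback round-trip
losslessly; NIfTI header pixdims are float32 and are rounded to 1 nm when
read back).

## Synthetic phantom generator

The generator emulates an axial CatPhan-like slice: a water-equivalent
disk in air, with optional sensitometry inserts (ring of seven materials,
air −1000 HU … Teflon 990 HU at the standard nominal values), four
fidelity rods on an axis-aligned 50 mm square, or a slanted high-contrast
edge. Material boundaries are anti-aliased by 4×4 sub-pixel area
averaging, so noiseless rod centroids are sub-0.01 mm accurate and
insert means are exact away from rims.

Degradations are phenomenological, applied in a fixed order
(ideal map → blur → cupping → rim smear → double contour → noise):

* **Blur**: isotropic Gaussian PSF, σ in mm.
* **Cupping**: radial parabola `A·(r/R)²` inside the disk; the edge−center
  difference equals the amplitude A (positive = edges high). The parabola
  is the simplest smooth field consistent with reporting only edge-vs-
  center numbers.
* **Rim smear**: additive Gaussian shell `depth·exp(−(r−R)²/2w²)` inside
  the disk, emulating detector-saturation smearing that depresses the
  phantom margin.
* **Double contour**: an additive ghost of the high-pass rim structure
  sampled at a radially shifted position — only the qualitative effect
  (edge doubling from geometric instability) is modelled; the offset is an
  explicit parameter rather than being derived from any mechanical model.
* **Noise**: white Gaussian, or colored by spectral shaping
  `|f|^(−e/2)` of white noise rescaled to the target σ, which reproduces a
  low-frequency-weighted spectrum without claiming any device's exact NPS.

Identical spec + seed give bit-identical volumes, and every render returns
its ground truth alongside the voxels, so downstream recovery tests never
re-derive the truth from the image.

The slanted-edge generator samples the *analytic* Gaussian-convolved step
at pixel centers (`low + (high−low)·Φ(d/σ)` with d the signed distance
from the edge line), so the rendered ESF is exactly the model ESF before
noise — the natural fixture for resolution-pipeline validation.

The calibration-run generator produces, per run and rotation direction,
nine per-angle corrections
`offset + amp·sin(2π·angle/360 + phase) ± hysteresis/2 + N(0, sd)`; its
defaults mirror the magnitudes observed on a real ring-gantry device
(offsets up to ~11.5 mm, per-angle fluctuation SDs of a few mm, CW/CCW
differences up to ~4.6 mm). The DLP generator inverts the weighted
dose-index formula exactly, then applies multiplicative Gaussian noise, so
the estimator is unbiased by construction.

**What the test bed does not establish**: the generator has no projection
physics (scatter, beam hardening, cone-beam artifacts, FDK kernels), no
spatially correlated reconstruction noise beyond the isotropic spectral
model, and no mechanical model linking geometric fluctuations to image
artifacts. Passing recovery tests therefore validate the *estimators*
(their algebra, normalization and invariances), not any claim about a
particular scanner.

## Metric details and numerical choices

**Fidelity.** Rod detection thresholds halfway between the background
histogram mode (256 bins) and the rod plateau (top 0.2 percentile), keeps
the n largest connected components and takes intensity-weighted centroids.
An optional search radius confines detection to the central region when
other high-contrast structures (inserts, the air background for
dark rods) would compete. Measured pair distances are matched to the
nominal ones by rank order, which is unambiguous for a square (two
distinct nominal values) and avoids solving a general assignment problem;
layouts whose side and diagonal lengths coincide are rejected.

**Uniformity.** "Profile length" is the masked phantom extent along the
profile direction, not the image width — 5%/95% of the image width could
fall in air and make the statistic meaningless. Edge and center values are
single linearly interpolated samples (a windowed average is available but
off by default). For a parabolic field the 5% sample sits at r = 0.9 R, so
the statistic reads 0.81 × amplitude; recovery tests invert this factor.

**CNR.** Exact evaluation of the insert/background formula; the default
background ROI sits at the insert's ring radius, rotated into the widest
insert-free azimuthal gap (nearest such gap to the insert). Insert ROIs
default to 60% of the insert radius to stay clear of partial-volume rims.

**NPS.** Mean subtraction per ROI is the only detrending (no window or
taper); the zero-frequency bin is therefore exactly zero and spectral
leakage is accepted — it vanishes for the white-noise validation case.
Overlapping ROIs are allowed (required to exceed 200 ROIs in a 20 cm
disk; default stride 6 mm yields ~400); the correlation between
overlapping periodograms only slows ensemble convergence, it does not
bias the mean. The radial 1D NPS is an unweighted mean over annuli one
frequency sample wide. Integration restores the 2π·f_r·Δf Jacobian inside
the Nyquist disk and clips the annulus area to the square frequency
support beyond it (exact annulus–square intersection area); this makes the
radial σ_NPS agree with the direct 2D integral to binning accuracy and
returns the pixel SD for white noise, which plain 2π·f·Δf weighting would
overestimate by ~25% (corner annuli) on a square grid. The factor ½
compensates the variance doubling of the two-slice difference image; a
Monte-Carlo estimate of that factor is provided as a self-check.
Conversion of σ_NPS to a 1 mGy reference dose uses the quantum-noise
square-root law `σ_ref = σ·sqrt(CBDI_w/1 mGy)` — a documented assumption,
not a device calibration.

**Resolution.** The edge angle comes from per-row half-maximum crossings
plus a line fit; all ROI pixels are projected onto the signed perpendicular
distance from that line, giving an ESF sampled far below the pixel pitch
for tilts ≥ 1°. The Fermi fit `A/(1+exp((x−x0)/s)) + B` is initialized
from plateau medians, the half-level crossing and the 25–75% transition
distance (/2.2), with a deterministic ladder of width restarts; a negative
fitted width is folded back to the canonical branch. Two MTF routes exist
and are kept deliberately distinct:

* the *analytic* route transforms the fitted Fermi LSF (sampled at
  pixel/10 over at least ±10 widths) and matches the closed form
  `q/sinh(q)`, `q = 2π²·s·f`, to numerical precision;
* the *empirical* route (used by the end-to-end pipeline) bins the
  oversampled ESF at pixel/10, differentiates, and transforms.

The analytic route is model-limited: the logistic kernel has exponential
tails, so for a near-Gaussian PSF its MTF overestimates the
high-frequency response by up to ~0.05 and places the 10% point where the
true Gaussian MTF is only ~5–6%. The empirical route is kernel-agnostic
(errors < 0.003 against the analytic Gaussian MTF in noiseless tests) and
is therefore the default for quantitative resolution claims, with the
Fermi fit retained for localization, plateau estimation and QC. f_lim is
linearly interpolated at the 10% level (threshold configurable) and
reported in both cycles/mm and lp/cm (= 10 × cycles/mm).

**Dose.** The weighted index is evaluated exactly; the 10 cm chamber
length is carried as data, not a constant. Replicate SDs use n−1 (three
measurements per protocol is the typical practice).

**Calibration statistics.** All records must share the angle grid exactly
— the device samples a fixed schedule, so no interpolation across runs is
performed. The overall mean ± SD pools all (angle, run, direction)
samples, reading "averaged over the entire orbit and all calibrations"
literally; the alternative (SD across per-run orbit means) is available
behind `overall_sd="run_means"` without being endorsed. Per-angle
across-run SDs use n−1 and are computed within each rotation direction,
then averaged over the directions present (the directions carry a
systematic hysteresis offset that would otherwise inflate the estimate).
The CW/CCW comparison is formed per run, averaged over runs per angle,
and the absolute value taken *after* averaging, so random fluctuations
cancel and only a systematic direction difference survives.

## Problem sizes used in tests and benchmarks

The suite and the acceptance script run phantoms at the device-typical
0.4 mm in-plane grid: 400²–540² pixels per slice (20 cm uniform module,
15 cm rod module), 512² slanted-edge renders, 8-run × 53-angle × 2-direction
calibration ensembles (200 repetitions for coverage statistics), 50-seed
noise ensembles for rod detection, and ~400-ROI NPS ensembles — sizes at
which every estimator's sampling error is far below its acceptance
tolerance while the whole suite completes in well under a minute of
compute per module.

## Known limitations

* Phenomenological degradations only; no projection-space simulation or
  scatter/hardening physics.
* No 3D NPS, NEQ/DQE, or detrending beyond per-ROI mean subtraction.
* No bar-pattern contrast-resolution scoring, anisotropic 2D MTF maps, or
  vendor-style CatPhan auto-alignment.
* The flexmap corrections are consumed, never estimated from projections,
  and are not fed into any reconstructor.
* Multi-frame enhanced DICOM, gantry-tilted acquisitions and
  projection-domain data are out of scope.
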
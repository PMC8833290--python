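# cbctqa

Quantitative image-quality and geometric-stability QA for cone-beam CT
(CBCT), written for medical physicists commissioning or monitoring
volumetric imaging devices. The package evaluates CatPhan-style phantom
scans and calibration logs, and ships a synthetic phantom/calibration
generator with embedded ground truth so the entire pipeline is verifiable
by parameter recovery without any scanner data.

## What it computes

* **Imaging fidelity** — threshold-based detection of the four fidelity
  rods (nominally a 50 mm square), pairwise Euclidean distances matched to
  the physical layout, mean ± SD of the absolute deviations.
* **CT-number accuracy / linearity** — circular-ROI means of the
  sensitometry inserts regressed on their nominal HU values (slope,
  intercept, R²).
* **Uniformity** — band-averaged CT-number profiles (10 rows/columns) in
  the lateral and AP directions; the non-uniformity is the signed
  difference between the profile edge (5%/95% of the masked profile
  length, whichever deviates more) and the center, so cupping and
  asymmetric rim artifacts are both captured. Also evaluated as a function
  of longitudinal phantom offset.
* **Contrast-to-noise ratio** —
  `CNR = (ROI_bkg − ROI_insert) / sqrt((σ_bkg² + σ_insert²)/2)`.
* **Noise power spectrum** — from a two-slice difference image (slices
  spaced 4 slice thicknesses), an ensemble of N_ROI > 200 overlapping
  5 × 5 cm² ROIs:
  `NPS(fx,fy) = (Δx·Δy)/(Nx·Ny·N_ROI) · Σᵢ |DFT{ROIᵢ − mean(ROIᵢ)}|² · ½`,
  radially averaged to NPS(f_r); discrete integration yields the noise
  magnitude σ_NPS, optionally rescaled to a 1 mGy reference dose via the
  quantum-noise square-root law.
* **Spatial resolution** — oversampled edge-spread function from a
  slightly tilted edge, Fermi (logistic) edge fit, line-spread function
  resampled at one tenth of the pixel size, `MTF(fx) = |DFT{LSF(x)}|`
  normalized to MTF(0) = 1, and the limiting frequency f_lim at the 10%
  level (reported in cycles/mm and lp/cm).
* **Dose** — weighted cone-beam dose index from pencil-chamber DLP
  readings in the body dosimetry phantom:
  `CBDI_w = DLP_central/(3L) + 2·mean(DLP_peripheral)/(3L)`, L = 10 cm.
* **Geometric reproducibility** — statistics over repeated flexmap
  calibrations (nine per-angle corrections tSx…rz over a 520° orbit in 10°
  steps, i.e. 53 views): overall mean ± SD, per-angle across-run SDs, and
  per-angle |CW − CCW| rotation-direction differences.

## Worked example

```python
import cbctqa as q

# Uniform 20 cm module with -30 HU cupping and 15 HU white noise
vol, truth = q.render_phantom(
    q.catphan_uniform_module(),
    q.DegradationSpec(noise_sigma=15.0, cupping_amplitude=-30.0, seed=42),
    q.GridSpec(shape=(540, 540), spacing=(0.4, 0.4, 1.0), n_slices=5))

lat = q.uniformity_profile(vol, 0, "lateral")
nps = q.noise_power_spectrum(vol, 0, 4, q.phantom_mask(vol, 0))

ev, _ = q.render_edge((3.0, -200.0, 800.0), 0.5, 0.0,
                      q.GridSpec(shape=(512, 512), spacing=(0.4, 0.4, 1.0)))
edge, mtf = q.edge_resolution(ev, 0, q.RectROI(0, (60.0, 60.0), (80.0, 80.0)))

rv, _ = q.render_phantom(q.catphan_rod_module(),
                         q.DegradationSpec(noise_sigma=20, seed=7),
                         q.GridSpec(shape=(400, 400), spacing=(0.4, 0.4, 1.0)))
fid = q.imaging_fidelity(q.detect_rods(rv, 0, "bright", 4), 50.0)
dose = q.cbdi_w([q.simulate_dlp(8.7, 1.2, 0.02, seed=s) for s in (1, 2, 3)])
```

This prints (via the obvious f-strings):

```
lateral non-uniformity: -22.1 HU
sigma_NPS: 14.98 HU from 400 ROIs
edge angle: 3.00 deg, Fermi width s = 0.294 mm
f_lim: 0.682 cycles/mm = 6.82 lp/cm
imaging fidelity: 0.003 +/- 0.002 mm
CBDI_w: 8.70 +/- 0.04 mGy (peripheral/central = 1.17)
noise at 1 mGy: 44.2 HU
```

Reading the numbers: the injected −30 HU parabolic cupping appears as a
−22.1 HU edge-vs-center non-uniformity (the 5% profile sample sits at
0.9 R, where a parabola reaches 81% of its amplitude: −30 × 0.81 ≈ −24);
σ_NPS recovers the injected 15 HU noise; the 0.5 mm Gaussian blur yields a
limiting frequency of 0.68 cycles/mm; the rod square is recovered to a few
micrometres despite 20 HU noise; and the three replicate DLP tables return
the simulated 8.7 mGy dose index.

A `cbctqa` console command exposes the same pipelines (`simulate`,
`fidelity`, `linearity`, `uniformity`, `cnr`, `nps`, `mtf`, `cbdi`,
`calib-stats`, `report`), each reading a small YAML/CSV configuration and
writing JSON/CSV with input hashes and seeds logged to stderr.

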
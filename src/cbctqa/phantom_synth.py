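"""Synthetic CatPhan-like phantoms, calibration runs and dose tables.

This module is the test bed standing in for the scanner: every generated
object carries its ground truth so downstream metrics can be validated by
parameter recovery.  The degradations are phenomenological emulations of
effects seen on real cone-beam systems — Gaussian blur, radial cupping,
rim saturation smearing, double contours from geometric instability, and
white/colored noise — not a physical projection/reconstruction model.

Rendering order is fixed: ideal HU map -> blur -> cupping -> edge smear ->
double contour -> noise.  Identical spec + seed give bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import ndtr

from .exceptions import SpecError
from .geometry_qa import CORRECTIONS, CalibrationRecord, calibration_schedule
from .volume_io import ImageVolume

__all__ = [
    "PhantomSpec",
    "DegradationSpec",
    "GridSpec",
    "CalibrationSimSpec",
    "RenderResult",
    "render_phantom",
    "render_edge",
    "simulate_calibration_runs",
    "simulate_dlp",
    "catphan_insert_module",
    "catphan_rod_module",
    "catphan_uniform_module",
    "catphan_edge_module",
    "CTP404_INSERT_HU",
]

AIR_HU = -1000.0

#: Standard nominal CT-numbers of the sensitometry inserts (phantom manual values).
CTP404_INSERT_HU: dict[str, float] = {
    "air": -1000.0,
    "pmp": -200.0,
    "ldpe": -100.0,
    "polystyrene": -35.0,
    "acrylic": 120.0,
    "delrin": 340.0,
    "teflon": 990.0,
}


# --------------------------------------------------------------------------
# Specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and materials of one axial phantom module.

    Inserts and rods are ``(name, (row, col) mm offset from disk center,
    radius mm, HU)`` and ``((row, col) mm, radius mm, HU)`` respectively.
    The default insert-module rod layout is four rods at the corners of an
    axis-aligned 50 mm square.  ``edge`` is (angle deg from the vertical
    image axis, low HU, high HU) for the edge module.
    """

    module_kind: str  # insert_module | uniform_module | edge_module
    diameter: float = 200.0
    background_hu: float = 100.0
    inserts: tuple = ()
    rods: tuple = ()
    edge: tuple[float, float, float] = (3.0, -200.0, 800.0)

    def __post_init__(self) -> None:
        if self.module_kind not in ("insert_module", "uniform_module", "edge_module"):
            raise SpecError(f"unknown module kind {self.module_kind!r}")
        r_disk = self.diameter / 2.0
        for name, center, radius, _ in self.inserts:
            if np.hypot(*center) + radius > r_disk:
                raise SpecError(f"insert {name!r} extends outside the phantom disk")
        for center, radius, _ in self.rods:
            if np.hypot(*center) + radius > r_disk:
                raise SpecError(f"rod at {center} extends outside the phantom disk")


def _square_rods(side: float = 50.0, radius: float = 3.0, hu: float = 950.0) -> tuple:
    h = side / 2.0
    return tuple(((r, c), radius, hu) for r in (-h, h) for c in (-h, h))


def catphan_insert_module(background_hu: float = 100.0,
                          insert_radius: float = 6.0,
                          insert_ring_radius: float = 60.0,
                          rod_side: float = 50.0,
                          rod_radius: float = 3.0,
                          rod_hu: float = 950.0) -> PhantomSpec:
    """Sensitometry module: seven HU inserts on a ring + four fidelity rods
    at the corners of a 50 mm square."""
    azimuths = dict(zip(CTP404_INSERT_HU, range(0, 315, 45)))
    inserts = tuple(
        (name,
         (insert_ring_radius * np.sin(np.deg2rad(az)),
          insert_ring_radius * np.cos(np.deg2rad(az))),
         insert_radius, hu)
        for (name, hu), az in zip(CTP404_INSERT_HU.items(), azimuths.values()))
    return PhantomSpec(module_kind="insert_module", background_hu=background_hu,
                       inserts=inserts, rods=_square_rods(rod_side, rod_radius, rod_hu))


def catphan_rod_module(background_hu: float = 100.0, diameter: float = 150.0,
                       rod_side: float = 50.0, rod_radius: float = 3.0,
                       rod_hu: float = 950.0) -> PhantomSpec:
    """Fidelity-only module: the four rods on the nominal 50 mm square."""
    return PhantomSpec(module_kind="insert_module", diameter=diameter,
                       background_hu=background_hu,
                       rods=_square_rods(rod_side, rod_radius, rod_hu))


def catphan_uniform_module(background_hu: float = 20.0,
                           diameter: float = 200.0) -> PhantomSpec:
    """Homogeneous 20 cm module used for uniformity and NPS."""
    return PhantomSpec(module_kind="uniform_module", diameter=diameter,
                       background_hu=background_hu)


def catphan_edge_module(angle: float = 3.0, low_hu: float = -200.0,
                        high_hu: float = 800.0) -> PhantomSpec:
    return PhantomSpec(module_kind="edge_module", edge=(angle, low_hu, high_hu))


@dataclass(frozen=True)
class DegradationSpec:
    """Phenomenological image degradations, applied in a fixed order.

    noise_color_exponent e shapes the noise spectrum as |f|^(-e/2) (0 = white);
    cupping is a radial parabola with edge-center difference = amplitude
    (positive = edges high); edge_smear (width mm, depth HU) adds a Gaussian
    rim deficit/excess; double_contour (offset mm, fraction) adds a radially
    shifted ghost of the rim gradients.
    """

    noise_sigma: float = 0.0
    noise_color_exponent: float = 0.0
    blur_sigma: float = 0.0
    cupping_amplitude: float = 0.0
    edge_smear: tuple[float, float] = (0.0, 0.0)
    double_contour: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0 or self.blur_sigma < 0:
            raise SpecError("noise_sigma and blur_sigma must be >= 0")


@dataclass(frozen=True)
class GridSpec:
    """Output sampling grid: (ny, nx) pixels, (dx, dy, dz) mm, n_slices copies."""

    shape: tuple[int, int] = (512, 512)
    spacing: tuple[float, float, float] = (0.4, 0.4, 1.0)
    n_slices: int = 1


class RenderResult(NamedTuple):
    volume: ImageVolume
    truth: dict


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

_SUPERSAMPLE = 4  # sub-pixel area-fraction anti-aliasing at material boundaries


def _ideal_slice(spec: PhantomSpec, grid: GridSpec) -> np.ndarray:
    """Noiseless HU map with 4x4 sub-pixel averaging at boundaries."""
    ny, nx = grid.shape
    dx, dy, _ = grid.spacing
    s = _SUPERSAMPLE
    # supersampled pixel centers (mm), covering the same extent
    ys = (np.arange(ny * s) + 0.5) / s - 0.5
    xs = (np.arange(nx * s) + 0.5) / s - 0.5
    y = ys * dy
    x = xs * dx
    cy = (ny - 1) * dy / 2.0
    cx = (nx - 1) * dx / 2.0
    yy = (y - cy)[:, None]
    xx = (x - cx)[None, :]
    r2 = yy ** 2 + xx ** 2
    r_disk = spec.diameter / 2.0
    img = np.full((ny * s, nx * s), AIR_HU)
    inside = r2 <= r_disk ** 2
    img[inside] = spec.background_hu
    if spec.module_kind == "edge_module":
        theta = np.deg2rad(spec.edge[0])
        d = xx * np.cos(theta) - yy * np.sin(theta)
        img[inside & (d >= 0)] = spec.edge[2]
        img[inside & (d < 0)] = spec.edge[1]
    for name, center, radius, hu in spec.inserts:
        img[(yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2] = hu
    for center, radius, hu in spec.rods:
        img[(yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2] = hu
    return img.reshape(ny, s, nx, s).mean(axis=(1, 3))


def _colored_noise(shape: tuple[int, int], sigma: float, exponent: float,
                   rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(shape)
    if sigma == 0:
        return np.zeros(shape)
    if exponent == 0:
        return sigma * white
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    fr = np.hypot(fy, fx)
    gain = np.zeros_like(fr)
    nz = fr > 0
    gain[nz] = fr[nz] ** (-exponent / 2.0)
    shaped = np.fft.ifft2(np.fft.fft2(white) * gain).real
    return sigma * shaped / shaped.std()


def render_phantom(spec: PhantomSpec, degrade: DegradationSpec,
                   grid: GridSpec = GridSpec()) -> RenderResult:
    """Render a degraded phantom volume plus its ground-truth record.

    Effects are applied in the documented order; every slice shares the
    deterministic part and receives independent noise.
    """
    ny, nx = grid.shape
    dx, dy, dz = grid.spacing
    if min(nx * dx, ny * dy) < spec.diameter:
        raise SpecError("grid does not cover the phantom diameter")
    img = _ideal_slice(spec, grid)
    cy = (ny - 1) * dy / 2.0
    cx = (nx - 1) * dx / 2.0
    yy = (np.arange(ny) * dy - cy)[:, None]
    xx = (np.arange(nx) * dx - cx)[None, :]
    r = np.hypot(yy, xx)
    r_disk = spec.diameter / 2.0
    inside = r <= r_disk

    if degrade.blur_sigma > 0:
        img = ndimage.gaussian_filter(
            img, sigma=(degrade.blur_sigma / dy, degrade.blur_sigma / dx))
    if degrade.cupping_amplitude != 0:
        img = img + np.where(inside,
                             degrade.cupping_amplitude * (r / r_disk) ** 2, 0.0)
    smear_w, smear_d = degrade.edge_smear
    if smear_w > 0 and smear_d != 0:
        img = img + np.where(inside,
                             smear_d * np.exp(-0.5 * ((r - r_disk) / smear_w) ** 2),
                             0.0)
    dc_offset, dc_frac = degrade.double_contour
    if dc_offset != 0 and dc_frac != 0:
        highpass = img - ndimage.gaussian_filter(img, sigma=(1.0 / dy, 1.0 / dx))
        # sample the highpass field at radius r + offset (same azimuth)
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(r > 1e-9, (r + dc_offset) / r, 1.0)
        coords = np.array([(yy * scale + cy) / dy, (xx * scale + cx) / dx])
        ghost = ndimage.map_coordinates(highpass, coords, order=1, mode="nearest")
        img = img + dc_frac * ghost

    rng = np.random.default_rng(degrade.seed)
    slices = [img + _colored_noise(img.shape, degrade.noise_sigma,
                                   degrade.noise_color_exponent, rng)
              for _ in range(grid.n_slices)]
    vol = ImageVolume(voxels=np.stack(slices), spacing=grid.spacing)
    truth = {
        "module_kind": spec.module_kind,
        "disk_center_mm": (cy, cx),
        "disk_radius_mm": r_disk,
        "background_hu": spec.background_hu,
        "insert_centers_mm": {name: (cy + c[0], cx + c[1])
                              for name, c, _, _ in spec.inserts},
        "insert_hu": {name: hu for name, _, _, hu in spec.inserts},
        "rod_centers_mm": [(cy + c[0], cx + c[1]) for c, _, _ in spec.rods],
        "degradation": {
            "noise_sigma": degrade.noise_sigma,
            "noise_color_exponent": degrade.noise_color_exponent,
            "blur_sigma": degrade.blur_sigma,
            "cupping_amplitude": degrade.cupping_amplitude,
            "edge_smear": list(degrade.edge_smear),
            "double_contour": list(degrade.double_contour),
            "seed": degrade.seed,
        },
    }
    return RenderResult(volume=vol, truth=truth)


def render_edge(edge: tuple[float, float, float], blur_sigma: float,
                noise_sigma: float, grid: GridSpec = GridSpec(),
                seed: int = 0) -> RenderResult:
    """Analytic Gaussian-convolved slanted step, sampled at pixel centers.

    ``edge`` is (angle deg from the vertical image axis, low HU, high HU);
    the edge profile before noise is exactly ``low + (high-low) *
    Phi(d / blur_sigma)`` with d the signed distance from the edge line
    through the grid center.  Recommended tilt is 1..10 deg; angle 0 gives
    no sub-pixel phase diversity and triggers a warning.
    """
    angle, low, high = edge
    if angle == 0:
        warnings.warn("edge angle 0: no oversampling possible", stacklevel=2)
    ny, nx = grid.shape
    dx, dy, _ = grid.spacing
    cy = (ny - 1) * dy / 2.0
    cx = (nx - 1) * dx / 2.0
    yy = (np.arange(ny) * dy - cy)[:, None]
    xx = (np.arange(nx) * dx - cx)[None, :]
    theta = np.deg2rad(angle)
    d = xx * np.cos(theta) - yy * np.sin(theta)
    if blur_sigma > 0:
        img = low + (high - low) * ndtr(d / blur_sigma)
    else:
        img = np.where(d >= 0, high, low).astype(float)
    rng = np.random.default_rng(seed)
    slices = [img + (rng.standard_normal(img.shape) * noise_sigma
                     if noise_sigma > 0 else 0.0)
              for _ in range(grid.n_slices)]
    vol = ImageVolume(voxels=np.stack(slices), spacing=grid.spacing)
    truth = {"edge_angle_deg": angle, "low_hu": low, "high_hu": high,
             "blur_sigma_mm": blur_sigma, "noise_sigma_hu": noise_sigma,
             "edge_through_mm": (cy, cx), "seed": seed}
    return RenderResult(volume=vol, truth=truth)


# --------------------------------------------------------------------------
# Calibration-run simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationSimSpec:
    """Generator settings for repeated flexmap calibrations.

    Per correction (9-vectors ordered as ``CORRECTIONS``): a systematic
    offset, a smooth sinusoidal angular modulation amplitude, a run-to-run
    fluctuation SD, and a CW/CCW hysteresis (mean CW-minus-CCW difference).
    Translations in mm, rotations in degrees.  Defaults emulate the observed
    device behaviour: offsets up to ~11.5 mm (tCz) with ~0.4 mm fluctuation,
    and direction differences up to ~4.6 mm (tSz).
    """

    n_runs: int = 8
    angle_start: float = 0.0
    angle_stop: float = 520.0
    angle_step: float = 10.0
    offsets: tuple = (1.2, -0.8, 2.5, 0.6, 0.0, 11.5, 0.64, 0.2, -0.1)
    modulation_amp: tuple = (0.3, 0.2, 0.8, 0.2, 0.1, 0.5, 0.05, 0.08, 0.01)
    fluctuation_sd: tuple = (0.8, 0.6, 3.0, 0.7, 0.5, 2.1, 0.04, 0.23, 0.039)
    hysteresis: tuple = (0.5, 0.2, 4.6, 0.4, 0.1, 3.1, 0.05, 0.3, 0.02)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("offsets", "modulation_amp", "fluctuation_sd", "hysteresis"):
            if len(getattr(self, name)) != 9:
                raise SpecError(f"{name} must have 9 entries (one per correction)")
        if any(s < 0 for s in self.fluctuation_sd):
            raise SpecError("fluctuation SDs must be >= 0")


def simulate_calibration_runs(spec: CalibrationSimSpec
                              ) -> tuple[list[CalibrationRecord], dict]:
    """One CW and one CCW record per run, with the ground truth retained.

    value(c, angle, run, dir) = offset_c + amp_c * sin(2*pi*angle/360 + phase_c)
    + (+-)hysteresis_c/2 + N(0, fluctuation_sd_c), with a fixed per-correction
    phase and independent Gaussian fluctuations per (run, direction, angle).
    """
    angles = calibration_schedule(spec.angle_start,
                                  spec.angle_stop - spec.angle_start,
                                  spec.angle_step)
    rng = np.random.default_rng(spec.seed)
    phases = 0.7 * np.arange(9)
    base = (np.asarray(spec.offsets)[None, :]
            + np.asarray(spec.modulation_amp)[None, :]
            * np.sin(2 * np.pi * angles[:, None] / 360.0 + phases[None, :]))
    records = []
    for run in range(spec.n_runs):
        for direction, sign in (("cw", 1.0), ("ccw", -1.0)):
            noise = rng.standard_normal((len(angles), 9)) * np.asarray(spec.fluctuation_sd)
            values = base + sign * 0.5 * np.asarray(spec.hysteresis)[None, :] + noise
            records.append(CalibrationRecord(
                run_id=f"run{run:02d}", direction=direction, angles=angles,
                corrections=pd.DataFrame(values, columns=list(CORRECTIONS))))
    truth = {"offsets": dict(zip(CORRECTIONS, spec.offsets)),
             "modulation_amp": dict(zip(CORRECTIONS, spec.modulation_amp)),
             "fluctuation_sd": dict(zip(CORRECTIONS, spec.fluctuation_sd)),
             "hysteresis": dict(zip(CORRECTIONS, spec.hysteresis)),
             "n_runs": spec.n_runs, "seed": spec.seed,
             "angles": angles.tolist()}
    return records, truth


# --------------------------------------------------------------------------
# Dose-table simulation
# --------------------------------------------------------------------------

def simulate_dlp(true_cbdi: float, peripheral_to_central_ratio: float = 1.0,
                 noise_cv: float = 0.0, seed: int = 0,
                 chamber_length_cm: float = 10.0) -> pd.DataFrame:
    """Five DLP rows (1 central + 4 peripheral) whose weighted combination
    equals ``true_cbdi`` exactly before noise.

    The central DLP solves CBDI_w = (DLP_c + 2*ratio*DLP_c) / (3*L); each row
    then receives multiplicative Gaussian noise of coefficient of variation
    ``noise_cv`` (so the estimator stays unbiased).
    """
    if peripheral_to_central_ratio <= 0:
        raise SpecError("peripheral_to_central_ratio must be positive")
    dlp_central = 3.0 * chamber_length_cm * true_cbdi / (1.0 + 2.0 * peripheral_to_central_ratio)
    dlp_peripheral = peripheral_to_central_ratio * dlp_central
    rng = np.random.default_rng(seed)
    positions = ["central"] + [f"peripheral_{i}" for i in range(1, 5)]
    ideal = np.array([dlp_central] + [dlp_peripheral] * 4)
    noisy = ideal * (1.0 + noise_cv * rng.standard_normal(5)) if noise_cv > 0 else ideal
    return pd.DataFrame({"position": positions,
                         "dlp_mGy_cm": noisy,
                         "chamber_length_cm": chamber_length_cm})
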
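"""Noise power spectrum from a difference-image ROI ensemble.

Two uniform-module slices spaced four slice thicknesses apart are
subtracted; an ensemble of overlapping 5 x 5 cm^2 ROIs is tiled inside the
phantom mask of the difference image and the 2D NPS is

    NPS(fx, fy) = (dx*dy) / (Nx*Ny*N_ROI) * sum_i |DFT{ROI_i - mean_i}|^2 * 1/2

in HU^2 mm^2, the factor 1/2 compensating the variance doubling of the
difference image.  Each ROI is offset-corrected with its own mean only (no
window/taper, no detrending polynomials).  The radial 1D NPS is the
unweighted mean over annular bins of width one frequency sample; the noise
magnitude sigma_NPS integrates it with the annulus-area Jacobian clipped to
the square frequency support, so that the radial and direct 2D integrals
agree and white noise returns its pixel SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .exceptions import PlacementError, SpecError
from .volume_io import ImageVolume, RectROI

__all__ = [
    "NoiseROIEnsemble",
    "NPSResult",
    "build_difference_image",
    "place_roi_ensemble",
    "nps2d",
    "radial_average_and_integrate",
    "noise_power_spectrum",
    "noise_at_reference_dose",
    "estimate_difference_variance_factor",
]

#: Default ROI edge (mm) and grid stride (mm) of the ensemble placement.
DEFAULT_ROI_SIZE_MM = (50.0, 50.0)
DEFAULT_STRIDE_MM = 6.0


@dataclass
class NoiseROIEnsemble:
    difference_image: np.ndarray
    rois: list[RectROI]
    nx: int              # ROI pixel count along columns
    ny: int              # ROI pixel count along rows
    dx: float            # mm
    dy: float            # mm

    @property
    def n_roi(self) -> int:
        return len(self.rois)


@dataclass
class NPSResult:
    nps2d: np.ndarray        # fftshifted, HU^2 mm^2
    fx: np.ndarray           # cycles/mm, fftshifted axis
    fy: np.ndarray
    nps1d: Optional[np.ndarray] = None   # radial mean, bins up to Nyquist
    f_radial: Optional[np.ndarray] = None
    sigma_nps: Optional[float] = None    # HU
    n_roi: int = 0

    @property
    def nyquist(self) -> float:
        return float(-self.fx[0])


def build_difference_image(vol: ImageVolume, slice_a: int, slice_b: int) -> np.ndarray:
    """Voxelwise slice_a - slice_b; warns unless spaced 4 slice thicknesses."""
    if slice_a == slice_b:
        raise SpecError("difference image requires two distinct slices")
    a = vol.get_slice(slice_a)
    b = vol.get_slice(slice_b)
    if abs(slice_a - slice_b) != 4:
        warnings.warn(
            f"slices {slice_a}/{slice_b} are {abs(slice_a - slice_b)} apart; "
            "4x the slice thickness is recommended to avoid cross-correlation",
            stacklevel=2)
    return a - b


def place_roi_ensemble(mask: np.ndarray, spacing: tuple[float, float],
                       roi_size_mm: tuple[float, float] = DEFAULT_ROI_SIZE_MM,
                       stride_mm: float = DEFAULT_STRIDE_MM,
                       slice_index: int = 0) -> list[RectROI]:
    """Regular (overlapping) grid of rectangles fully inside the mask.

    The grid is corner-aligned with the mask bounding box and stepped by
    ``stride_mm``; a ROI is kept iff every pixel under it is masked.
    ``spacing`` is (dx, dy) in mm.  Raises :class:`PlacementError` when
    nothing fits.
    """
    dx, dy = float(spacing[0]), float(spacing[1])
    h = int(round(roi_size_mm[0] / dy))
    w = int(round(roi_size_mm[1] / dx))
    sr = max(int(round(stride_mm / dy)), 1)
    sc = max(int(round(stride_mm / dx)), 1)
    ridx, cidx = np.nonzero(mask)
    if ridx.size == 0 or h < 1 or w < 1:
        raise PlacementError("mask empty or ROI smaller than one pixel")
    r0, r1 = ridx.min(), ridx.max()
    c0, c1 = cidx.min(), cidx.max()
    # summed-area table for O(1) full-coverage tests
    integral = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), dtype=np.int64)
    integral[1:, 1:] = np.cumsum(np.cumsum(mask.astype(np.int64), axis=0), axis=1)
    rois = []
    for rs in range(r0, r1 - h + 2, sr):
        for cs in range(c0, c1 - w + 2, sc):
            covered = (integral[rs + h, cs + w] - integral[rs, cs + w]
                       - integral[rs + h, cs] + integral[rs, cs])
            if covered == h * w:
                rois.append(RectROI(slice_index=slice_index,
                                    corner=(rs * dy, cs * dx),
                                    extent=(h * dy, w * dx)))
    if not rois:
        raise PlacementError(
            f"no {roi_size_mm} mm ROI fits inside the mask")
    return rois


def nps2d(ensemble: NoiseROIEnsemble, difference_factor: float = 0.5) -> NPSResult:
    """Ensemble-averaged 2D NPS of the (mean-subtracted) difference-image ROIs."""
    img = ensemble.difference_image
    ny, nx = ensemble.ny, ensemble.nx
    acc = np.zeros((ny, nx))
    for roi in ensemble.rois:
        r = int(round(roi.corner[0] / ensemble.dy))
        c = int(round(roi.corner[1] / ensemble.dx))
        sub = img[r:r + ny, c:c + nx]
        if sub.shape != (ny, nx):
            raise SpecError("ROI shapes heterogeneous or outside the image")
        sub = sub - sub.mean()
        acc += np.abs(np.fft.fft2(sub)) ** 2
    scale = difference_factor * ensemble.dx * ensemble.dy / (nx * ny * ensemble.n_roi)
    spectrum = np.fft.fftshift(acc * scale)
    fx = np.fft.fftshift(np.fft.fftfreq(nx, d=ensemble.dx))
    fy = np.fft.fftshift(np.fft.fftfreq(ny, d=ensemble.dy))
    return NPSResult(nps2d=spectrum, fx=fx, fy=fy, n_roi=ensemble.n_roi)


def _annulus_square_area(f: np.ndarray, half_side: float) -> np.ndarray:
    """Area of the disk of radius f intersected with the square [-a, a]^2."""
    f = np.asarray(f, dtype=float)
    a = half_side
    area = np.where(f <= a, np.pi * f ** 2, 0.0)
    over = f > a
    if np.any(over):
        fo = np.minimum(f[over], a * np.sqrt(2.0))
        b = np.sqrt(np.maximum(fo ** 2 - a ** 2, 0.0))
        quad = a * b + fo ** 2 / 2.0 * (np.arcsin(np.minimum(a / fo, 1.0))
                                        - np.arcsin(np.minimum(b / fo, 1.0)))
        area[over] = 4.0 * quad
    return area


def radial_average_and_integrate(result: NPSResult) -> NPSResult:
    """Radial 1D reduction and integrated noise magnitude sigma_NPS.

    Annular bins have width equal to the frequency sample spacing; within
    the Nyquist disk the integration weight reduces to the plain 2*pi*f*df
    Jacobian, beyond it the annulus area is clipped to the square support.
    The returned ``nps1d``/``f_radial`` are reported up to Nyquist.
    """
    fx, fy = result.fx, result.fy
    if len(fx) != len(fy) or not np.allclose(fx, fy):
        raise SpecError("radial reduction requires a square frequency grid")
    df = float(fx[1] - fx[0])
    fr = np.hypot(fy[:, None], fx[None, :])
    nbins = int(np.ceil(fr.max() / df)) + 1
    idx = np.minimum((fr / df).astype(int), nbins - 1)
    counts = np.bincount(idx.ravel(), minlength=nbins)
    sums = np.bincount(idx.ravel(), weights=result.nps2d.ravel(), minlength=nbins)
    with np.errstate(invalid="ignore"):
        mean_b = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    edges = df * np.arange(nbins + 1)
    half_side = len(fx) * df / 2.0  # square support of the sampled spectrum
    areas = np.diff(_annulus_square_area(edges, half_side))
    sigma2 = float(np.sum(mean_b * areas))
    centers = edges[:-1] + df / 2.0
    keep = centers <= result.nyquist + 1e-12
    result.nps1d = mean_b[keep]
    result.f_radial = centers[keep]
    result.sigma_nps = float(np.sqrt(max(sigma2, 0.0)))
    return result


def noise_power_spectrum(vol: ImageVolume, slice_a: int, slice_b: int,
                         mask: np.ndarray,
                         roi_size_mm: tuple[float, float] = DEFAULT_ROI_SIZE_MM,
                         stride_mm: float = DEFAULT_STRIDE_MM) -> NPSResult:
    """End-to-end pipeline: difference image -> ROI ensemble -> 2D NPS ->
    radial 1D NPS and sigma_NPS."""
    diff = build_difference_image(vol, slice_a, slice_b)
    rois = place_roi_ensemble(mask, vol.spacing[:2], roi_size_mm, stride_mm,
                              slice_index=slice_a)
    dx, dy, _ = vol.spacing
    ny = int(round(rois[0].extent[0] / dy))
    nx = int(round(rois[0].extent[1] / dx))
    ens = NoiseROIEnsemble(difference_image=diff, rois=rois, nx=nx, ny=ny,
                           dx=dx, dy=dy)
    return radial_average_and_integrate(nps2d(ens))


def noise_at_reference_dose(sigma_nps: float, cbdi_w: float,
                            reference_mgy: float = 1.0) -> float:
    """Quantum-noise scaling of sigma_NPS to a reference dose:
    sigma_ref = sigma * sqrt(CBDI_w / reference).  This square-root law is a
    documented modelling assumption, not a device calibration."""
    if cbdi_w <= 0 or reference_mgy <= 0:
        raise SpecError("doses must be positive")
    return float(sigma_nps * np.sqrt(cbdi_w / reference_mgy))


def estimate_difference_variance_factor(sigma: float = 20.0,
                                        shape: tuple[int, int] = (256, 256),
                                        n_reps: int = 100,
                                        seed: int = 0) -> float:
    """Monte-Carlo estimate of var(single image) / var(difference image).

    For independent equal-noise slices the factor converges to 1/2 — the
    correction applied inside the NPS normalization.
    """
    rng = np.random.default_rng(seed)
    ratios = np.empty(n_reps)
    for i in range(n_reps):
        a = rng.standard_normal(shape) * sigma
        b = rng.standard_normal(shape) * sigma
        ratios[i] = a.var() / (a - b).var()
    return float(ratios.mean())
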
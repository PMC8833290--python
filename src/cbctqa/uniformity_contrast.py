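"""CT-number accuracy/linearity, edge-vs-center uniformity, and CNR.

Uniformity follows the asymmetric-profile statistic: a band of 10 rows
(lateral) or columns (AP) centered on the phantom midpoint is averaged into
a mean CT-number profile; the non-uniformity is the signed difference
between the profile edge (sampled at 5% and 95% of the *masked* profile
length, whichever differs more in magnitude) and the profile center (50%).
Negative values therefore mean higher CT-numbers in the center (cupping
reads positive, capping/rim deficits negative).

CNR between an insert and adjacent background:

    CNR = (ROI_bkg - ROI_insert) / sqrt((sigma_bkg^2 + sigma_insert^2) / 2)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateFitError, ProfileError, UndefinedCNRError
from .volume_io import CircularROI, ImageVolume, ROIStats, extract_roi_stats

__all__ = [
    "LinearityResult",
    "UniformityResult",
    "CNRResult",
    "ct_number_linearity",
    "uniformity_profile",
    "uniformity_vs_longitudinal",
    "cnr",
    "phantom_mask",
    "background_roi_for_insert",
]

#: Default fraction of the insert radius used for measurement ROIs, chosen to
#: stay clear of partial-volume rims.
INSERT_ROI_FRACTION = 0.6


# --------------------------------------------------------------------------
# CT-number linearity
# --------------------------------------------------------------------------

@dataclass
class LinearityResult:
    table: pd.DataFrame  # columns name, nominal_hu, measured_mean, measured_sd
    slope: float
    intercept: float
    r_squared: float


def ct_number_linearity(vol: ImageVolume,
                        insert_rois: Sequence[tuple],
                        ) -> LinearityResult:
    """OLS of measured mean CT-number on nominal CT-number over the inserts.

    ``insert_rois`` entries are ``(CircularROI, nominal_hu)`` or
    ``(name, CircularROI, nominal_hu)``.  R^2 = 1 - SS_res / SS_tot.
    """
    rows = []
    for entry in insert_rois:
        if len(entry) == 3:
            name, roi, nominal = entry
        else:
            roi, nominal = entry
            name = f"insert_{len(rows)}"
        st = extract_roi_stats(vol, roi)
        rows.append((name, float(nominal), st.mean, st.sd))
    table = pd.DataFrame(rows, columns=["name", "nominal_hu",
                                        "measured_mean", "measured_sd"])
    nominal = table["nominal_hu"].to_numpy()
    measured = table["measured_mean"].to_numpy()
    if len(rows) < 2 or np.ptp(nominal) == 0:
        raise DegenerateFitError("need >=2 inserts with distinct nominal CT-numbers")
    fit = stats.linregress(nominal, measured)
    pred = fit.intercept + fit.slope * nominal
    ss_res = float(np.sum((measured - pred) ** 2))
    ss_tot = float(np.sum((measured - measured.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return LinearityResult(table=table, slope=float(fit.slope),
                           intercept=float(fit.intercept), r_squared=float(r2))


# --------------------------------------------------------------------------
# Uniformity
# --------------------------------------------------------------------------

@dataclass
class UniformityResult:
    direction: str                 # "lateral" | "ap"
    positions_mm: np.ndarray       # along-profile position within the mask
    profile: np.ndarray            # mean CT-number
    edge_low: float                # value at 5% of profile length
    edge_high: float               # value at 95%
    center: float                  # value at 50%
    nonuniformity: float           # signed edge - center, larger |.| edge


def phantom_mask(vol: ImageVolume, slice_index: int,
                 threshold_hu: float = -500.0) -> np.ndarray:
    """Simple phantom support mask: pixels above ``threshold_hu`` (air cut)."""
    return vol.get_slice(slice_index) > threshold_hu


def uniformity_profile(vol: ImageVolume, slice_index: int, direction: str,
                       band_width: int = 10,
                       mask: Optional[np.ndarray] = None,
                       window_mm: float = 0.0) -> UniformityResult:
    """Band-averaged CT-number profile and its signed edge-center statistic.

    ``direction="lateral"`` averages ``band_width`` image rows centered on
    the mask midpoint into a profile over columns; ``"ap"`` does the same
    with columns/rows swapped.  Profile length is the masked phantom extent
    along the direction (5%/95% of image width could fall in air).  Edge and
    center values are linearly interpolated single samples; ``window_mm``
    optionally averages the profile within +-window/2 around each sample
    point (off by default).
    """
    img = vol.get_slice(slice_index)
    if mask is None:
        mask = phantom_mask(vol, slice_index)
    if direction == "ap":
        img = img.T
        mask = mask.T
    elif direction != "lateral":
        raise ValueError(f"direction must be lateral/ap, got {direction!r}")
    dx, dy, _ = vol.spacing
    step = dx if direction == "lateral" else dy

    ridx, cidx = np.nonzero(mask)
    if ridx.size == 0:
        raise ProfileError("empty phantom mask")
    center_row = int(round(ridx.mean()))
    half = band_width // 2
    band = slice(max(center_row - half, 0), center_row - half + band_width)
    center_cols = np.nonzero(mask[center_row])[0]
    cmin, cmax = center_cols.min(), center_cols.max()
    if cmax - cmin + 1 < 20:
        raise ProfileError("mask extent along profile shorter than 20 pixels")
    profile = img[band, cmin:cmax + 1].mean(axis=0)
    positions = np.arange(profile.size) * step
    length = positions[-1]

    def sample(frac: float) -> float:
        x = frac * length
        if window_mm > 0:
            sel = np.abs(positions - x) <= window_mm / 2
            return float(profile[sel].mean())
        return float(np.interp(x, positions, profile))

    edge_low, center, edge_high = sample(0.05), sample(0.50), sample(0.95)
    d_low = edge_low - center
    d_high = edge_high - center
    nonuni = d_low if abs(d_low) >= abs(d_high) else d_high
    return UniformityResult(direction=direction, positions_mm=positions,
                            profile=profile, edge_low=edge_low,
                            edge_high=edge_high, center=center,
                            nonuniformity=float(nonuni))


def uniformity_vs_longitudinal(vols: Sequence[tuple[ImageVolume, float]],
                               slice_index: int = 0,
                               band_width: int = 10) -> pd.DataFrame:
    """Lateral and AP non-uniformity per longitudinal phantom offset.

    Returns a table with one row per offset plus ``attrs["max_spread"]``
    (max - min non-uniformity over offsets, worst direction).
    """
    if len(vols) < 2:
        raise ProfileError("need at least two longitudinal offsets")
    rows = []
    for vol, offset in vols:
        lat = uniformity_profile(vol, slice_index, "lateral", band_width)
        ap = uniformity_profile(vol, slice_index, "ap", band_width)
        rows.append((float(offset), lat.nonuniformity, ap.nonuniformity))
    table = pd.DataFrame(rows, columns=["offset_mm", "lateral", "ap"])
    spread = {d: float(table[d].max() - table[d].min()) for d in ("lateral", "ap")}
    table.attrs["spread"] = spread
    table.attrs["max_spread"] = max(spread.values())
    return table


# --------------------------------------------------------------------------
# CNR
# --------------------------------------------------------------------------

@dataclass
class CNRResult:
    insert_name: str
    cnr: float
    insert_stats: ROIStats
    background_stats: ROIStats


def cnr(insert_stats: ROIStats, background_stats: ROIStats,
        insert_name: str = "") -> CNRResult:
    """Contrast-to-noise ratio; sign follows (background - insert)."""
    denom2 = 0.5 * (background_stats.sd ** 2 + insert_stats.sd ** 2)
    if denom2 == 0:
        raise UndefinedCNRError("both ROI standard deviations are zero")
    value = (background_stats.mean - insert_stats.mean) / np.sqrt(denom2)
    return CNRResult(insert_name=insert_name, cnr=float(value),
                     insert_stats=insert_stats, background_stats=background_stats)


def background_roi_for_insert(target: CircularROI,
                              all_insert_centers: Sequence[tuple[float, float]],
                              phantom_center: tuple[float, float],
                              radius: Optional[float] = None) -> CircularROI:
    """Adjacent background ROI: same radial distance as the insert, rotated
    into the most insert-free azimuth near the target.

    Candidates are the midpoints of the *widest* gaps between occupied
    azimuths (the genuinely insert-free sector); ties are broken by
    proximity to the target's azimuth.
    """
    cy, cx = phantom_center
    t_az = np.arctan2(target.center[0] - cy, target.center[1] - cx)
    r_ring = float(np.hypot(target.center[0] - cy, target.center[1] - cx))
    az = np.sort([np.arctan2(r - cy, c - cx) for r, c in all_insert_centers])
    gaps = []  # (width, midpoint)
    for i in range(len(az)):
        a = az[i]
        b = az[(i + 1) % len(az)] + (2 * np.pi if i == len(az) - 1 else 0)
        if b - a > 1e-6:
            gaps.append((b - a, (a + b) / 2.0))
    if not gaps:
        raise ProfileError("no insert-free azimuth available")
    max_w = max(w for w, _ in gaps)
    widest = [mid for w, mid in gaps if w >= max_w - 1e-9]
    def angdist(a: float, b: float) -> float:
        d = abs(a - b) % (2 * np.pi)
        return min(d, 2 * np.pi - d)
    best = min(widest, key=lambda g: angdist(g, t_az))
    center = (cy + r_ring * np.sin(best), cx + r_ring * np.cos(best))
    return CircularROI(slice_index=target.slice_index, center=center,
                       radius=radius if radius is not None else target.radius)
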
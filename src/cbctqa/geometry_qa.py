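"""Geometric-stability QA: flexmap-calibration reproducibility and imaging fidelity.

The scanner's geometric calibration ("flexmap") yields, per gantry angle, nine
corrections: focal-spot translations tSx/tSy/tSz and detector-midpoint
translations tCx/tCy/tCz (mm) plus detector Euler rotations rx/ry/rz (deg).
The x component points along the gantry rotation direction, y along the
rotational axis, z radially in the tomographic plane.  Repeating the
calibration gives reproducibility statistics; rod landmarks in an image give
imaging fidelity (measured vs. physical inter-rod distances).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import AlignmentError, DetectionError, MatchingError
from .volume_io import ImageVolume

__all__ = [
    "CORRECTIONS",
    "CalibrationRecord",
    "CalibrationStats",
    "FidelityResult",
    "calibration_schedule",
    "calibration_stats",
    "detect_rods",
    "imaging_fidelity",
    "square_layout",
    "records_to_csv",
    "records_from_csv",
]

#: The nine per-angle geometric corrections, in canonical column order.
CORRECTIONS: tuple[str, ...] = (
    "tSx", "tSy", "tSz", "tCx", "tCy", "tCz", "rx", "ry", "rz",
)


# --------------------------------------------------------------------------
# Calibration records and reproducibility statistics
# --------------------------------------------------------------------------

@dataclass
class CalibrationRecord:
    """Per-angle 9-DOF corrections for one calibration run and rotation direction."""

    run_id: str
    direction: str  # "cw" | "ccw"
    angles: np.ndarray
    corrections: pd.DataFrame  # index = angles, columns = CORRECTIONS

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.direction not in ("cw", "ccw"):
            raise ValueError(f"direction must be cw/ccw, got {self.direction!r}")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        missing = [c for c in CORRECTIONS if c not in self.corrections.columns]
        if missing:
            raise ValueError(f"corrections table missing columns {missing}")
        if len(self.corrections) != len(self.angles):
            raise ValueError("one corrections row required per angle")
        self.corrections = self.corrections.loc[:, list(CORRECTIONS)].set_axis(self.angles)


def calibration_schedule(start: float, range_deg: float, step: float) -> np.ndarray:
    """Inclusive arithmetic angle sequence; count = floor(range/step) + 1.

    The device acquires its calibration over a 520 deg orbit in 10 deg steps,
    i.e. 53 projection views.  If ``step`` does not divide ``range_deg`` a
    warning is emitted and the last view sits at the largest multiple.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if range_deg < 0:
        raise ValueError("range must be non-negative")
    n = int(np.floor(range_deg / step + 1e-9)) + 1
    if abs((n - 1) * step - range_deg) > 1e-9 * max(1.0, range_deg):
        warnings.warn(
            f"step {step} does not divide range {range_deg}; "
            f"last view at {(n - 1) * step}", stacklevel=2)
    return start + step * np.arange(n)


@dataclass
class CalibrationStats:
    """Reproducibility summary over repeated calibration runs.

    All tables are indexed/columned by the nine correction names.  Across-run
    SDs use ddof=1; when both rotation directions are present the per-angle
    SD is the mean of the per-direction across-run SDs.
    """

    overall_mean: pd.Series
    overall_sd: pd.Series
    per_angle_sd: pd.DataFrame          # index angles, columns corrections
    max_per_angle_sd: pd.Series
    mean_per_angle_sd: pd.Series
    sd_per_angle_sd: pd.Series
    hysteresis_abs: Optional[pd.DataFrame]  # per-angle |mean(CW-CCW)|
    max_hysteresis: Optional[pd.Series]
    n_runs: int
    directions: tuple[str, ...]


def calibration_stats(records: Sequence[CalibrationRecord],
                      overall_sd: str = "pooled") -> CalibrationStats:
    """Reproducibility statistics over >=2 calibration runs.

    Parameters
    ----------
    records
        One record per (run, direction); all must share the angle grid.
    overall_sd
        ``"pooled"`` (default): overall mean/SD over the pool of all
        (angle, run, direction) samples.  ``"run_means"``: SD across the
        per-run orbit means instead.

    The CW/CCW difference is formed per run (CW minus CCW at each angle),
    averaged over runs per angle, and the absolute value taken *after*
    averaging.
    """
    if len(records) < 2:
        raise AlignmentError("need at least two calibration records")
    angles = records[0].angles
    for rec in records[1:]:
        if len(rec.angles) != len(angles) or not np.allclose(rec.angles, angles):
            raise AlignmentError(
                f"angle grid of run {rec.run_id!r} does not match the first record")
    directions = tuple(sorted({r.direction for r in records}))
    run_ids = sorted({r.run_id for r in records})
    n_runs = len(run_ids)
    if n_runs < 2:
        raise AlignmentError("need at least two distinct runs")

    pool = pd.concat([r.corrections for r in records])
    overall_mean = pool.mean()
    if overall_sd == "pooled":
        overall_sd_s = pool.std(ddof=1)
    elif overall_sd == "run_means":
        by_run = pd.DataFrame({rid: pd.concat(
            [r.corrections for r in records if r.run_id == rid]).mean()
            for rid in run_ids}).T
        overall_sd_s = by_run.std(ddof=1)
    else:
        raise ValueError(f"unknown overall_sd mode {overall_sd!r}")

    # per-angle SD across runs, within each direction, averaged over directions
    per_dir_sds = []
    for d in directions:
        stack = np.stack([r.corrections.to_numpy() for r in records
                          if r.direction == d])  # (runs, angles, 9)
        if stack.shape[0] >= 2:
            per_dir_sds.append(stack.std(axis=0, ddof=1))
    if not per_dir_sds:
        raise AlignmentError("per-angle SD needs >=2 runs in at least one direction")
    per_angle_sd = pd.DataFrame(np.mean(per_dir_sds, axis=0), index=angles,
                                columns=list(CORRECTIONS))

    hysteresis_abs = max_hyst = None
    if "cw" in directions and "ccw" in directions:
        diffs = []
        for rid in run_ids:
            cw = [r for r in records if r.run_id == rid and r.direction == "cw"]
            ccw = [r for r in records if r.run_id == rid and r.direction == "ccw"]
            if cw and ccw:
                diffs.append(cw[0].corrections.to_numpy() - ccw[0].corrections.to_numpy())
        if diffs:
            hysteresis_abs = pd.DataFrame(np.abs(np.mean(diffs, axis=0)),
                                          index=angles, columns=list(CORRECTIONS))
            max_hyst = hysteresis_abs.max()

    return CalibrationStats(
        overall_mean=overall_mean,
        overall_sd=overall_sd_s,
        per_angle_sd=per_angle_sd,
        max_per_angle_sd=per_angle_sd.max(),
        mean_per_angle_sd=per_angle_sd.mean(),
        sd_per_angle_sd=per_angle_sd.std(ddof=1),
        hysteresis_abs=hysteresis_abs,
        max_hysteresis=max_hyst,
        n_runs=n_runs,
        directions=directions,
    )


def records_to_csv(records: Sequence[CalibrationRecord], path: Union[str, Path]) -> Path:
    """Write calibration runs as long-format CSV (run_id, direction, angle_deg, tSx..rz)."""
    rows = []
    for rec in records:
        frame = rec.corrections.reset_index(names="angle_deg")
        frame.insert(0, "direction", rec.direction)
        frame.insert(0, "run_id", rec.run_id)
        rows.append(frame)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    return Path(path)


def records_from_csv(path: Union[str, Path]) -> list[CalibrationRecord]:
    df = pd.read_csv(path)
    records = []
    for (rid, direction), grp in df.groupby(["run_id", "direction"], sort=True):
        grp = grp.sort_values("angle_deg")
        records.append(CalibrationRecord(
            run_id=str(rid), direction=str(direction),
            angles=grp["angle_deg"].to_numpy(),
            corrections=grp[list(CORRECTIONS)].reset_index(drop=True)))
    return records


# --------------------------------------------------------------------------
# Rod detection and imaging fidelity
# --------------------------------------------------------------------------

def detect_rods(vol: ImageVolume, slice_index: int,
                expected_hu_polarity: str = "bright",
                n_rods: int = 4,
                search_radius_mm: Optional[float] = None) -> np.ndarray:
    """Threshold-based rod detection; returns (n_rods, 2) centers as (row, col) mm.

    The threshold sits halfway between the background histogram mode and the
    rod plateau (top 0.2 percentile of the search region); the ``n_rods``
    largest connected components are kept and located by intensity-weighted
    centroid.  Assumes the rods jointly cover at least ~0.2% of the region.
    ``search_radius_mm`` restricts the search to a disk around the slice
    center, which excludes other high-contrast structures (e.g. sensitometry
    inserts) when the rods sit well inside them.
    """
    img = vol.get_slice(slice_index)
    work = (img if expected_hu_polarity == "bright" else -img).copy()
    if search_radius_mm is not None:
        rows_c, cols_c = vol.slice_grid_mm()
        rr = rows_c - rows_c.mean()
        cc = cols_c - cols_c.mean()
        outside = rr[:, None] ** 2 + cc[None, :] ** 2 > search_radius_mm ** 2
        work[outside] = np.median(work)
    counts, edges = np.histogram(work, bins=256)
    bg_mode = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
    plateau = float(np.percentile(work, 99.8))
    if plateau - bg_mode < 1.0:
        raise DetectionError("no high-contrast plateau distinguishable from background")
    threshold = 0.5 * (bg_mode + plateau)
    labels, n_comp = ndimage.label(work > threshold)
    if n_comp < n_rods:
        raise DetectionError(f"found {n_comp} components, expected {n_rods}")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_comp + 1))
    keep = np.argsort(sizes)[::-1][:n_rods] + 1
    rows_mm, cols_mm = vol.slice_grid_mm()
    centers = []
    for lab in keep:
        mask = labels == lab
        w = np.clip(work[mask] - bg_mode, 0, None)
        ridx, cidx = np.nonzero(mask)
        wsum = w.sum()
        centers.append((float((w * rows_mm[ridx]).sum() / wsum),
                        float((w * cols_mm[cidx]).sum() / wsum)))
    centers = np.array(sorted(centers))
    return centers


@dataclass
class FidelityResult:
    """Pairwise rod-distance agreement with the physical layout."""

    rod_centers: np.ndarray          # (4, 2) mm
    pair_distances: np.ndarray       # 6 measured distances, ascending
    nominal_distances: np.ndarray    # 6 nominal distances, ascending
    abs_errors: np.ndarray
    mean_abs_error: float
    sd_abs_error: float

    @property
    def mean_side_length(self) -> float:
        """Mean of the four shortest (side) distances, mm."""
        return float(self.pair_distances[:4].mean())


def square_layout(side: float) -> np.ndarray:
    """The six pair distances of a square: four sides and two diagonals."""
    return np.array([side] * 4 + [side * np.sqrt(2.0)] * 2)


def imaging_fidelity(centers: np.ndarray,
                     nominal_layout: Union[float, Sequence[float]]) -> FidelityResult:
    """Pairwise Euclidean distances between four rod centers vs. nominal lengths.

    ``nominal_layout`` is either the six nominal pair distances or a scalar
    square side length (expanded to 4 sides + 2 diagonals).  Measured and
    nominal distances are matched by rank order, which requires the nominal
    side/diagonal groups to be distinct.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.shape != (4, 2):
        raise MatchingError(f"need exactly 4 centers, got shape {centers.shape}")
    nominal = (square_layout(float(nominal_layout))
               if np.isscalar(nominal_layout) else np.asarray(nominal_layout, dtype=float))
    if nominal.shape != (6,):
        raise MatchingError("nominal layout must provide 6 pair distances")
    nominal = np.sort(nominal)
    if nominal[3] >= nominal[4] - 1e-9:
        raise MatchingError("degenerate nominal layout: side and diagonal lengths coincide")
    dists = np.sort([float(np.hypot(*(a - b)))
                     for a, b in itertools.combinations(centers, 2)])
    errors = np.abs(dists - nominal)
    return FidelityResult(
        rod_centers=centers,
        pair_distances=dists,
        nominal_distances=nominal,
        abs_errors=errors,
        mean_abs_error=float(errors.mean()),
        sd_abs_error=float(errors.std(ddof=1)),
    )
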
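"""Weighted cone-beam dose index and per-protocol QA report assembly.

The CBDI_w combines the dose-length products (DLP, mGy cm) measured by a
pencil ionization chamber in the central and the four peripheral drill
holes of the body dosimetry phantom:

    CBDI_w = DLP_central / (3 L) + 2 * mean(DLP_peripheral) / (3 L)

with L the chamber length (10 cm by default, carried as data so other
chambers are representable).  The weights 1/3 + 2/3 sum to one over L.
Reports mirror the per-protocol metric table: CBDI_w, CNR triplet,
lateral/AP non-uniformity, noise (raw and dose-normalized), imaging
fidelity and limiting frequency, with missing metrics rendered as explicit
nulls and every cell traceable to run metadata.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import CollisionError, SchemaError

__all__ = [
    "POSITIONS",
    "REPORT_METRICS",
    "CBDIResult",
    "QAReport",
    "read_dose_table",
    "cbdi_w",
    "assemble_report",
]

POSITIONS = ("central", "peripheral_1", "peripheral_2", "peripheral_3", "peripheral_4")

#: Canonical report columns (one per metric table cell).
REPORT_METRICS = (
    "cbdi_w_mGy",
    "cnr_ldpe", "cnr_polystyrene", "cnr_delrin",
    "nonuniformity_lateral_hu", "nonuniformity_ap_hu",
    "sigma_nps_hu", "noise_at_1mGy_hu",
    "fidelity_mm", "f_lim_lp_cm",
)


def read_dose_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate one DLP table (CSV: position, dlp_mGy_cm, chamber_length_cm)."""
    table = pd.read_csv(path)
    return validate_dose_table(table)


def validate_dose_table(table: pd.DataFrame) -> pd.DataFrame:
    for col in ("position", "dlp_mGy_cm", "chamber_length_cm"):
        if col not in table.columns:
            raise SchemaError(f"dose table missing column {col!r}")
    seen = set(table["position"])
    missing = [p for p in POSITIONS if p not in seen]
    if missing or len(table) != 5:
        raise SchemaError(f"dose table must have exactly rows {POSITIONS}; "
                          f"missing {missing}")
    if (table["dlp_mGy_cm"] < 0).any():
        raise SchemaError("DLP values must be >= 0")
    return table


@dataclass
class CBDIResult:
    cbdi_w: float                       # mGy (mean over replicates)
    dlp_central: float                  # mGy cm (mean over replicates)
    dlp_peripheral_mean: float          # mGy cm
    peripheral_to_central_ratio: float
    replicates: list[float]             # per-table CBDI_w values
    sd: Optional[float] = None          # ddof=1 over replicates, None if single


def cbdi_w(tables: Union[pd.DataFrame, Sequence[pd.DataFrame]]) -> CBDIResult:
    """Exact weighted dose-index evaluation, aggregating replicate tables.

    The index is linear in every DLP; replicate SD uses n-1.
    """
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    if not tables:
        raise SchemaError("at least one dose table required")
    values, centrals, peripherals = [], [], []
    for table in tables:
        table = validate_dose_table(table)
        length = float(table["chamber_length_cm"].iloc[0])
        if length <= 0:
            raise SchemaError("chamber length must be positive")
        central = float(table.loc[table["position"] == "central", "dlp_mGy_cm"].iloc[0])
        periph = float(table.loc[table["position"] != "central", "dlp_mGy_cm"].mean())
        values.append(central / (3.0 * length) + 2.0 * periph / (3.0 * length))
        centrals.append(central)
        peripherals.append(periph)
    mean_central = float(np.mean(centrals))
    mean_periph = float(np.mean(peripherals))
    return CBDIResult(
        cbdi_w=float(np.mean(values)),
        dlp_central=mean_central,
        dlp_peripheral_mean=mean_periph,
        peripheral_to_central_ratio=(mean_periph / mean_central
                                     if mean_central > 0 else float("nan")),
        replicates=[float(v) for v in values],
        sd=float(np.std(values, ddof=1)) if len(values) > 1 else None,
    )


# --------------------------------------------------------------------------
# Report assembly
# --------------------------------------------------------------------------

@dataclass
class QAReport:
    """Per-protocol metric table plus run metadata.

    ``cells[protocol][metric]`` is ``{"value", "sd", "n"}`` (sd/n None for
    single measurements); missing metrics are explicit ``None`` cells.
    """

    cells: dict
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for protocol, metrics in self.cells.items():
            rows[protocol] = {m: (c["value"] if c else None)
                              for m, c in metrics.items()}
        return pd.DataFrame.from_dict(rows, orient="index",
                                      columns=list(REPORT_METRICS))

    def to_json(self) -> str:
        return json.dumps({"cells": self.cells, "metadata": self.metadata},
                          indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "QAReport":
        payload = json.loads(text)
        return cls(cells=payload["cells"], metadata=payload.get("metadata", {}))

    def to_csv(self, path: Union[str, Path]) -> Path:
        self.to_frame().to_csv(path, index_label="protocol")
        return Path(path)


def assemble_report(entries: Iterable[tuple[str, str, object]],
                    metadata: Optional[dict] = None) -> QAReport:
    """Assemble per-protocol rows from (protocol, metric, value) entries.

    ``value`` may be a scalar or a sequence of replicates (aggregated to
    mean +- SD with n recorded).  Duplicate (protocol, metric) pairs raise
    :class:`CollisionError`; metrics never measured for a protocol appear
    as explicit nulls.
    """
    cells: dict = {}
    for protocol, metric, value in entries:
        if metric not in REPORT_METRICS:
            raise SchemaError(f"unknown report metric {metric!r}; "
                              f"expected one of {REPORT_METRICS}")
        row = cells.setdefault(protocol, {m: None for m in REPORT_METRICS})
        if row[metric] is not None:
            raise CollisionError(f"duplicate metric {metric!r} for protocol {protocol!r}")
        if isinstance(value, (list, tuple, np.ndarray)):
            arr = np.asarray(value, dtype=float)
            cell = {"value": float(arr.mean()),
                    "sd": float(arr.std(ddof=1)) if arr.size > 1 else None,
                    "n": int(arr.size)}
        else:
            cell = {"value": float(value), "sd": None, "n": 1}
        row[metric] = cell
    if not cells:
        raise SchemaError("no metrics supplied")
    meta = dict(metadata or {})
    meta.setdefault("generator", "cbctqa")
    return QAReport(cells=cells, metadata=meta)


def file_sha256(path: Union[str, Path]) -> str:
    """Hash of an input file, for report traceability."""
    digest = hashlib.sha256()
    digest.update(Path(path).read_bytes())
    return digest.hexdigest()
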
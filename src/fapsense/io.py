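"""Reading and writing the pipeline's CSV interchange formats.

Long-format CSV is the single interchange format: one row per well and time
point for plates, one row per well for fit results and summaries.  Output is
deterministic (fixed column order, fixed float precision), so identical runs
produce identical bytes.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import RaggedGridError, SchemaError
from .plate import PLATE_COLUMNS, PlateTimeSeries, Well
from .sysid import FitResult

__all__ = [
    "read_plate_csv",
    "write_plate_csv",
    "fit_record",
    "results_frame",
    "write_results",
    "RESULT_COLUMNS",
]

#: canonical column order of the identification results table — the
#: machine-readable analogue of a per-construct (K, tau_1, tau_2) table
RESULT_COLUMNS = [
    "well_id",
    "construct",
    "iptg_mM",
    "arabinose_pct",
    "substrate",
    "replicate",
    "order",
    "K",
    "tau_z",
    "tau_1",
    "tau_2",
    "tau_3",
    "r_squared",
    "residual_variance",
    "stable",
    "real_poles",
    "n_samples",
]


def write_plate_csv(plate: PlateTimeSeries, path) -> Path:
    """Write a plate as long-format CSV (full float precision, round-trips)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # shortest round-trip repr so reading back reproduces the exact floats
    df = plate.to_frame()
    for col in ("iptg_mM", "arabinose_pct", "time_min", "od600", "rfp"):
        df[col] = df[col].map(lambda v: repr(float(v)))
    df.to_csv(path, index=False)
    return path


def read_plate_csv(path) -> PlateTimeSeries:
    """Read and validate a long-format plate CSV.

    Raises :class:`SchemaError` naming any missing column, and
    :class:`RaggedGridError` naming the first well whose time vector does not
    match the shared grid.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty plate file") from exc
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")

    grid = np.sort(df["time_min"].unique().astype(float))
    wells = []
    for well_id, grp in df.groupby("well_id", sort=False):
        t = grp["time_min"].to_numpy(dtype=float)
        if t.size != grid.size or not np.array_equal(np.sort(t), grid):
            raise RaggedGridError(
                f"{path}: well {well_id} has {t.size} time points; "
                f"expected the shared grid of {grid.size}"
            )
        grp = grp.sort_values("time_min")
        meta = grp.iloc[0]
        wells.append(
            Well(
                well_id=str(well_id),
                construct=str(meta["construct"]),
                iptg_mm=float(meta["iptg_mM"]),
                arabinose_pct=float(meta["arabinose_pct"]),
                substrate=bool(meta["substrate"]),
                replicate=int(meta["replicate"]),
                od=grp["od600"].to_numpy(dtype=float),
                rfp=grp["rfp"].to_numpy(dtype=float),
            )
        )
    try:
        return PlateTimeSeries(time_min=grid, wells=tuple(wells))
    except Exception as exc:  # non-uniform grid etc.
        raise SchemaError(f"{path}: {exc}") from exc


def fit_record(fit: FitResult, order: int, **meta) -> dict:
    """Flatten one :class:`FitResult` (plus well metadata) into a table row."""
    row = dict(meta)
    row["order"] = order
    cont = fit.continuous
    row["K"] = cont.k if cont is not None else math.nan
    row["tau_z"] = cont.tau_z if cont is not None else math.nan
    for i in range(1, 4):
        row[f"tau_{i}"] = (
            cont.tau_p[i - 1] if cont is not None and len(cont.tau_p) >= i else math.nan
        )
    row["r_squared"] = fit.r_squared
    row["residual_variance"] = fit.residual_variance
    row["stable"] = fit.validity.stable
    row["real_poles"] = fit.validity.real_poles
    row["n_samples"] = fit.n_samples
    return row


def results_frame(records) -> pd.DataFrame:
    """Records to a DataFrame in the canonical column order."""
    df = pd.DataFrame(list(records))
    ordered = [c for c in RESULT_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in ordered]
    return df[ordered + sorted(extra)]


def write_results(df: pd.DataFrame, path) -> Path:
    """Write a results table deterministically (canonical order, %.8g floats)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ordered = [c for c in RESULT_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in ordered]
    df[ordered + sorted(extra)].to_csv(path, index=False, float_format="%.8g")
    return path
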
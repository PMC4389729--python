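"""In-memory container for plate-reader kinetic runs.

A :class:`PlateTimeSeries` holds per-well OD600 and fluorescence trajectories
on one shared, uniform time grid (default spacing 12 min — one reading per
well every 12 minutes), together with the condition metadata needed by the
analyses: construct label, IPTG (mM), arabinose (%), substrate
supplementation, replicate index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = ["Well", "PlateTimeSeries", "PLATE_COLUMNS"]

#: canonical long-format column order for plate CSV files
PLATE_COLUMNS = [
    "well_id",
    "construct",
    "iptg_mM",
    "arabinose_pct",
    "substrate",
    "replicate",
    "time_min",
    "od600",
    "rfp",
]


@dataclass(frozen=True)
class Well:
    """One well's metadata and measured trajectories."""

    well_id: str
    construct: str
    iptg_mm: float
    arabinose_pct: float
    substrate: bool
    replicate: int
    od: np.ndarray = field(repr=False)
    rfp: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class PlateTimeSeries:
    """All wells of one run on a shared uniform time grid (minutes)."""

    time_min: np.ndarray
    wells: tuple

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise InvalidParameterError("time grid must be 1-D with at least two samples")
        dt = np.diff(t)
        if not (dt[0] > 0 and np.allclose(dt, dt[0], rtol=1e-8, atol=0)):
            raise InvalidParameterError("time grid must be uniform and increasing")
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "wells", tuple(self.wells))
        for w in self.wells:
            if len(w.od) != t.size or len(w.rfp) != t.size:
                raise InvalidParameterError(
                    f"well {w.well_id}: series length does not match the time grid"
                )

    @property
    def ts(self) -> float:
        """Sampling period (min)."""
        return float(self.time_min[1] - self.time_min[0])

    def well(self, well_id: str) -> Well:
        for w in self.wells:
            if w.well_id == well_id:
                return w
        raise KeyError(well_id)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per well and time point."""
        n = self.time_min.size
        frames = []
        for w in self.wells:
            frames.append(
                pd.DataFrame(
                    {
                        "well_id": w.well_id,
                        "construct": w.construct,
                        "iptg_mM": w.iptg_mm,
                        "arabinose_pct": w.arabinose_pct,
                        "substrate": w.substrate,
                        "replicate": w.replicate,
                        "time_min": self.time_min,
                        "od600": np.asarray(w.od, dtype=float),
                        "rfp": np.asarray(w.rfp, dtype=float),
                    }
                )
            )
        if not frames:
            return pd.DataFrame(columns=PLATE_COLUMNS)
        return pd.concat(frames, ignore_index=True)[PLATE_COLUMNS]
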
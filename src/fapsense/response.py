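"""Plate-response analyses: readouts, dose-response, correlations, statistics.

Cultures are compared at a fixed physiological anchor — the fluorescence when
the culture first reaches OD 0.6 (log phase, before stationary-phase
artifacts such as arabinose depletion).  On top of that readout the module
builds dose-response curves, correlates identified sensor parameters with
induction, tests substrate supplementation effects (Welch t-test), and
quantifies reproducibility as the coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError, NoGrowthError
from .plate import PlateTimeSeries

__all__ = [
    "WellSummary",
    "DoseResponseCurve",
    "readout_at_od",
    "normalize_rfp_od",
    "well_summaries",
    "dose_response",
    "pearson_r",
    "CorrelationReport",
    "param_induction_correlation",
    "SubstrateEffect",
    "substrate_effect_test",
    "replicate_cv",
]


@dataclass(frozen=True)
class WellSummary:
    well_id: str
    construct: str
    iptg_mm: float
    arabinose_pct: float
    substrate: bool
    replicate: int
    fluorescence_at_od: float
    crossing_time_min: float


@dataclass(frozen=True)
class DoseResponseCurve:
    """Mean readout and dispersion per inducer concentration (ascending)."""

    concentrations_mm: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray


def readout_at_od(time_min, od, rfp, od_threshold: float = 0.6):
    """Fluorescence at the first upward crossing of the OD threshold.

    Linear interpolation between the bracketing samples; an on-grid hit
    returns that sample.  Later crossings (after lysis dips) are ignored.
    Returns ``(fluorescence, crossing_time)``; raises :class:`NoGrowthError`
    if the OD never reaches the threshold.
    """
    t = np.asarray(time_min, dtype=float)
    od = np.asarray(od, dtype=float)
    rfp = np.asarray(rfp, dtype=float)
    if od[0] >= od_threshold:
        raise InvalidParameterError(
            f"OD series must start below the threshold {od_threshold}, got {od[0]}"
        )
    above = np.nonzero(od >= od_threshold)[0]
    if above.size == 0:
        raise NoGrowthError(f"OD never reaches {od_threshold} (max {od.max():.3g})")
    k = above[0]
    if od[k] == od_threshold:
        return float(rfp[k]), float(t[k])
    frac = (od_threshold - od[k - 1]) / (od[k] - od[k - 1])
    return (
        float(rfp[k - 1] + frac * (rfp[k] - rfp[k - 1])),
        float(t[k - 1] + frac * (t[k] - t[k - 1])),
    )


def normalize_rfp_od(od, rfp, od_floor: float = 0.05) -> np.ma.MaskedArray:
    """Elementwise RFP/OD with samples below the OD floor masked, not infinite."""
    od = np.asarray(od, dtype=float)
    rfp = np.asarray(rfp, dtype=float)
    mask = od < od_floor
    safe = np.where(mask, 1.0, od)
    return np.ma.MaskedArray(rfp / safe, mask=mask)


def well_summaries(
    plate: PlateTimeSeries, od_threshold: float = 0.6
) -> pd.DataFrame:
    """OD-threshold readout for every well that grows; one row per well.

    Wells that never cross the threshold are reported with NaN readout and a
    ``grew = False`` flag rather than dropped, mirroring no-growth wells.
    """
    rows = []
    for w in plate.wells:
        try:
            fl, tc = readout_at_od(plate.time_min, w.od, w.rfp, od_threshold)
            grew = True
        except NoGrowthError:
            fl, tc, grew = np.nan, np.nan, False
        rows.append(
            {
                "well_id": w.well_id,
                "construct": w.construct,
                "iptg_mM": w.iptg_mm,
                "arabinose_pct": w.arabinose_pct,
                "substrate": w.substrate,
                "replicate": w.replicate,
                "fluorescence_at_od": fl,
                "crossing_time_min": tc,
                "grew": grew,
            }
        )
    return pd.DataFrame(rows)


def dose_response(doses, readouts) -> DoseResponseCurve:
    """Per-concentration mean, sample SD and replicate count.

    Input order is irrelevant; concentrations are reported strictly
    increasing.  Requires at least two distinct concentrations.
    """
    doses = np.asarray(doses, dtype=float)
    readouts = np.asarray(readouts, dtype=float)
    if doses.shape != readouts.shape or doses.ndim != 1:
        raise InvalidParameterError("doses and readouts must be aligned 1-D arrays")
    levels = np.unique(doses)
    if levels.size < 2:
        raise InvalidParameterError("need at least two inducer concentrations")
    mean, sd, n = [], [], []
    for c in levels:
        vals = readouts[doses == c]
        mean.append(vals.mean())
        sd.append(vals.std(ddof=1) if vals.size > 1 else 0.0)
        n.append(vals.size)
    return DoseResponseCurve(
        concentrations_mm=levels,
        mean=np.array(mean),
        sd=np.array(sd),
        n=np.array(n, dtype=int),
    )


def pearson_r(x, y):
    """Sample Pearson correlation with its two-sided t-distributed p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidParameterError("need aligned samples with n >= 3")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise InvalidParameterError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class CorrelationReport:
    """Parameter-vs-induction correlations and the time-constant clustering."""

    correlations: dict  # parameter -> (r, p)
    within_construct_spread: float
    between_construct_separation: float

    @property
    def clusters_by_construct(self) -> bool:
        return self.within_construct_spread < self.between_construct_separation


def param_induction_correlation(fits: pd.DataFrame) -> CorrelationReport:
    """Correlate identified parameters with log10(IPTG) across wells.

    ``fits`` needs columns construct, iptg_mM, K, tau_1, tau_2 (tau_z
    optional); rows with missing parameters (invalid fits) are dropped.
    Doses span decades, hence the log scale.  The clustering summary
    compares, in log-tau space, the mean within-construct scatter around the
    construct centroid with the mean pairwise centroid separation.
    """
    params = [c for c in ("K", "tau_1", "tau_2", "tau_z") if c in fits.columns]
    df = fits.dropna(subset=[c for c in params if c != "tau_z"])
    if df["iptg_mM"].nunique() < 4:
        raise InvalidParameterError("need fits from at least 4 induction levels")
    logdose = np.log10(df["iptg_mM"].to_numpy())
    correlations = {}
    for p in params:
        try:
            correlations[p] = pearson_r(logdose, df[p].to_numpy())
        except InvalidParameterError:  # degenerate (constant) parameter
            correlations[p] = (np.nan, np.nan)

    pts = np.log10(df[["tau_1", "tau_2"]].to_numpy())
    centroids = {}
    spreads = []
    for name, grp in df.groupby("construct"):
        g = np.log10(grp[["tau_1", "tau_2"]].to_numpy())
        centroids[name] = g.mean(axis=0)
        if len(g) > 1:
            spreads.append(np.linalg.norm(g - g.mean(axis=0), axis=1).mean())
    cent = list(centroids.values())
    seps = [
        np.linalg.norm(cent[i] - cent[j])
        for i in range(len(cent))
        for j in range(i + 1, len(cent))
    ]
    return CorrelationReport(
        correlations=correlations,
        within_construct_spread=float(np.mean(spreads)) if spreads else np.nan,
        between_construct_separation=float(np.mean(seps)) if seps else np.nan,
    )


@dataclass(frozen=True)
class SubstrateEffect:
    p_value: float
    significant: bool
    direction: int  # sign of mean(with substrate) - mean(without)


def substrate_effect_test(with_substrate, without_substrate, alpha: float = 0.05) -> SubstrateEffect:
    """Welch two-sample t-test for a substrate supplementation effect.

    ``direction`` is +1 when the substrate boosts the readout, -1 when it
    hinders it (both occur: malonate boosts the synthase construct but
    hinders the transferase one).  Requires >= 2 replicates per group.
    """
    a = np.asarray(with_substrate, dtype=float)
    b = np.asarray(without_substrate, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidParameterError("need at least 2 replicates per group")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return SubstrateEffect(
        p_value=float(p),
        significant=bool(p < alpha),
        direction=int(np.sign(a.mean() - b.mean())),
    )


def replicate_cv(values) -> float:
    """Coefficient of variation: sample (n-1) SD over the mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InvalidParameterError("need at least 2 replicates")
    m = v.mean()
    if m <= 0:
        raise InvalidParameterError(f"CV requires a positive mean, got {m}")
    return float(v.std(ddof=1) / m)
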
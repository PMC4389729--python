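"""Mechanistic model of the FapR/RFP malonyl-CoA sensor cascade.

Three coupled balances link biomass X(t) to fluorescence R(t):

* malonyl-CoA M(t):  dM/dt = vm*X - vg*dX/dt - gamma_m*M
  (production proportional to biomass, consumption proportional to growth,
  first-order turnover),
* FapR:malonyl-CoA complex C(t):  dC/dt = kf*F*M - kr*C
  (mass-action binding to a constant pool F of the transcription factor;
  the dissociation constant is Kd = kr/kf, 2.4 uM for FapR),
* reporter R(t):  dR/dt = kappa*C - gamma_r*R
  (promoter-strength constant kappa, reporter decay/dilution gamma_r).

All states start at zero unless overridden; with vg = 0 and non-negative
inputs every state stays non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .errors import InvalidParameterError

__all__ = ["SensorParams", "CascadeResult", "simulate_sensor_cascade", "DEFAULT_KD"]

#: FapR-malonyl-CoA dissociation constant (uM).
DEFAULT_KD = 2.4


@dataclass(frozen=True)
class SensorParams:
    """Rate constants of the mechanistic sensor cascade.

    Units: concentrations in uM, biomass in OD units, time in minutes.

    Attributes
    ----------
    vm : float
        Malonyl-CoA production rate (uM/(OD*min)); construct and
        induction specific.
    gamma_m : float
        Malonyl-CoA turnover rate (1/min).
    kf : float
        FapR-malonyl-CoA association rate (1/(uM*min)); must be > 0 so that
        Kd = kr/kf is defined.
    kr : float
        Complex dissociation rate (1/min).
    f : float
        Free FapR concentration (uM), held constant (set by arabinose).
    kappa : float
        Promoter-strength constant (fluorescence/(uM*min)).
    gamma_r : float
        Reporter decay/dilution rate (1/min).
    vg : float
        Growth-linked malonyl-CoA consumption (uM/OD); default 0 — the term
        is implemented but the growth drain is not separately measurable from
        plate data, so it stays off unless requested.
    """

    vm: float
    gamma_m: float
    kf: float
    kr: float
    f: float
    kappa: float
    gamma_r: float
    vg: float = 0.0

    def __post_init__(self) -> None:
        for name in ("vm", "gamma_m", "kr", "f", "kappa", "gamma_r"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not self.kf > 0:
            raise InvalidParameterError(f"kf must be > 0 so Kd = kr/kf exists, got {self.kf}")

    @property
    def kd(self) -> float:
        """Dissociation constant Kd = kr/kf (uM)."""
        return self.kr / self.kf


@dataclass(frozen=True)
class CascadeResult:
    """State trajectories of the cascade on the simulation grid."""

    time_min: np.ndarray
    m: np.ndarray = field(repr=False)
    c: np.ndarray = field(repr=False)
    r: np.ndarray = field(repr=False)


def simulate_sensor_cascade(
    sensor: SensorParams,
    biomass,
    time_min,
    dbiomass=None,
    f_series=None,
    initial=(0.0, 0.0, 0.0),
    rtol: float = 1e-8,
) -> CascadeResult:
    """Integrate the three-stage cascade driven by a biomass trace.

    Parameters
    ----------
    sensor : SensorParams
    biomass : array-like
        X(t) sampled on ``time_min``; linearly interpolated between samples.
    time_min : array-like
        Uniform, increasing grid (minutes).
    dbiomass : array-like, optional
        dX/dt on the grid.  When the biomass comes from a parametric growth
        model pass its analytic derivative; otherwise central differences
        (``numpy.gradient``) are used.
    f_series : array-like, optional
        Time-varying free FapR concentration; overrides ``sensor.f``.  Used
        for the stationary-phase arabinose-depletion scenario.
    initial : tuple
        Initial (M, C, R); zeros by default.
    rtol : float
        Relative tolerance of the adaptive (LSODA) integrator; the binding
        stage can be much faster than the others, so a stiff-capable scheme
        with a tight tolerance is used.
    """
    t = np.asarray(time_min, dtype=float)
    x = np.asarray(biomass, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise InvalidParameterError("time grid must contain at least two samples")
    if x.shape != t.shape:
        raise InvalidParameterError("biomass series must be defined on the time grid")
    dx = np.gradient(x, t) if dbiomass is None else np.asarray(dbiomass, dtype=float)
    if dx.shape != t.shape:
        raise InvalidParameterError("dbiomass must be defined on the time grid")
    f_t = None if f_series is None else np.asarray(f_series, dtype=float)
    if f_t is not None and f_t.shape != t.shape:
        raise InvalidParameterError("f_series must be defined on the time grid")

    s = sensor

    def rhs(tt, y):
        m, c, r = y
        xt = np.interp(tt, t, x)
        dxt = np.interp(tt, t, dx)
        ft = s.f if f_t is None else np.interp(tt, t, f_t)
        dm = s.vm * xt - s.vg * dxt - s.gamma_m * m
        dc = s.kf * ft * m - s.kr * c
        dr = s.kappa * c - s.gamma_r * r
        return (dm, dc, dr)

    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        np.asarray(initial, dtype=float),
        method="LSODA",
        t_eval=t,
        rtol=rtol,
        atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(
            "cascade integration failed "
            f"(gamma_m={s.gamma_m}, kf*F={s.kf * s.f}, kr={s.kr}, "
            f"gamma_r={s.gamma_r}): {sol.message}"
        )
    return CascadeResult(time_min=t, m=sol.y[0], c=sol.y[1], r=sol.y[2])
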
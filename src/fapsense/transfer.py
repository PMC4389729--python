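"""Approximate linear filter models of the sensor.

The cascade of first-order stages that maps biomass X(t) to fluorescence R(t)
is summarized by one of three zero-pole transfer functions,

    order 1:  R(s)/X(s) = K (1 - tau_z s) / (1 + tau_p1 s)
    order 2:  R(s)/X(s) = K (1 - tau_z s) / ((1 + tau_p1 s)(1 + tau_p2 s))
    order 3:  R(s)/X(s) = K (1 - tau_z s) / ((1 + tau_p1 s)(1 + tau_p2 s)(1 + tau_p3 s))

with a gain K (fluorescence per OD), a derivative time constant tau_z coupling
the growth rate into the response, and one to three integral time constants
tau_p (minutes) setting the lag of the fluorescence.  All three models have DC
gain K, so K is the steady-state fluorescence/biomass ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lsim

from .cascade import SensorParams
from .errors import InvalidParameterError

__all__ = [
    "TransferModelParams",
    "dc_gain",
    "steady_state_gain",
    "simulate_continuous",
    "step_response",
]


@dataclass(frozen=True)
class TransferModelParams:
    """Zero-pole sensor model of order 1-3.

    Attributes
    ----------
    k : float
        Gain (fluorescence per OD unit).
    tau_z : float
        Derivative time constant (min).  Positive for the physiological case
        (growth drains the metabolite, a right-half-plane zero); identified
        models may carry a small negative value when the true zero is near
        the origin, so the sign is not constrained.
    tau_p : tuple of float
        Integral time constants (min), all > 0.  Stored sorted descending so
        ``tau_p[0]`` is always the slow constant.
    """

    k: float
    tau_z: float
    tau_p: tuple

    def __post_init__(self) -> None:
        taus = tuple(float(t) for t in (
            self.tau_p if np.iterable(self.tau_p) else (self.tau_p,)
        ))
        if not 1 <= len(taus) <= 3:
            raise InvalidParameterError(f"model order must be 1-3, got {len(taus)} poles")
        if any(t <= 0 for t in taus):
            raise InvalidParameterError(f"integral time constants must be > 0, got {taus}")
        if not np.isfinite(self.k) or not np.isfinite(self.tau_z):
            raise InvalidParameterError("k and tau_z must be finite")
        object.__setattr__(self, "tau_p", tuple(sorted(taus, reverse=True)))

    @property
    def order(self) -> int:
        return len(self.tau_p)

    def as_tf(self):
        """(num, den) polynomial coefficients in s, descending powers."""
        num = np.array([-self.k * self.tau_z, self.k]) if self.tau_z != 0 else np.array([self.k])
        den = np.array([1.0])
        for tau in self.tau_p:
            den = np.convolve(den, np.array([tau, 1.0]))
        return num, den


def dc_gain(params: TransferModelParams) -> float:
    """Transfer-function value at s = 0: every (1 + tau s) factor is 1, so K."""
    return params.k


def steady_state_gain(sensor: SensorParams) -> float:
    """Steady-state fluorescence/biomass ratio of the mechanistic cascade.

    Chaining the three stage equilibria under constant biomass X and vg = 0:
    M = vm X / gamma_m, C = F M / Kd, R = kappa C / gamma_r, giving

        R / X = kappa * F * vm / (Kd * gamma_m * gamma_r).
    """
    if sensor.gamma_m == 0 or sensor.gamma_r == 0:
        raise InvalidParameterError(
            "steady-state gain requires gamma_m > 0 and gamma_r > 0 "
            f"(got gamma_m={sensor.gamma_m}, gamma_r={sensor.gamma_r})"
        )
    if sensor.kr == 0:
        raise InvalidParameterError("steady-state gain requires kr > 0 (Kd would be 0)")
    return sensor.kappa * sensor.f * sensor.vm / (sensor.kd * sensor.gamma_m * sensor.gamma_r)


def simulate_continuous(params: TransferModelParams, x, time_min) -> np.ndarray:
    """Response R(t) of the filter to input X(t), zero initial conditions.

    The input is treated as piecewise linear between samples, for which the
    state-space integration is exact.  The map is linear, so superposition
    holds to integration tolerance.
    """
    t = np.asarray(time_min, dtype=float)
    u = np.asarray(x, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise InvalidParameterError("time grid must contain at least two samples")
    if u.shape != t.shape:
        raise InvalidParameterError("input series must be defined on the time grid")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-8, atol=0):
        raise InvalidParameterError("time grid must be uniform")
    _, y, _ = lsim(params.as_tf(), U=u, T=t)
    return y


def step_response(params: TransferModelParams, amplitude: float, time_min) -> np.ndarray:
    """Closed-form response to a step input of height ``amplitude`` at t = 0.

    Partial-fraction solution for distinct poles,

        R(t) = K c [1 - sum_i (tau_i + tau_z) tau_i^(n-2)
                         / prod_{j != i} (tau_i - tau_j) * exp(-t/tau_i)],

    with the repeated-root limit substituted when two poles of an order-2
    model coincide (regression can legitimately return coincident poles).
    """
    t = np.asarray(time_min, dtype=float)
    k, tz = params.k, params.tau_z
    taus = params.tau_p
    c = amplitude
    if params.order == 1:
        (tau,) = taus
        return k * c * (1.0 - (tau + tz) / tau * np.exp(-t / tau))
    if params.order == 2 and np.isclose(taus[0], taus[1], rtol=1e-9):
        tau = taus[0]
        return k * c * (1.0 - np.exp(-t / tau) * (1.0 + t * (tau + tz) / tau**2))
    if len(set(taus)) < len(taus):
        raise InvalidParameterError(
            "repeated poles beyond order 2 have no closed form here; "
            "use simulate_continuous"
        )
    n = params.order
    out = np.full_like(t, 1.0, dtype=float)
    for i, tau_i in enumerate(taus):
        denom = np.prod([tau_i - tau_j for j, tau_j in enumerate(taus) if j != i])
        coeff = (tau_i + tz) * tau_i ** (n - 2) / denom
        out -= coeff * np.exp(-t / tau_i)
    return k * c * out
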
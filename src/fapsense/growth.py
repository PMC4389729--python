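"""Logistic biomass curves.

The culture density X(t) (OD600) is the input signal of every sensor model in
this package.  Plate-reader growth curves are emulated by a logistic law with
an optional lag phase: flat at the inoculum density ``x0`` until ``lag``, then
logistic growth at specific rate ``mu`` toward the carrying capacity ``xmax``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

__all__ = ["GrowthParams", "logistic_growth", "logistic_derivative"]


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of a lagged logistic growth curve.

    Attributes
    ----------
    x0 : float
        Inoculum density (OD units), ``0 < x0 < xmax``.
    xmax : float
        Carrying capacity (OD units).
    mu : float
        Specific growth rate (1/min), ``mu > 0``.
    lag : float
        Lag-phase duration (min), ``lag >= 0``.
    """

    x0: float
    xmax: float
    mu: float
    lag: float = 0.0

    def __post_init__(self) -> None:
        if not self.x0 > 0:
            raise InvalidParameterError(f"x0 must be positive, got {self.x0}")
        if not self.xmax > self.x0:
            raise InvalidParameterError(
                f"xmax must exceed x0, got xmax={self.xmax}, x0={self.x0}"
            )
        if not self.mu > 0:
            raise InvalidParameterError(f"mu must be positive, got {self.mu}")
        if self.lag < 0:
            raise InvalidParameterError(f"lag must be >= 0, got {self.lag}")


def _check_grid(time_min: np.ndarray) -> np.ndarray:
    t = np.asarray(time_min, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise InvalidParameterError("time grid must be a non-empty 1-D array")
    return t


def logistic_growth(params: GrowthParams, time_min) -> np.ndarray:
    """Biomass X(t) on ``time_min``.

    X(t) = x0 for t <= lag, then the logistic
    ``xmax / (1 + (xmax/x0 - 1) * exp(-mu * (t - lag)))``.  The curve is
    non-decreasing and bounded by ``xmax``.
    """
    t = _check_grid(time_min)
    shifted = np.clip(t - params.lag, 0.0, None)
    ratio = params.xmax / params.x0 - 1.0
    return params.xmax / (1.0 + ratio * np.exp(-params.mu * shifted))


def logistic_derivative(params: GrowthParams, time_min) -> np.ndarray:
    """Analytic dX/dt of :func:`logistic_growth` (zero during the lag)."""
    t = _check_grid(time_min)
    x = logistic_growth(params, t)
    dx = params.mu * x * (1.0 - x / params.xmax)
    dx[t < params.lag] = 0.0
    return dx
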
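"""Discrete ARX form of the sensor models via the bilinear (Tustin) transform.

Substituting s = (2/Ts)(z - 1)/(z + 1) into a zero-pole transfer function
yields a difference equation in the sampled signals,

    R[k] = sum_i a_i R[k-i] + sum_j b_j X[k-j],

an ARX (autoregressive with exogenous input) model whose coefficients are
linear in the data — the property the identification procedure exploits.
The map sends s = 0 to z = 1, so the DC gain K is preserved exactly, and it
carries left-half-plane poles to the interior of the unit circle, preserving
stability in both directions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.signal import lfilter

from .errors import InvalidParameterError
from .transfer import TransferModelParams

__all__ = ["DiscreteARX", "simulate_discrete_arx", "bilinear_discretize"]


@dataclass(frozen=True)
class DiscreteARX:
    """Difference-equation coefficients at sampling period ``ts`` (min).

    ``a`` has ``order`` autoregressive coefficients, ``b`` has ``order + 1``
    input coefficients (the bilinear map makes the numerator full order).
    """

    a: tuple
    b: tuple
    ts: float

    def __post_init__(self) -> None:
        a = tuple(float(v) for v in self.a)
        b = tuple(float(v) for v in self.b)
        if len(b) != len(a) + 1:
            raise InvalidParameterError(
                f"need len(b) == len(a) + 1, got {len(a)} AR and {len(b)} input coefficients"
            )
        if not len(a) >= 1:
            raise InvalidParameterError("model order must be at least 1")
        if not self.ts > 0:
            raise InvalidParameterError(f"sampling period must be > 0, got {self.ts}")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def order(self) -> int:
        return len(self.a)

    def ar_polynomial(self) -> np.ndarray:
        """Monic AR polynomial in z, descending powers: z^n - a_1 z^(n-1) - ..."""
        return np.concatenate(([1.0], -np.asarray(self.a)))

    def poles(self) -> np.ndarray:
        return np.roots(self.ar_polynomial())

    @property
    def is_stable(self) -> bool:
        """True iff all AR roots lie strictly inside the unit circle."""
        return bool(np.all(np.abs(self.poles()) < 1.0))

    @property
    def dc_gain(self) -> float:
        """Steady-state gain (sum b)/(1 - sum a); z = 1 corresponds to s = 0.

        Both sums cancel almost completely when the poles are slow relative
        to the sampling period, so they are accumulated with exactly-rounded
        summation.
        """
        denom = math.fsum((1.0, *(-ai for ai in self.a)))
        if denom == 0:
            raise InvalidParameterError("model has a pole at z = 1; DC gain undefined")
        return math.fsum(self.b) / denom


def simulate_discrete_arx(model: DiscreteARX, x) -> np.ndarray:
    """Iterate the difference equation over input ``x``, zero initial state.

    An unstable model (pole on or outside the unit circle) is simulated
    anyway, with a warning — diverging output is itself diagnostic.
    """
    u = np.asarray(x, dtype=float)
    if u.ndim != 1 or u.size < model.order:
        raise InvalidParameterError("input series must be 1-D with length >= model order")
    if not model.is_stable:
        warnings.warn("simulating an unstable ARX model (pole magnitude >= 1)", stacklevel=2)
    return lfilter(np.asarray(model.b), model.ar_polynomial(), u)


def _bilinear_poly(coeffs_asc, n: int, ts: float) -> np.ndarray:
    """Expand P(s) under s = (2/Ts)(z-1)/(z+1), cleared by (z+1)^n.

    For P(s) = sum_k p_k s^k the result is
    sum_k p_k (2/Ts)^k (z-1)^k (z+1)^(n-k), returned in ascending powers of z.
    """
    out = np.zeros(n + 1)
    for k, p in enumerate(coeffs_asc):
        if p == 0:
            continue
        term = npoly.polymul(
            npoly.polypow([-1.0, 1.0], k), npoly.polypow([1.0, 1.0], n - k)
        )
        out[: len(term)] += p * (2.0 / ts) ** k * term
    return out


def bilinear_discretize(params: TransferModelParams, ts: float) -> DiscreteARX:
    """Bilinear-discretize a zero-pole model into ARX coefficients.

    The sampling period should resolve the fastest pole (``ts < 2*min(tau_p)``);
    a coarser grid still produces a valid model but the frequency warping of
    the transform grows, so a warning is emitted.
    """
    if not ts > 0:
        raise InvalidParameterError(f"sampling period must be > 0, got {ts}")
    if ts >= 2.0 * min(params.tau_p):
        warnings.warn(
            f"ts={ts} does not resolve the fastest time constant "
            f"{min(params.tau_p)}; bilinear warping may be severe",
            stacklevel=2,
        )
    n = params.order
    num_asc = [params.k, -params.k * params.tau_z]
    den_asc = [1.0]
    for tau in params.tau_p:
        den_asc = list(npoly.polymul(den_asc, [1.0, tau]))
    num_z = _bilinear_poly(num_asc, n, ts)  # ascending powers of z
    den_z = _bilinear_poly(den_asc, n, ts)
    lead = den_z[n]
    a = tuple(-den_z[n - i] / lead for i in range(1, n + 1))
    b = tuple(num_z[n - j] / lead for j in range(0, n + 1))
    return DiscreteARX(a=a, b=b, ts=ts)
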
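"""Identification of the sensor model from OD/fluorescence series.

The pipeline mirrors a classical discrete-time identification:

1. :func:`fit_discrete` — ordinary least squares of the fluorescence sample
   R[k] on its own lags and on the biomass lags (an ARX regression, no
   intercept);
2. :func:`continuous_from_discrete` — map the fitted difference equation back
   to continuous gain and time constants by inverting the bilinear transform
   on the roots, s_i = (2/Ts)(z_i - 1)/(z_i + 1), with tau_i = -1/s_i;
3. :func:`identify` — both steps plus diagnostics, producing a
   :class:`FitResult` per well;
4. :func:`compare_orders` — the same fit at orders 1-3 on a common sample so
   residual variances are directly comparable (the model classes are nested).

Estimates with complex or unstable poles are never coerced to time constants;
validity flags gate what downstream analyses may use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .arx import DiscreteARX
from .errors import IdentifiabilityError, InvalidParameterError, MappingError
from .transfer import TransferModelParams

__all__ = [
    "FitDiagnostics",
    "Validity",
    "FitResult",
    "fit_discrete",
    "continuous_from_discrete",
    "identify",
    "compare_orders",
]

# relative imaginary-part threshold below which a root counts as real
_REAL_TOL = 1e-7
# numerator roots this close to z = -1 are bilinear clearing artifacts
_NYQUIST_TOL = 1e-6


@dataclass(frozen=True)
class FitDiagnostics:
    residual_variance: float
    r_squared: float
    n_samples: int


@dataclass(frozen=True)
class Validity:
    """Flags explaining whether continuous parameters could be extracted."""

    stable: bool
    real_poles: bool
    positive_gain: bool
    n_unmodeled_zeros: int = 0

    @property
    def ok(self) -> bool:
        return self.stable and self.real_poles


@dataclass(frozen=True)
class FitResult:
    """Identified model for one well/condition.

    ``continuous`` is present only when the discrete poles are real and
    stable; otherwise ``validity`` explains the absence.
    """

    discrete: DiscreteARX
    continuous: Optional[TransferModelParams]
    validity: Validity
    residual_variance: float
    r_squared: float
    n_samples: int


def _lag_matrix(r: np.ndarray, x: np.ndarray, order: int, burn_in: int):
    n = r.size
    rows = np.arange(burn_in, n)
    cols = [r[rows - i] for i in range(1, order + 1)]
    cols += [x[rows - j] for j in range(0, order + 1)]
    return np.column_stack(cols), r[rows]


def fit_discrete(r, x, order: int, ts: float, burn_in: int | None = None):
    """OLS fit of the order-``order`` ARX model; returns (model, diagnostics).

    The first ``burn_in`` samples (default: ``order``, the incomplete lag
    rows) are dropped; there is no intercept.  A constant input carries no
    dynamic information and raises :class:`IdentifiabilityError`, as does a
    rank-deficient regression that cannot reproduce the output.  A merely
    overparameterized fit (e.g. a higher order than the data, where the
    perfect fit is non-unique) returns the minimum-norm solution, and an
    all-zero output is exactly fit by zero coefficients.
    """
    r = np.asarray(r, dtype=float)
    x = np.asarray(x, dtype=float)
    if r.shape != x.shape or r.ndim != 1:
        raise InvalidParameterError("series must be aligned 1-D arrays")
    if order not in (1, 2, 3):
        raise InvalidParameterError(f"order must be 1, 2 or 3, got {order}")
    if not ts > 0:
        raise InvalidParameterError(f"ts must be > 0, got {ts}")
    if r.size <= 3 * (order + 1):
        raise InvalidParameterError(
            f"need more than {3 * (order + 1)} samples for order {order}, got {r.size}"
        )
    burn = order if burn_in is None else int(burn_in)
    if burn < order:
        raise InvalidParameterError("burn_in must be >= order")

    if np.allclose(r, 0.0):
        zero = DiscreteARX(a=(0.0,) * order, b=(0.0,) * (order + 1), ts=ts)
        return zero, FitDiagnostics(0.0, 1.0, int(r.size - burn))
    if np.allclose(x, x[0]):
        raise IdentifiabilityError("constant input carries no dynamic information")

    design, target = _lag_matrix(r, x, order, burn)
    n_params = 2 * order + 1
    coeffs, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    fitted = design @ coeffs
    rss = float(np.sum((target - fitted) ** 2))
    tss = float(np.sum((target - target.mean()) ** 2))
    if rank < n_params and tss > 0 and rss > 1e-8 * tss:
        raise IdentifiabilityError(
            f"regressor matrix rank {rank} < {n_params} parameters and the "
            "deficient fit cannot reproduce the output"
        )
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else 0.0)
    model = DiscreteARX(a=tuple(coeffs[:order]), b=tuple(coeffs[order:]), ts=ts)
    return model, FitDiagnostics(rss / target.size, r2, int(target.size))


def _is_real(roots: np.ndarray) -> np.ndarray:
    return np.abs(roots.imag) <= _REAL_TOL * (1.0 + np.abs(roots.real))


def continuous_from_discrete(model: DiscreteARX):
    """Map ARX coefficients back to (K, tau_z, tau_p); returns (params, validity).

    Poles: roots z_i of the AR polynomial map to s_i = (2/Ts)(z_i - 1)/(z_i + 1)
    and tau_i = -1/s_i, reported sorted descending (slow constant first).
    Gain: the DC gain, exact under the bilinear map.  Zero: the numerator of
    the continuous model is first order, so of the ``order`` discrete
    numerator roots exactly one is the mapped zero and the rest sit at z = -1
    (clearing factors); the genuine root is taken as the real root farthest
    from z = -1, and tau_z = 1/s(zero).  Surplus non-artifact numerator roots
    are counted as unmodeled zeros.  ``params`` is None whenever the poles
    are complex or unstable.
    """
    z_poles = model.poles()
    if np.any(np.abs(z_poles + 1.0) < 1e-9):
        raise MappingError("discrete pole at z = -1 (Nyquist); bilinear inverse is singular")
    s_poles = (2.0 / model.ts) * (z_poles - 1.0) / (z_poles + 1.0)
    real_poles = bool(np.all(_is_real(s_poles)))
    stable = bool(np.all(s_poles.real < 0))

    try:
        gain = model.dc_gain
    except InvalidParameterError:
        gain = np.nan
        stable = False

    # numerator root analysis
    b = np.asarray(model.b)
    tau_z = 0.0
    n_unmodeled = 0
    scale = np.max(np.abs(b)) if np.any(b) else 0.0
    if scale > 0:
        bb = np.trim_zeros(np.where(np.abs(b) > 1e-12 * scale, b, 0.0), "f")
        z_zeros = np.roots(bb) if bb.size > 1 else np.array([])
        genuine = [
            z for z in z_zeros
            if abs(z + 1.0) > _NYQUIST_TOL and abs(z.imag) <= _REAL_TOL * (1.0 + abs(z.real))
        ]
        n_complex = int(np.sum(~_is_real(z_zeros) & (np.abs(z_zeros + 1.0) > _NYQUIST_TOL)))
        if genuine:
            z0 = max(genuine, key=lambda z: abs(z + 1.0)).real
            s0 = (2.0 / model.ts) * (z0 - 1.0) / (z0 + 1.0)
            if s0 != 0:
                tau_z = 1.0 / s0
            n_unmodeled = len(genuine) - 1 + n_complex
        else:
            n_unmodeled = n_complex

    validity = Validity(
        stable=stable,
        real_poles=real_poles,
        positive_gain=bool(np.isfinite(gain) and gain > 0),
        n_unmodeled_zeros=n_unmodeled,
    )
    if not (stable and real_poles):
        return None, validity
    taus = tuple(sorted((-1.0 / s.real for s in s_poles), reverse=True))
    params = TransferModelParams(k=float(gain), tau_z=float(tau_z), tau_p=taus)
    return params, validity


def identify(r, x, order: int, ts: float, burn_in: int | None = None) -> FitResult:
    """Full pipeline: lagged OLS fit, then discrete-to-continuous conversion."""
    model, diag = fit_discrete(r, x, order, ts, burn_in=burn_in)
    params, validity = continuous_from_discrete(model)
    return FitResult(
        discrete=model,
        continuous=params,
        validity=validity,
        residual_variance=diag.residual_variance,
        r_squared=diag.r_squared,
        n_samples=diag.n_samples,
    )


def compare_orders(r, x, ts: float, orders=(1, 2, 3)):
    """Fit every order on a common sample; returns ({order: FitResult}, {order: error}).

    All orders drop the same ``max(orders)`` initial samples, so the model
    classes are nested on identical rows and the in-sample residual variance
    is non-increasing with order.  Per-order failures (e.g. a Nyquist pole)
    are recorded, not raised.
    """
    burn = max(orders)
    results: dict[int, FitResult] = {}
    errors: dict[int, str] = {}
    for order in orders:
        try:
            results[order] = identify(r, x, order, ts, burn_in=burn)
        except (IdentifiabilityError, MappingError, InvalidParameterError) as exc:
            errors[order] = f"{type(exc).__name__}: {exc}"
    return results, errors
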
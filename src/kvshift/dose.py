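"""Concentration dependence of G(V) shifts.

The shift ΔV produced by a compound at bath concentration ``c`` follows a
rectangular hyperbola with Hill coefficient 1:

    ΔV(c) = ΔV_MAX / (1 + EC50 / c)

where ΔV_MAX is the shift at saturating concentration (efficacy) and EC50 the
concentration of half-maximal response (apparent affinity). Fitting is by
unweighted nonlinear least squares in linear concentration space; standard
errors come from the Jacobian-based covariance at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "DoseResponseFit",
    "hyperbolic_shift",
    "fit_dose_response",
    "predict_shift",
    "efficacy_increase_percent",
]


def hyperbolic_shift(c: np.ndarray, ec50: float, delta_v_max: float) -> np.ndarray:
    """ΔV(c) = ΔV_MAX / (1 + EC50/c) for concentrations c > 0 (µM)."""
    c = np.asarray(c, dtype=float)
    return delta_v_max / (1.0 + ec50 / c)


@dataclass
class DoseResponseFit:
    """(EC50 in µM, ΔV_MAX in mV) with fit diagnostics."""

    EC50: float
    delta_V_MAX: float
    standard_errors: tuple[float, float] = (np.nan, np.nan)
    residual_sum_of_squares: float = np.nan
    converged: bool = True

    def predict(self, c):
        return predict_shift(self, c)


def fit_dose_response(
    concentrations: np.ndarray,
    shifts: np.ndarray,
    weights: np.ndarray | None = None,
) -> DoseResponseFit:
    """Least-squares fit of ΔV(c) = ΔV_MAX/(1+EC50/c) to (c, shift) points.

    Requires at least three distinct concentrations. All-equal shifts leave
    EC50 unidentifiable and are flagged (``converged=False``); solver
    non-convergence is flagged the same way.
    """
    c = np.asarray(concentrations, dtype=float)
    dv = np.asarray(shifts, dtype=float)
    if c.size != dv.size or c.size == 0:
        raise ValueError("concentrations and shifts must be equal-length, non-empty")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    if np.unique(c).size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if np.allclose(dv, dv[0]):
        return DoseResponseFit(
            EC50=np.nan, delta_V_MAX=float(dv[0]), converged=False,
            residual_sum_of_squares=0.0,
        )
    # Initialise ΔV_MAX slightly beyond the extreme observed shift and EC50 at
    # the concentration whose shift lies nearest half of that extreme.
    extreme = dv[np.argmax(np.abs(dv))]
    dv_max0 = 1.2 * extreme
    ec50_0 = float(c[np.argmin(np.abs(dv - 0.5 * extreme))])
    sigma = None if weights is None else 1.0 / np.sqrt(np.asarray(weights, float))
    try:
        popt, pcov = optimize.curve_fit(
            hyperbolic_shift, c, dv,
            p0=[ec50_0, dv_max0], sigma=sigma,
            bounds=([1e-9, -np.inf], [np.inf, np.inf]), maxfev=10000,
        )
        converged = True
    except RuntimeError:
        popt = np.array([ec50_0, dv_max0])
        pcov = np.full((2, 2), np.nan)
        converged = False
    resid = dv - hyperbolic_shift(c, *popt)
    return DoseResponseFit(
        EC50=float(popt[0]),
        delta_V_MAX=float(popt[1]),
        standard_errors=tuple(np.sqrt(np.diag(pcov)).tolist()),
        residual_sum_of_squares=float(resid @ resid),
        converged=converged,
    )


def predict_shift(fit: DoseResponseFit, c) -> float | np.ndarray:
    """Model shift at concentration ``c`` (µM): ΔV_MAX/(1+EC50/c)."""
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr <= 0):
        raise ValueError("concentration must be positive")
    out = hyperbolic_shift(c_arr, fit.EC50, fit.delta_V_MAX)
    return float(out) if np.isscalar(c) or c_arr.ndim == 0 else out


def efficacy_increase_percent(
    reference: DoseResponseFit | float, variant: DoseResponseFit | float
) -> float:
    """Percent increase in maximal-shift magnitude of ``variant`` over ``reference``.

    Accepts fits or raw ΔV_MAX values; e.g. −36.1 → −56.5 mV is a 57% increase
    (to two significant figures).
    """
    ref = reference.delta_V_MAX if isinstance(reference, DoseResponseFit) else reference
    var = variant.delta_V_MAX if isinstance(variant, DoseResponseFit) else variant
    if ref == 0:
        raise ValueError("reference maximal shift is zero")
    return 100.0 * (abs(var) - abs(ref)) / abs(ref)
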
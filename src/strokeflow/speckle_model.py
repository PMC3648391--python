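"""Time-integrated speckle contrast model.

For dynamic laser speckle recorded with a finite camera exposure ``T``, the
squared speckle contrast relates to the speckle decorrelation time ``tau_c``
through the Lorentzian (negative-exponential field correlation) model

    k^2 = beta * (tau_c / 2T) * (1 - exp(-2T / tau_c))

where ``beta`` in (0, 1] is the coherence factor of the optical system.
``1/k^2`` is used as a relative flow index: red-blood-cell velocity is taken
proportional to ``1/tau_c``, so faster flow blurs the speckle during the
exposure and drives the contrast down.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

__all__ = ["contrast_model", "flow_index_model", "tau_c_from_contrast"]


def _validate(exposure_time_s: float, beta: float) -> None:
    if not np.all(np.isfinite(exposure_time_s)) or exposure_time_s <= 0:
        raise ValueError(f"exposure_time_s must be finite and > 0, got {exposure_time_s}")
    if not (0.0 < beta <= 1.0):
        raise ValueError(f"beta must be in (0, 1], got {beta}")


def contrast_model(tau_c, exposure_time_s: float, beta: float = 1.0):
    """Expected squared speckle contrast k^2 for decorrelation time ``tau_c``.

    Parameters
    ----------
    tau_c : float or ndarray
        Speckle decorrelation time(s) in seconds; all strictly positive.
    exposure_time_s : float
        Camera exposure T in seconds.
    beta : float
        Coherence factor in (0, 1].

    Returns
    -------
    float or ndarray
        k^2 = beta * (tau_c/2T) * (1 - exp(-2T/tau_c)).  Strictly increasing
        in ``tau_c`` at fixed T, with limits 0 (tau_c -> 0) and beta
        (tau_c -> inf, static scatterers).
    """
    _validate(exposure_time_s, beta)
    tau = np.asarray(tau_c, dtype=float)
    if not np.all(np.isfinite(tau)) or np.any(tau <= 0):
        raise ValueError("tau_c must be finite and strictly positive")
    x = tau / (2.0 * exposure_time_s)
    # -expm1(-1/x) keeps precision when tau_c >> T
    k2 = beta * x * (-np.expm1(-1.0 / x))
    if np.isscalar(tau_c):
        return float(k2)
    return k2


def flow_index_model(tau_c, exposure_time_s: float, beta: float = 1.0):
    """Model flow index 1/k^2 for decorrelation time ``tau_c``."""
    return 1.0 / contrast_model(tau_c, exposure_time_s, beta)


def tau_c_from_contrast(k2: float, exposure_time_s: float, beta: float = 1.0) -> float:
    """Invert the contrast model: the tau_c for which k^2 equals ``k2``.

    Uses bracketed root finding; ``k2`` must lie strictly inside (0, beta).
    """
    _validate(exposure_time_s, beta)
    if not (0.0 < k2 < beta):
        raise ValueError(f"k2 must be in (0, beta={beta}), got {k2}")

    def f(log_tau: float) -> float:
        return contrast_model(np.exp(log_tau), exposure_time_s, beta) - k2

    lo, hi = np.log(exposure_time_s) - 30.0, np.log(exposure_time_s) + 30.0
    return float(np.exp(brentq(f, lo, hi, xtol=1e-14, rtol=1e-14)))
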
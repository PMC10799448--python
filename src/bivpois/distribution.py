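"""Bivariate Poisson distribution via trivariate reduction.

The joint law of ``(Y1, Y2) = (A + C, B + C)`` with independent
``A ~ Poisson(theta1)``, ``B ~ Poisson(theta2)``, ``C ~ Poisson(theta3)``
has probability mass

.. math::

    f(y_1, y_2) = e^{-\\theta_1-\\theta_2-\\theta_3}
        \\frac{\\theta_1^{y_1}}{y_1!} \\frac{\\theta_2^{y_2}}{y_2!}
        \\sum_{k=0}^{\\min(y_1, y_2)} k!
        \\left(\\frac{\\theta_3}{\\theta_1\\theta_2}\\right)^k
        \\binom{y_1}{k} \\binom{y_2}{k},

with ``cov(Y1, Y2) = theta3 >= 0``.  At ``theta3 = 0`` the distribution
factorises into two independent Poisson margins.  Everything here is
computed in log space (log-gamma factorials, log-sum-exp over the shared
index ``k``) so that large counts and small rates do not overflow.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = ["bivpois_logpmf", "bivpois_pmf"]


def _validate_counts(y1: np.ndarray, y2: np.ndarray) -> None:
    for name, y in (("y1", y1), ("y2", y2)):
        if not np.all(np.isfinite(y)):
            raise ValueError(f"{name} must be finite")
        if np.any(y < 0) or np.any(y != np.floor(y)):
            raise ValueError(f"{name} must contain non-negative integers")


def _logpmf_one(y1: int, y2: int, t1: float, t2: float, t3: float) -> float:
    # log of the k-sum: sum_k theta1^-k theta2^-k theta3^k / (k!(y1-k)!(y2-k)!)
    m = min(y1, y2)
    if t3 == 0.0:
        # only k = 0 survives (0^0 = 1)
        log_sum = -gammaln(y1 + 1) - gammaln(y2 + 1)
    else:
        k = np.arange(m + 1)
        terms = (
            k * (np.log(t3) - np.log(t1) - np.log(t2))
            - gammaln(k + 1)
            - gammaln(y1 - k + 1)
            - gammaln(y2 - k + 1)
        )
        log_sum = logsumexp(terms)
    return y1 * np.log(t1) + y2 * np.log(t2) - t1 - t2 - t3 + log_sum


def bivpois_logpmf(y1, y2, theta1, theta2, theta3=0.0):
    """Log pmf of the bivariate Poisson distribution.

    Parameters
    ----------
    y1, y2 : int or array-like of int
        Non-negative paired counts.
    theta1, theta2 : float or array-like
        Positive marginal rates (on the same broadcast shape as the counts).
    theta3 : float, default 0
        Non-negative common-shock (covariance) rate.

    Returns
    -------
    float or ndarray
        ``log f(y1, y2)``; exponentiating gives a probability in (0, 1].
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    _validate_counts(y1, y2)
    t1 = np.asarray(theta1, dtype=float)
    t2 = np.asarray(theta2, dtype=float)
    if np.any(t1 <= 0) or np.any(t2 <= 0):
        raise ValueError("theta1 and theta2 must be strictly positive")
    t3 = float(theta3)
    if t3 < 0:
        raise ValueError(
            "theta3 must be >= 0: the bivariate Poisson pmf is a valid "
            "probability mass function only for non-negative covariance rates"
        )
    y1b, y2b, t1b, t2b = np.broadcast_arrays(y1, y2, t1, t2)
    if y1b.ndim == 0:
        return float(_logpmf_one(int(y1b), int(y2b), float(t1b), float(t2b), t3))
    out = np.empty(y1b.shape, dtype=float)
    it = np.nditer(y1b, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        out[idx] = _logpmf_one(
            int(y1b[idx]), int(y2b[idx]), float(t1b[idx]), float(t2b[idx]), t3
        )
    return out


def bivpois_pmf(y1, y2, theta1, theta2, theta3=0.0):
    """Pmf of the bivariate Poisson distribution (``exp`` of the log pmf)."""
    return np.exp(bivpois_logpmf(y1, y2, theta1, theta2, theta3))
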
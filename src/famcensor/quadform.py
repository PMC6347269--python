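"""Tail probabilities of positively weighted sums of chi-square(1) variables.

``P(sum_m lambda_m chi2_1 > q)`` is computed by numerical inversion of the
characteristic function (Imhof's integral, the same quantity Davies'
algorithm evaluates)::

    P(Q > q) = 1/2 + (1/pi) * int_0^inf sin(theta(u)) / (u rho(u)) du
    theta(u) = 1/2 sum_m arctan(lambda_m u) - q u / 2
    rho(u)   = prod_m (1 + lambda_m^2 u^2)^(1/4)

integrated with adaptive quadrature.  If the integral misbehaves (non-finite
or outside [0, 1] beyond tolerance) a Kuonen-type saddlepoint approximation
of the Lugannani-Rice form is used instead, with a warning.
"""
from __future__ import annotations

import logging

import numpy as np
from scipy import integrate
from scipy.optimize import brentq
from scipy.stats import norm

logger = logging.getLogger(__name__)


def _imhof_tail(q: float, lam: np.ndarray, atol: float) -> float:
    def phase(u):
        return 0.5 * np.sum(np.arctan(lam * u))

    def amp(u):
        log_rho = 0.25 * np.sum(np.log1p((lam * u) ** 2))
        return 1.0 / (u * np.exp(log_rho))

    def integrand(u):
        return np.sin(phase(u) - 0.5 * q * u) * amp(u)

    # integrand -> (sum lam - q)/2 as u -> 0; envelope decays like
    # u^(-1-k/2).  Beyond a scale-aware breakpoint the oscillation has the
    # fixed asymptotic frequency q/2, so the tail is evaluated with the
    # Fourier-weighted infinite-range rule (QAWF):
    #   sin(phi(u) - qu/2) = sin(phi)cos(qu/2) - cos(phi)sin(qu/2)
    scale = max(np.max(lam), 1e-300)
    cut = 16.0 / scale
    val1, _ = integrate.quad(
        integrand, 0.0, cut, epsabs=atol / 20.0, epsrel=1e-13, limit=500
    )
    omega = 0.5 * q
    t_cos, _ = integrate.quad(
        lambda u: np.sin(phase(u)) * amp(u),
        cut, np.inf, weight="cos", wvar=omega, epsabs=atol / 20.0, limit=500,
    )
    t_sin, _ = integrate.quad(
        lambda u: np.cos(phase(u)) * amp(u),
        cut, np.inf, weight="sin", wvar=omega, epsabs=atol / 20.0, limit=500,
    )
    return 0.5 + (val1 + t_cos - t_sin) / np.pi


def saddlepoint_tail(q: float, lam: np.ndarray) -> float:
    """Lugannani-Rice saddlepoint tail for ``sum lambda_m chi2_1``."""
    mu = lam.sum()
    if abs(q - mu) < 1e-10 * max(mu, 1.0):
        # zeta_hat = 0: fall back to the normal-approximation midpoint limit
        return 0.5 - np.sum(lam**3) / (3 * np.sqrt(2 * np.pi) * np.sum(lam**2) ** 1.5)
    upper = 1.0 / (2.0 * lam.max())

    def kprime_minus_q(z):
        return np.sum(lam / (1.0 - 2.0 * z * lam)) - q

    if q > mu:
        zhat = brentq(kprime_minus_q, 0.0, upper * (1 - 1e-12), xtol=1e-14)
    else:
        lo = -1.0
        while kprime_minus_q(lo) > 0:
            lo *= 2.0
        zhat = brentq(kprime_minus_q, lo, 0.0, xtol=1e-14)
    k = -0.5 * np.sum(np.log1p(-2.0 * zhat * lam))
    kpp = 2.0 * np.sum(lam**2 / (1.0 - 2.0 * zhat * lam) ** 2)
    w = np.sign(zhat) * np.sqrt(max(2.0 * (zhat * q - k), 0.0))
    v = zhat * np.sqrt(kpp)
    if w == 0.0:
        return 0.5
    return float(norm.sf(w + np.log(v / w) / w))


def davies_pvalue(q: float, lambdas, atol: float = 1e-9) -> float:
    """Upper-tail probability ``P(sum lambda_m chi2_1 > q)``.

    ``lambdas`` must be nonnegative and not all zero; ``q`` is the observed
    quadratic-form value.  Accuracy target ``atol`` (absolute).
    """
    lam = np.asarray(lambdas, float).ravel()
    if lam.size == 0:
        raise ValueError("empty eigenvalue list")
    if np.any(lam < 0):
        raise ValueError("negative eigenvalue passed to davies_pvalue")
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("all eigenvalues are zero")
    if q <= 0:
        return 1.0
    try:
        with np.errstate(all="ignore"):
            p = _imhof_tail(float(q), lam, atol)
    except Exception:
        p = np.nan
    if not np.isfinite(p) or p < -1e-6 or p > 1 + 1e-6:
        logger.warning(
            "characteristic-function inversion failed (p=%r); "
            "falling back to saddlepoint approximation",
            p,
        )
        p = saddlepoint_tail(float(q), lam)
    return float(min(max(p, 0.0), 1.0))
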
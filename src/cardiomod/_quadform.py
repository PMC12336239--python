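"""Tail probabilities for quadratic forms in standard normal variables.

The null distribution of a variance-component score statistic is a linear
combination of independent 1-df chi-square variables, ``sum_j lambda_j z_j^2``
with possibly mixed-sign coefficients.  The primary evaluator is Imhof's exact
numerical inversion of the characteristic function; a three-moment chi-square
approximation (Liu et al.) serves as a fallback when the integration fails to
converge.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import integrate, special, stats

__all__ = ["imhof_tail", "liu_tail", "ruben_tail", "quadform_tail",
           "quadform_quantile"]

# coefficients smaller than this (relative to the largest) carry no mass
_EIGEN_RTOL = 1e-12


def _clean(lmbda: np.ndarray) -> np.ndarray:
    lmbda = np.asarray(lmbda, dtype=float).ravel()
    if lmbda.size == 0:
        raise ValueError("no eigenvalues supplied")
    top = np.max(np.abs(lmbda))
    if top == 0.0:
        return np.zeros(0)
    return lmbda[np.abs(lmbda) > _EIGEN_RTOL * top]


def imhof_tail(lmbda, q: float) -> float:
    """P(sum_j lmbda_j * chi2_1 > q) by Imhof (1961) numerical integration."""
    lam = _clean(lmbda)
    if lam.size == 0:
        return 1.0 if q <= 0 else 0.0

    def integrand(u: float) -> float:
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        log_rho = 0.25 * np.sum(np.log1p((lam * u) ** 2))
        return float(np.sin(theta) * np.exp(-log_rho) / u)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, err = integrate.quad(integrand, 0.0, np.inf, limit=2000)
    if not np.isfinite(val) or err > 1e-4:
        raise ArithmeticError("Imhof integration did not converge")
    return float(np.clip(0.5 + val / np.pi, 0.0, 1.0))


def liu_tail(lmbda, q: float) -> float:
    """Three-moment chi-square approximation to P(sum lmbda_j chi2_1 > q)."""
    lam = _clean(lmbda)
    if lam.size == 0:
        return 1.0 if q <= 0 else 0.0
    c1 = np.sum(lam)
    c2 = np.sum(lam**2)
    c3 = np.sum(lam**3)
    c4 = np.sum(lam**4)
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
    mu_x = df + delta
    sigma_x = np.sqrt(2.0 * (df + 2 * delta))
    t_star = (q - c1) / np.sqrt(2.0 * c2)
    x = t_star * sigma_x + mu_x
    if x <= 0:
        return 1.0
    return float(np.clip(1.0 - special.chndtr(x, df, delta), 0.0, 1.0))


def ruben_tail(lmbda, q: float, tol: float = 1e-10, max_terms: int = 5000
               ) -> float:
    """Exact tail for a positive-coefficient mixture by Ruben's series.

    Expands the distribution as a mixture of central chi-squares,
    ``P(Q <= q) = sum_k a_k F_{K+2k}(q / beta)``, with nonnegative weights
    summing to one, so the truncation error is bounded by the remaining
    mixture mass.
    """
    lam = _clean(lmbda)
    if lam.size == 0:
        return 1.0 if q <= 0 else 0.0
    if np.any(lam <= 0):
        raise ValueError("Ruben series requires strictly positive coefficients")
    if q <= 0:
        return 1.0
    K = lam.size
    beta = 0.90625 * float(lam.min())
    ratios = 1.0 - beta / lam  # in [0, 1)
    a = np.empty(max_terms)
    a[0] = float(np.exp(0.5 * np.sum(np.log(beta / lam))))
    g_cache = np.empty(max_terms)
    cdf = a[0] * float(special.chdtr(K, q / beta))
    mass = a[0]
    for k in range(1, max_terms):
        g_cache[k] = float(np.sum(ratios**k))
        a[k] = np.dot(g_cache[1:k + 1], a[k - 1::-1][:k]) / (2.0 * k)
        cdf += a[k] * float(special.chdtr(K + 2 * k, q / beta))
        mass += a[k]
        if 1.0 - mass < tol:
            return float(np.clip(1.0 - cdf, 0.0, 1.0))
    raise ArithmeticError("Ruben series did not converge")


def _tail_one(lam: float, q: float) -> float:
    """Exact tail of a single scaled 1-df chi-square (either sign)."""
    if lam > 0:
        return float(stats.chi2.sf(q / lam, 1)) if q > 0 else 1.0
    return float(stats.chi2.cdf(q / lam, 1)) if q < 0 else 0.0


def _tail_two(lam: np.ndarray, q: float) -> float:
    """Tail for two coefficients by conditioning on one chi-square.

    Imhof's oscillatory integrand decays too slowly for one or two
    coefficients, so small cases use smooth 1-D integration instead.
    """
    a, b = float(lam[0]), float(lam[1])

    def integrand(x: float) -> float:
        return _tail_one(a, q - b * x) * stats.chi2.pdf(x, 1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(integrand, 0.0, np.inf, limit=500)
    return float(np.clip(val, 0.0, 1.0))


def quadform_tail(lmbda, q: float) -> float:
    """Tail probability, routed by spectrum shape.

    One or two coefficients use exact/smooth forms; one-signed spectra use
    Ruben's exact series (fast for the small kernels of region tests); mixed
    signs - which arise only in the ratio-statistic path, where the spectrum
    is large and Imhof's integrand decays quickly - use Imhof integration.
    Liu's moment approximation is the fallback throughout.
    """
    lam = _clean(lmbda)
    if lam.size == 0:
        return 1.0 if q <= 0 else 0.0
    if lam.size == 1:
        return _tail_one(float(lam[0]), q)
    if lam.size == 2:
        return _tail_two(lam, q)
    try:
        if np.all(lam > 0):
            return ruben_tail(lam, q)
        if np.all(lam < 0):
            return 1.0 - ruben_tail(-lam, -q)
        return imhof_tail(lam, q)
    except ArithmeticError:
        return liu_tail(lam, q)


def quadform_quantile(lmbda, tail: float) -> float:
    """Approximate q with P(sum lmbda_j chi2_1 > q) = tail (lmbda >= 0).

    Inverts the Liu three-moment approximation in closed form; this is the
    standard choice for the per-rho quantiles inside the optimal-test
    correction, where speed matters and the approximation error is second
    order.
    """
    lam = _clean(lmbda)
    if lam.size == 0 or tail >= 1.0:
        return 0.0
    if np.any(lam < 0):
        raise ValueError("quantile inversion requires nonnegative coefficients")
    if lam.size == 1:
        return float(lam[0] * stats.chi2.isf(tail, 1))
    c1 = np.sum(lam)
    c2 = np.sum(lam**2)
    c3 = np.sum(lam**3)
    c4 = np.sum(lam**4)
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
    mu_x = df + delta
    sigma_x = np.sqrt(2.0 * (df + 2 * delta))
    x = stats.ncx2.isf(tail, df, delta) if delta > 0 else stats.chi2.isf(tail, df)
    return float(c1 + (x - mu_x) / sigma_x * np.sqrt(2.0 * c2))
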
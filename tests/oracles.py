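"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: direct formula
evaluation, exact rational hypergeometric enumeration, and adaptive
numerical integration over the posterior.
"""
from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy import integrate, optimize


def ror_oracle(a, b, c, d):
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ror = a * d / (b * c)
    half = 1.959963984540054 * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * math.exp(-half), ror * math.exp(half)


def prr_chi2_oracle(a, b, c, d):
    n = a + b + c + d
    prr = math.inf if c == 0 else (a / (a + b)) / (c / (c + d))
    diff = abs(a * d - b * c)
    chi2 = 0.0 if diff <= n / 2 else (
        n * (diff - n / 2) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    )
    return prr, chi2


def ic_oracle(a, b, c, d):
    n = a + b + c + d
    e = (a + b) * (a + c) / n
    ic = math.log2((a + 0.5) / (e + 0.5))
    return ic, ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5


def fisher_exact_oracle(a, b, c, d):
    """Two-sided Fisher exact p by full hypergeometric enumeration in exact
    rational arithmetic (method of small p-values)."""
    n = a + b + c + d
    r, cc = a + b, a + c
    if n == 0 or r in (0, n) or cc in (0, n):
        return 1.0
    denom = math.comb(n, cc)

    def pmf(k):
        return Fraction(math.comb(r, k) * math.comb(n - r, cc - k), denom)

    p0 = pmf(a)
    total = sum(
        pmf(k)
        for k in range(max(0, r + cc - n), min(r, cc) + 1)
        if pmf(k) <= p0
    )
    return float(min(total, Fraction(1)))


def _mixture_pdf(lam, w, a1, b1, a2, b2):
    from scipy.stats import gamma

    return w * gamma.pdf(lam, a1, scale=1 / b1) + (1 - w) * gamma.pdf(
        lam, a2, scale=1 / b2
    )


def marginal_quad_oracle(o, e, w, a1, b1, a2, b2):
    """log P(O=o) by adaptive quadrature of Poisson(o; lam*e) against the
    gamma-mixture prior."""

    def integrand(lam):
        logpois = o * math.log(lam * e) - lam * e - math.lgamma(o + 1)
        return math.exp(logpois) * _mixture_pdf(lam, w, a1, b1, a2, b2)

    mode = max((o + 1) / e, 1e-6)
    upper = max(mode * 20, 30 / min(b1, b2), 100.0)
    val, _ = integrate.quad(integrand, 0, upper,
                            points=[mode / 10, mode, mode * 10], limit=400)
    return math.log(val)


def ebgm_quad_oracle(o, e, w, a1, b1, a2, b2):
    """(exp(E[ln lam | O]), 5th posterior percentile) by adaptive quadrature
    over the unnormalized posterior density."""

    def post(lam):
        logpois = o * math.log(lam * e) - lam * e - math.lgamma(o + 1)
        return math.exp(logpois) * _mixture_pdf(lam, w, a1, b1, a2, b2)

    mode = max((o + 1) / e, 1e-6)
    pts = [mode / 10, mode, mode * 10]
    upper = max(mode * 20, 30 / min(b1, b2), 100.0)
    z, _ = integrate.quad(post, 0, upper, points=pts, limit=400)
    mean_log, _ = integrate.quad(
        lambda lam: math.log(lam) * post(lam), 0, upper, points=pts, limit=400
    )
    mean_log /= z

    def cdf(x):
        val, _ = integrate.quad(post, 0, x, limit=400)
        return val / z

    hi = mode
    while cdf(hi) < 0.05:
        hi *= 2
    q05 = optimize.brentq(lambda x: cdf(x) - 0.05, 1e-12, hi, xtol=1e-13,
                          rtol=1e-13)
    return math.exp(mean_log), q05
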
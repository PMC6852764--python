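"""Edgeworth-series approximation to the pmf of a sum of truncated Poissons.

For large sample sizes the exact convolution of the truncated components is
unnecessary: by the local limit theorem the sum's pmf at an integer point n is
well approximated by a normal density refined with higher-cumulant correction
terms.  Each component's cumulants are computed exactly (by summation over its
support), summed across components, and fed into the standardized Edgeworth
series

    P(S = n) ~ phi(x)/sigma * [1 + sum_s term_s(x)],   x = (n - mu)/sigma,

where ``term_s`` collects, over the integer partitions of s, products of
scaled cumulants with probabilists' Hermite polynomials.  Terms are added in
increasing order s until the last addition is negligible relative to the
accumulated value; growth over several consecutive orders signals divergence
and the caller falls back to exact convolution.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy.stats import poisson

from .errors import EdgeworthDivergenceError
from .lattice import TruncatedPoissonSpec, poisson_logpmf

__all__ = ["edgeworth_sum_mass_at", "truncated_poisson_cumulants"]

# Residual Poisson tail mass allowed beyond the moment-summation window.
_TAIL_EPS = 1e-16
_ABS_FLOOR = 1e-15


def _support_window(spec: TruncatedPoissonSpec) -> tuple[int, int]:
    """Integer window [lo, hi] outside which the truncated pmf is negligible."""
    lo = spec.min_support
    if math.isfinite(spec.upper_incl):
        hi = int(spec.upper_incl)
    else:
        hi = int(poisson.isf(_TAIL_EPS, spec.rate)) + 2
    # Trim a negligible lower tail for large rates (window stays inside the
    # truncation interval, normalization still uses the full interval mass).
    if spec.rate > 50:
        lo = max(lo, int(poisson.ppf(_TAIL_EPS, spec.rate)) - 2)
    return lo, max(hi, lo)


def truncated_poisson_cumulants(spec: TruncatedPoissonSpec, order: int) -> np.ndarray:
    """Cumulants kappa_1..kappa_order of a truncated Poisson, by summation.

    Central moments are accumulated over the support window and converted to
    cumulants with the standard recursion; centering first keeps the
    conversion numerically tame at large rates.
    """
    if spec.rate == 0.0:
        return np.zeros(order)  # degenerate at 0
    lo, hi = _support_window(spec)
    support = np.arange(lo, hi + 1, dtype=float)
    w = np.exp(poisson_logpmf(support, spec.rate) - spec.log_interval_mass())
    mean = float(np.dot(w, support))
    centered = support - mean
    # m[j] = E[(X - mean)^j]
    m = np.empty(order + 1)
    m[0] = float(np.sum(w))
    pw = np.ones_like(centered)
    for j in range(1, order + 1):
        pw = pw * centered
        m[j] = float(np.dot(w, pw))
    # Cumulants of the centered variable: kappa_n = m_n - sum C(n-1, j-1) kappa_j m_{n-j}
    kappa = np.zeros(order + 1)
    for n in range(1, order + 1):
        s = m[n]
        for j in range(1, n):
            s -= math.comb(n - 1, j - 1) * kappa[j] * m[n - j]
        kappa[n] = s
    out = kappa[1:].copy()
    out[0] += mean  # un-center the first cumulant
    return out


@lru_cache(maxsize=None)
def _partitions(s: int) -> tuple[tuple[tuple[int, int], ...], ...]:
    """Integer partitions of s as tuples of (part, multiplicity)."""
    result: list[tuple[tuple[int, int], ...]] = []

    def rec(remaining: int, max_part: int, acc: list[tuple[int, int]]) -> None:
        if remaining == 0:
            result.append(tuple(acc))
            return
        for part in range(min(max_part, remaining), 0, -1):
            for mult in range(remaining // part, 0, -1):
                acc.append((part, mult))
                rec(remaining - part * mult, part - 1, acc)
                acc.pop()

    rec(s, s, [])
    return tuple(result)


def _hermite_values(x: float, max_degree: int) -> np.ndarray:
    """Probabilists' Hermite polynomials He_0..He_max_degree at x."""
    he = np.empty(max_degree + 1)
    he[0] = 1.0
    if max_degree >= 1:
        he[1] = x
    for n in range(1, max_degree):
        he[n + 1] = x * he[n] - n * he[n - 1]
    return he


def edgeworth_sum_mass_at(
    specs: list[TruncatedPoissonSpec],
    target: int,
    rel_tol: float = 1e-9,
    max_order: int = 20,
) -> float:
    """Approximate P(sum of truncated Poissons = target) by Edgeworth series.

    Parameters
    ----------
    specs
        Truncated Poisson components of the sum.
    target
        Integer point at which the sum's pmf is evaluated.
    rel_tol
        Stop once the last added term is below ``rel_tol`` times the
        accumulated sum (an absolute floor of 1e-15 also stops the series).
    max_order
        Highest series order s to include.

    Raises
    ------
    EdgeworthDivergenceError
        If term magnitudes grow for three consecutive orders; callers should
        fall back to exact convolution.
    """
    if target < 0:
        return 0.0
    if rel_tol <= 0:
        raise ValueError("rel_tol must be positive")
    if not specs:
        raise ValueError("need at least one component")

    order_needed = max_order + 2
    kappa = np.zeros(order_needed)
    for spec in specs:
        kappa += truncated_poisson_cumulants(spec, order_needed)

    mu, var = kappa[0], kappa[1]
    if var <= 0:
        return 1.0 if target == round(mu) else 0.0
    sigma = math.sqrt(var)
    x = (target - mu) / sigma
    # Scaled cumulants S_j = kappa_j / sigma^j for j >= 3.
    scaled = np.zeros(order_needed + 1)
    for j in range(3, order_needed + 1):
        scaled[j] = kappa[j - 1] / sigma**j

    base = math.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi) / sigma
    he = _hermite_values(x, 3 * max_order)

    total = base
    prev_mag = abs(base)
    growth_streak = 0
    small_streak = 0
    for s in range(1, max_order + 1):
        coef = 0.0
        for partition in _partitions(s):
            r = sum(mult for _, mult in partition)
            prod = 1.0
            for part, mult in partition:
                prod *= (scaled[part + 2] / math.factorial(part + 2)) ** mult
                prod /= math.factorial(mult)
            coef += he[s + 2 * r] * prod
        term = base * coef
        mag = abs(term)
        if mag < rel_tol * abs(total) or mag < _ABS_FLOOR:
            # Negligible terms are dropped rather than added.  A single tiny
            # term can be an exact zero of an odd-order Hermite polynomial
            # (e.g. at a symmetric point x=0) rather than true convergence,
            # so stop only after two negligible orders in a row.
            small_streak += 1
            if small_streak >= 2:
                break
            continue
        total += term
        small_streak = 0
        if mag > prev_mag:
            growth_streak += 1
            if growth_streak >= 3:
                raise EdgeworthDivergenceError(
                    f"series terms growing at order {s} (|term|={mag:.3g})"
                )
        else:
            growth_streak = 0
        prev_mag = mag
    return max(total, 0.0)
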
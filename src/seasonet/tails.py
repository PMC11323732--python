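"""Upper-tail probabilities for the chi-squared, F and Student-t distributions.

These are the tail routines behind every p-value the package reports
(ANOVA, Kruskal-Wallis, Pearson correlation tests, module-trait
correlations).  They are implemented from first principles on top of the
regularized incomplete gamma and beta functions, evaluated with the
classic series / continued-fraction split (modified Lentz algorithm), so
the statistical layer is self-contained and auditable.  Absolute accuracy
is better than 1e-10 over the degree-of-freedom ranges that occur in
practice (df <= 200).
"""

from __future__ import annotations

import math

from .errors import ValidationError

_EPS = 1e-15
_FPMIN = 1e-300
_ITMAX = 600

__all__ = ["reg_upper_gamma", "reg_inc_beta", "chi2_sf", "f_sf", "t_sf", "norm_sf"]


def _gser(a: float, x: float) -> float:
    """Lower regularized incomplete gamma P(a, x) by series expansion (x < a+1)."""
    ap = a
    summ = 1.0 / a
    delta = summ
    for _ in range(_ITMAX):
        ap += 1.0
        delta *= x / ap
        summ += delta
        if abs(delta) < abs(summ) * _EPS:
            break
    return summ * math.exp(-x + a * math.log(x) - math.lgamma(a))


def _gcf(a: float, x: float) -> float:
    """Upper regularized incomplete gamma Q(a, x) by continued fraction (x >= a+1)."""
    b = x + 1.0 - a
    c = 1.0 / _FPMIN
    d = 1.0 / b
    h = d
    for i in range(1, _ITMAX + 1):
        an = -i * (i - a)
        b += 2.0
        d = an * d + b
        if abs(d) < _FPMIN:
            d = _FPMIN
        c = b + an / c
        if abs(c) < _FPMIN:
            c = _FPMIN
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < _EPS:
            break
    return math.exp(-x + a * math.log(x) - math.lgamma(a)) * h


def reg_upper_gamma(a: float, x: float) -> float:
    """Regularized upper incomplete gamma Q(a, x) = Γ(a, x)/Γ(a)."""
    if a <= 0:
        raise ValidationError(f"shape parameter must be positive, got {a}")
    if x < 0:
        raise ValidationError(f"argument must be non-negative, got {x}")
    if x == 0:
        return 1.0
    if x < a + 1.0:
        return 1.0 - _gser(a, x)
    return _gcf(a, x)


def _betacf(a: float, b: float, x: float) -> float:
    """Continued fraction for the incomplete beta function (Lentz)."""
    qab = a + b
    qap = a + 1.0
    qam = a - 1.0
    c = 1.0
    d = 1.0 - qab * x / qap
    if abs(d) < _FPMIN:
        d = _FPMIN
    d = 1.0 / d
    h = d
    for m in range(1, _ITMAX + 1):
        m2 = 2 * m
        aa = m * (b - m) * x / ((qam + m2) * (a + m2))
        d = 1.0 + aa * d
        if abs(d) < _FPMIN:
            d = _FPMIN
        c = 1.0 + aa / c
        if abs(c) < _FPMIN:
            c = _FPMIN
        d = 1.0 / d
        h *= d * c
        aa = -(a + m) * (qab + m) * x / ((a + m2) * (qap + m2))
        d = 1.0 + aa * d
        if abs(d) < _FPMIN:
            d = _FPMIN
        c = 1.0 + aa / c
        if abs(c) < _FPMIN:
            c = _FPMIN
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < _EPS:
            break
    return h


def reg_inc_beta(a: float, b: float, x: float) -> float:
    """Regularized incomplete beta I_x(a, b)."""
    if a <= 0 or b <= 0:
        raise ValidationError(f"beta parameters must be positive, got a={a}, b={b}")
    if x < 0 or x > 1:
        raise ValidationError(f"argument must lie in [0, 1], got {x}")
    if x == 0.0:
        return 0.0
    if x == 1.0:
        return 1.0
    front = math.exp(
        math.lgamma(a + b)
        - math.lgamma(a)
        - math.lgamma(b)
        + a * math.log(x)
        + b * math.log1p(-x)
    )
    # symmetry split keeps the continued fraction in its fast-converging regime
    if x < (a + 1.0) / (a + b + 2.0):
        return front * _betacf(a, b, x) / a
    return 1.0 - front * _betacf(b, a, 1.0 - x) / b


def chi2_sf(x: float, k: float) -> float:
    """P(X > x) for a chi-squared variate with k degrees of freedom."""
    if k <= 0:
        raise ValidationError(f"degrees of freedom must be positive, got {k}")
    if x < 0:
        raise ValidationError(f"chi-squared statistic must be non-negative, got {x}")
    return reg_upper_gamma(k / 2.0, x / 2.0)


def f_sf(x: float, d1: float, d2: float) -> float:
    """P(F > x) for an F variate with (d1, d2) degrees of freedom."""
    if d1 <= 0 or d2 <= 0:
        raise ValidationError(f"degrees of freedom must be positive, got ({d1}, {d2})")
    if x < 0:
        raise ValidationError(f"F statistic must be non-negative, got {x}")
    if x == 0:
        return 1.0
    return reg_inc_beta(d2 / 2.0, d1 / 2.0, d2 / (d2 + d1 * x))


def t_sf(x: float, df: float) -> float:
    """P(T > x) for a Student-t variate with df degrees of freedom."""
    if df <= 0:
        raise ValidationError(f"degrees of freedom must be positive, got {df}")
    tail = 0.5 * reg_inc_beta(df / 2.0, 0.5, df / (df + x * x))
    return tail if x >= 0 else 1.0 - tail


def norm_sf(z: float) -> float:
    """Standard normal upper tail, used by the Mann-Whitney approximation."""
    return 0.5 * math.erfc(z / math.sqrt(2.0))
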
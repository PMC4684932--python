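"""Closed-form standard errors, power and asymptotic type-I-error predictions.

These serve as fast oracles for the Monte-Carlo module.  The standard-error
expressions assume standardized data and a balanced design; the type-I
formula for the naive t test uses the dummy-coded (0/1) sampling variances,
which differ from the standardized-data expressions by constant factors, so
the two live in separate operations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .exceptions import InvalidParameterError

__all__ = [
    "PowerPoint",
    "se_gamma10",
    "se_beta1_naive",
    "analytic_power_design_b",
    "analytic_type1_naive_ttest",
]


def _check_sizes(nc: int, n_clusters: int) -> None:
    if nc < 1 or n_clusters < 1:
        raise InvalidParameterError("nc and N must be >= 1")


def _check_var(name: str, value: float, strict: bool = False) -> None:
    if not math.isfinite(value) or value < 0 or (strict and value == 0):
        bound = "> 0" if strict else ">= 0"
        raise InvalidParameterError(f"{name} must be {bound}, got {value!r}")


def _check_alpha(alpha: float) -> None:
    if not 0.0 < alpha < 1.0:
        raise InvalidParameterError(f"alpha must lie in (0, 1), got {alpha!r}")


@dataclass(frozen=True)
class PowerPoint:
    """One point of an analytic power surface."""

    n_clusters: int
    n_per_condition: int
    d: float
    var_u1: float
    var_e: float
    alpha: float
    power: float


def se_gamma10(nc: int, N: int, var_u1: float, var_e: float) -> float:
    """Standard error of the overall effect in the full mixed model:
    ``sqrt((nc * var_u1 + var_e) / (nc * N))``.

    Valid for standardized data and a balanced design.  As ``nc`` grows this
    tends to ``sqrt(var_u1 / N)``: extra observations per cluster cannot
    reduce the uncertainty contributed by between-cluster effect variation.
    """
    _check_sizes(nc, N)
    _check_var("var_u1", var_u1)
    _check_var("var_e", var_e, strict=True)
    return math.sqrt((nc * var_u1 + var_e) / (nc * N))


def se_beta1_naive(nc: int, N: int, var_e: float) -> float:
    """Standard error of the effect assumed by the naive individual-level
    analysis: ``sqrt(var_e / (nc * N))``.

    ``var_e`` here is the composite of all variation left unexplained by the
    naive model (residual plus any ignored cluster components).
    """
    _check_sizes(nc, N)
    _check_var("var_e", var_e, strict=True)
    return math.sqrt(var_e / (nc * N))


def analytic_power_design_b(
    d: float,
    nc: int,
    N: int,
    var_u1: float,
    var_e: float = 1.0,
    alpha: float = 0.05,
) -> PowerPoint:
    """Two-sided normal-approximation power of the correctly specified
    mixed model for the overall effect.

    The noncentrality is ``d * sqrt(var_e) / se_gamma10(...)``; power is
    ``P(Z > z_crit - lambda) + P(Z < -z_crit - lambda)``.  Monotone in N and
    |d|; plateaus in nc whenever ``var_u1 > 0``.
    """
    _check_alpha(alpha)
    se = se_gamma10(nc, N, var_u1, var_e)
    lam = d * math.sqrt(var_e) / se
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    power = float(stats.norm.sf(z_crit - lam) + stats.norm.cdf(-z_crit - lam))
    return PowerPoint(
        n_clusters=N, n_per_condition=nc, d=d, var_u1=var_u1,
        var_e=var_e, alpha=alpha, power=power,
    )


def analytic_type1_naive_ttest(
    nc: int,
    N: int,
    var_u0: float,
    var_u1: float,
    var_e: float = 1.0,
    alpha: float = 0.05,
) -> float:
    """Asymptotic type-I error of the pooled t test on individual
    observations of a balanced design-B dataset with a null overall effect.

    The mean-difference estimator averages the within-cluster condition
    contrasts, so intercepts cancel and its true sampling SD is
    ``sqrt(var_u1 / N + 2 * var_e / (nc * N))``; the naive analysis expects
    ``sqrt(2 * (var_e + var_u0 + var_u1 / 2) / (nc * N))`` (the pooled group
    variance absorbs the ignored cluster components).  The rejection rate is
    the normal tail mass beyond the naive critical value on the true scale.
    Sampling noise in the naive variance estimate is ignored (expectation
    plug-in), which is accurate for large ``nc * N``.
    """
    _check_sizes(nc, N)
    _check_var("var_u0", var_u0)
    _check_var("var_u1", var_u1)
    _check_var("var_e", var_e, strict=True)
    _check_alpha(alpha)
    sd_true = math.sqrt(var_u1 / N + 2.0 * var_e / (nc * N))
    se_naive = math.sqrt(2.0 * (var_e + var_u0 + var_u1 / 2.0) / (nc * N))
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(2.0 * stats.norm.sf(z_crit * se_naive / sd_true))
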
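"""Parameter containers and the arithmetic linking user-facing settings
(effect size ``d``, intracluster correlation) to generative variance
components.

Conventions
-----------
* Two experimental conditions, dummy coded 0 (control) and 1 (experimental).
* The residual variance ``var_e`` defaults to 1, so the overall effect on the
  response scale equals the standardized effect size ``d`` and the intercept
  variance implied by an ICC of x is ``x / (1 - x)``.
* An ICC of exactly 1 (complete dependency) is excluded: it has no finite
  intercept variance under the fixed-residual-variance convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

from scipy import stats

from .exceptions import InvalidParameterError, UsageError

__all__ = [
    "DesignSpec",
    "PopulationParams",
    "icc",
    "resolve_params",
    "effect_dispersion_interval",
]

_DESIGNS = ("A", "B")


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise InvalidParameterError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class DesignSpec:
    """Structural layout of a study.

    Parameters
    ----------
    design:
        ``"A"`` — condition is a cluster-level variable, every cluster carries
        a single condition; ``"B"`` — both conditions occur within each
        cluster.
    n_clusters:
        Number of clusters (N), at least 2.
    n_per_condition:
        Observations per experimental condition per cluster for design B;
        observations per cluster for design A. At least 2.
    """

    design: str
    n_clusters: int
    n_per_condition: int
    n_conditions: int = field(default=2)

    def __post_init__(self) -> None:
        if self.design not in _DESIGNS:
            raise InvalidParameterError(
                f"design must be one of {_DESIGNS}, got {self.design!r}"
            )
        if self.n_conditions != 2:
            raise InvalidParameterError("only two experimental conditions are supported")
        if int(self.n_clusters) != self.n_clusters or self.n_clusters < 2:
            raise InvalidParameterError(
                f"n_clusters must be an integer >= 2, got {self.n_clusters!r}"
            )
        if int(self.n_per_condition) != self.n_per_condition or self.n_per_condition < 2:
            raise InvalidParameterError(
                f"n_per_condition must be an integer >= 2, got {self.n_per_condition!r}"
            )
        if self.design == "A" and self.n_clusters % 2:
            raise UsageError(
                "design A requires an even number of clusters "
                "(half-and-half allocation to conditions)"
            )

    @property
    def n_total(self) -> int:
        """Total number of observations in a balanced dataset."""
        per_cluster = self.n_per_condition * (2 if self.design == "B" else 1)
        return self.n_clusters * per_cluster


@dataclass(frozen=True)
class PopulationParams:
    """Generative parameters of the two-level model.

    ``gamma00`` is the overall intercept, ``gamma10`` the overall experimental
    effect (for design A it plays the role of the cluster-level condition
    coefficient).  ``var_e`` is the residual variance, ``var_u0`` the random
    intercept variance, ``var_u1`` the random slope variance and ``cov_u0u1``
    their covariance.  ``effect_size_d`` and ``icc`` are derived identities,
    not free fields.
    """

    gamma00: float = 0.0
    gamma10: float = 0.0
    var_e: float = 1.0
    var_u0: float = 0.0
    var_u1: float = 0.0
    cov_u0u1: float = 0.0

    def __post_init__(self) -> None:
        for name in ("gamma00", "gamma10", "cov_u0u1"):
            _require_finite(name, getattr(self, name))
        if not (math.isfinite(self.var_e) and self.var_e > 0):
            raise InvalidParameterError(f"var_e must be > 0, got {self.var_e!r}")
        for name in ("var_u0", "var_u1"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise InvalidParameterError(f"{name} must be >= 0, got {v!r}")
        # PSD of [[var_u0, cov],[cov, var_u1]]
        if self.cov_u0u1 ** 2 > self.var_u0 * self.var_u1 * (1 + 1e-12):
            raise InvalidParameterError(
                "random-effects covariance matrix is not positive semi-definite: "
                f"|cov_u0u1|={abs(self.cov_u0u1):g} exceeds "
                f"sqrt(var_u0*var_u1)={math.sqrt(self.var_u0 * self.var_u1):g}"
            )

    @property
    def effect_size_d(self) -> float:
        """Standardized effect size, ``gamma10 / sqrt(var_e)``."""
        return self.gamma10 / math.sqrt(self.var_e)

    @property
    def icc(self) -> float:
        """Intracluster correlation, ``var_u0 / (var_u0 + var_e)``."""
        return icc(self.var_u0, self.var_e)

    def re_covariance(self):
        """The 2x2 random-effects covariance matrix as a nested list."""
        return [
            [self.var_u0, self.cov_u0u1],
            [self.cov_u0u1, self.var_u1],
        ]


def icc(var_u0: float, var_e: float) -> float:
    """Intracluster correlation: between-cluster variance over total variance.

    Parameters
    ----------
    var_u0:
        Between-cluster (intercept) variance, >= 0.
    var_e:
        Within-cluster residual variance, > 0.
    """
    var_u0 = _require_finite("var_u0", var_u0)
    var_e = _require_finite("var_e", var_e)
    if var_u0 < 0:
        raise InvalidParameterError(f"var_u0 must be >= 0, got {var_u0!r}")
    if var_e <= 0:
        raise InvalidParameterError(f"var_e must be > 0, got {var_e!r}")
    return var_u0 / (var_u0 + var_e)


def resolve_params(
    d: float,
    icc: float,
    var_u1: float = 0.0,
    cov_u0u1: float = 0.0,
    var_e: float = 1.0,
    gamma00: float = 0.0,
) -> PopulationParams:
    """Map user-facing settings (effect size, ICC) onto generative parameters.

    Inverts the ICC identity at fixed residual variance:
    ``var_u0 = icc / (1 - icc) * var_e`` and ``gamma10 = d * sqrt(var_e)``.
    """
    d = _require_finite("d", d)
    icc_val = _require_finite("icc", icc)
    var_e = _require_finite("var_e", var_e)
    if var_e <= 0:
        raise InvalidParameterError(f"var_e must be > 0, got {var_e!r}")
    if not 0.0 <= icc_val < 1.0:
        raise InvalidParameterError(f"icc must lie in [0, 1), got {icc_val!r}")
    var_u0 = icc_val / (1.0 - icc_val) * var_e
    return PopulationParams(
        gamma00=gamma00,
        gamma10=d * math.sqrt(var_e),
        var_e=var_e,
        var_u0=var_u0,
        var_u1=var_u1,
        cov_u0u1=cov_u0u1,
    )


class DispersionInterval(NamedTuple):
    low: float
    high: float
    sd: float


def effect_dispersion_interval(
    d: float, var_u1: float, coverage: float = 0.95
) -> DispersionInterval:
    """Normal-theory range of cluster-specific experimental effects.

    Returns ``(low, high, sd)`` where ``sd = sqrt(var_u1)`` and the interval
    is ``d -/+ z * sd`` with ``z`` the two-sided normal quantile for the
    requested coverage (computed at double precision, not the rounded 1.96).
    """
    d = _require_finite("d", d)
    var_u1 = _require_finite("var_u1", var_u1)
    if var_u1 < 0:
        raise InvalidParameterError(f"var_u1 must be >= 0, got {var_u1!r}")
    if not 0.0 < coverage < 1.0:
        raise InvalidParameterError(f"coverage must lie in (0, 1), got {coverage!r}")
    sd = math.sqrt(var_u1)
    z = stats.norm.ppf((1.0 + coverage) / 2.0)
    return DispersionInterval(d - z * sd, d + z * sd, sd)
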
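"""Competing analyses of a nested dataset.

Every estimator returns a :class:`FitResult` for the overall experimental
effect (the coefficient on the 0/1 condition code), in Wald form:
``statistic = estimate / se`` referred to a Student t with the stated
degrees of freedom, or to the standard normal (``df = inf``) for the
mixed models.

Mixed models
------------
``lmm_intercept``, ``lmm_intercept_slope`` and ``lmm_covariate`` are REML
fits.  On balanced design-B data (equal cell sizes over clusters and
conditions) the REML solution is available in closed form through the
classical balanced-ANOVA identities, which this module uses for speed; the
closed form is verified against :class:`statsmodels` ``MixedLM`` in the test
suite, and unbalanced data (or ML estimation, or a constrained random-effects
covariance) fall through to ``MixedLM`` directly.  Variance estimates are
truncated at the 0 boundary; ``converged`` is False only on optimizer
failure, never for a boundary/singular fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional

import numpy as np
from scipy import special

from .datagen import NestedDataset
from .exceptions import UsageError

__all__ = [
    "FitResult",
    "ttest_individual",
    "paired_ttest_means",
    "ttest_cluster_means",
    "lmm_intercept",
    "lmm_intercept_slope",
    "fixed_effects_dummies",
    "lmm_covariate",
    "METHODS",
]


@dataclass
class FitResult:
    """Uniform output of one estimator.

    ``df`` is ``math.inf`` for Wald z tests.  ``varcomp`` holds estimated
    variance components (empty for the t-test family).  ``reject`` is the
    alpha-level decision when ``alpha`` was supplied.
    """

    method: str
    estimate: float
    se: float
    statistic: float
    df: float
    p_value: float
    alpha: Optional[float] = None
    reject: Optional[bool] = None
    varcomp: Dict[str, float] = field(default_factory=dict)
    converged: bool = True
    n_obs: int = 0
    n_clusters: int = 0

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "estimate": self.estimate,
            "se": self.se,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "reject": self.reject,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_clusters": self.n_clusters,
        }
        for k, v in self.varcomp.items():
            d[f"varcomp_{k}"] = v
        return d


def _two_sided_p(statistic: float, df: float) -> float:
    if math.isinf(df):
        return 2.0 * float(special.ndtr(-abs(statistic)))
    return 2.0 * float(special.stdtr(df, -abs(statistic)))


def _wald(
    method: str,
    estimate: float,
    se: float,
    df: float,
    alpha: Optional[float],
    varcomp: Optional[Dict[str, float]] = None,
    converged: bool = True,
    n_obs: int = 0,
    n_clusters: int = 0,
) -> FitResult:
    if se > 0:
        statistic = estimate / se
        p = _two_sided_p(statistic, df)
    else:  # degenerate (noiseless) data: flag via se == 0
        statistic = math.inf if estimate > 0 else (-math.inf if estimate < 0 else 0.0)
        p = 0.0 if estimate != 0 else 1.0
    return FitResult(
        method=method,
        estimate=float(estimate),
        se=float(se),
        statistic=float(statistic),
        df=float(df),
        p_value=float(p),
        alpha=alpha,
        reject=None if alpha is None else bool(p < alpha),
        varcomp=varcomp or {},
        converged=converged,
        n_obs=n_obs,
        n_clusters=n_clusters,
    )


# ---------------------------------------------------------------------------
# per-cluster / per-cell summaries
# ---------------------------------------------------------------------------


def _cells(data: NestedDataset):
    """Per (cluster, condition) cell counts, means and within-cell SSE.

    Returns (cluster_ids, counts[K,2], means[K,2], sse_within) where
    sse_within pools squared deviations from the cell means.
    """
    ids, inv = np.unique(data.cluster, return_inverse=True)
    key = inv * 2 + data.condition
    nk = ids.size * 2
    counts = np.bincount(key, minlength=nk)
    sums = np.bincount(key, weights=data.y, minlength=nk)
    sumsq = np.bincount(key, weights=data.y * data.y, minlength=nk)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    sse = float(np.sum(sumsq - counts * np.square(np.where(counts > 0, means, 0.0))))
    return ids, counts.reshape(-1, 2), means.reshape(-1, 2), sse


def _require_both_conditions(ids, counts) -> None:
    missing = (counts == 0).any(axis=1)
    if missing.any():
        raise UsageError(
            f"cluster {ids[missing][0]} lacks one of the two conditions"
        )


# ---------------------------------------------------------------------------
# t-test family
# ---------------------------------------------------------------------------


def ttest_individual(
    data: NestedDataset, alpha: Optional[float] = 0.05, welch: bool = False
) -> FitResult:
    """Two-sample t test on the individual observations, ignoring clustering.

    Pooled-variance Student t by default (groups are equal-sized by design);
    ``welch=True`` switches to the Welch unequal-variance form.
    """
    y0 = data.y[data.condition == 0]
    y1 = data.y[data.condition == 1]
    n0, n1 = y0.size, y1.size
    if n0 < 2 or n1 < 2:
        raise UsageError("each condition needs at least 2 observations")
    est = float(y1.mean() - y0.mean())
    v0 = float(y0.var(ddof=1))
    v1 = float(y1.var(ddof=1))
    if welch:
        se2 = v0 / n0 + v1 / n1
        df = se2 ** 2 / ((v0 / n0) ** 2 / (n0 - 1) + (v1 / n1) ** 2 / (n1 - 1)) if se2 > 0 else 1.0
        se = math.sqrt(se2)
    else:
        sp2 = ((n0 - 1) * v0 + (n1 - 1) * v1) / (n0 + n1 - 2)
        se = math.sqrt(sp2 * (1.0 / n0 + 1.0 / n1))
        df = n0 + n1 - 2
    return _wald(
        "ttest_individual", est, se, df, alpha,
        n_obs=n0 + n1, n_clusters=data.n_clusters,
    )


def paired_ttest_means(data: NestedDataset, alpha: Optional[float] = 0.05) -> FitResult:
    """Paired t test on the condition-specific cluster means (design B)."""
    if data.design != "B":
        raise UsageError("paired_ttest_means requires design-B data")
    ids, counts, means, _ = _cells(data)
    _require_both_conditions(ids, counts)
    diffs = means[:, 1] - means[:, 0]
    n = diffs.size
    if n < 2:
        raise UsageError("paired t test needs at least 2 clusters")
    est = float(diffs.mean())
    se = float(diffs.std(ddof=1) / math.sqrt(n))
    return _wald(
        "paired_ttest_means", est, se, n - 1, alpha,
        n_obs=len(data), n_clusters=n,
    )


def ttest_cluster_means(data: NestedDataset, alpha: Optional[float] = 0.05) -> FitResult:
    """Two-sample pooled t test on cluster means grouped by the cluster-level
    condition (design A aggregation)."""
    if data.design != "A":
        raise UsageError("ttest_cluster_means requires design-A data")
    ids, inv = np.unique(data.cluster, return_inverse=True)
    sums = np.bincount(inv, weights=data.y)
    counts = np.bincount(inv)
    cl_means = sums / counts
    # condition is constant within cluster
    cl_cond = np.zeros(ids.size, dtype=np.int64)
    cl_cond[inv[::-1]] = data.condition[::-1]
    m0 = cl_means[cl_cond == 0]
    m1 = cl_means[cl_cond == 1]
    if m0.size < 2 or m1.size < 2:
        raise UsageError("each condition needs at least 2 clusters")
    est = float(m1.mean() - m0.mean())
    sp2 = ((m0.size - 1) * m0.var(ddof=1) + (m1.size - 1) * m1.var(ddof=1)) / (
        m0.size + m1.size - 2
    )
    se = math.sqrt(sp2 * (1.0 / m0.size + 1.0 / m1.size))
    df = m0.size + m1.size - 2
    return _wald(
        "ttest_cluster_means", est, se, df, alpha,
        n_obs=len(data), n_clusters=ids.size,
    )


# ---------------------------------------------------------------------------
# mixed models
# ---------------------------------------------------------------------------


def _fit_mixedlm(
    data: NestedDataset,
    alpha: Optional[float],
    method_name: str,
    reml: bool,
    random_slope: bool,
    estimate_covariance: bool = True,
    with_covariate: bool = False,
) -> FitResult:
    """General-purpose fallback via statsmodels MixedLM (lazy import)."""
    import statsmodels.api as sm
    from statsmodels.regression.mixed_linear_model import MixedLMParams

    x = data.condition.astype(np.float64)
    cols = [np.ones_like(x), x]
    if with_covariate:
        cols += [data.w, data.w * x]
    exog = np.column_stack(cols)
    exog_re = np.column_stack([np.ones_like(x), x]) if random_slope else np.ones((x.size, 1))
    model = sm.MixedLM(data.y, exog, groups=data.cluster, exog_re=exog_re)
    fit_kwargs: dict = {"reml": reml}
    if random_slope and not estimate_covariance:
        free = MixedLMParams.from_components(
            fe_params=np.ones(exog.shape[1]), cov_re=np.eye(2)
        )
        fit_kwargs["free"] = free
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="lbfgs", **fit_kwargs)
            converged = bool(res.converged)
        except Exception:
            try:
                res = model.fit(method="powell", **fit_kwargs)
                converged = bool(res.converged)
            except Exception:
                return FitResult(
                    method=method_name, estimate=math.nan, se=math.nan,
                    statistic=math.nan, df=math.inf, p_value=math.nan,
                    alpha=alpha, reject=None, converged=False,
                    n_obs=len(data), n_clusters=data.n_clusters,
                )
    est = float(res.fe_params[1])
    se = float(res.bse_fe[1])
    varcomp = {
        "var_e": max(float(res.scale), 0.0),
        "var_u0": max(float(res.cov_re[0, 0]), 0.0),
    }
    if random_slope:
        varcomp["var_u1"] = max(float(res.cov_re[1, 1]), 0.0)
        varcomp["cov_u0u1"] = float(res.cov_re[0, 1]) if estimate_covariance else 0.0
    return _wald(
        method_name, est, se, math.inf, alpha, varcomp=varcomp,
        converged=converged, n_obs=len(data), n_clusters=data.n_clusters,
    )


def lmm_intercept(
    data: NestedDataset, alpha: Optional[float] = 0.05, reml: bool = True
) -> FitResult:
    """Random-intercept mixed model ``y ~ condition + (1 | cluster)``.

    Wald z test of the condition effect.  For balanced design-B data the REML
    estimates come from the exact balanced-ANOVA identities; otherwise the
    model is fitted numerically.
    """
    if data.n_clusters < 2:
        raise UsageError("mixed model needs at least 2 clusters")
    if not (reml and data.design == "B" and data.is_balanced()):
        return _fit_mixedlm(data, alpha, "lmm_intercept", reml, random_slope=False)
    ids, counts, means, sse_cells = _cells(data)
    nc = int(counts[0, 0])
    n_cl = ids.size
    n = len(data)
    # within estimator: balanced => difference of condition grand means
    diffs = means[:, 1] - means[:, 0]
    est = float(diffs.mean())
    cl_means = means.mean(axis=1)
    grand = float(cl_means.mean())
    # between-condition-within-cluster SS not explained by the common slope
    ss_slope_dev = (nc / 2.0) * float(np.sum((diffs - est) ** 2))
    ssw = sse_cells + ss_slope_dev
    df_w = n - n_cl - 1
    var_e = ssw / df_w
    ssb = 2.0 * nc * float(np.sum((cl_means - grand) ** 2))
    msb = ssb / (n_cl - 1)
    var_u0 = (msb - var_e) / (2.0 * nc)
    if var_u0 < 0:  # boundary: model collapses to OLS on [1, x]
        var_u0 = 0.0
        var_e = (ssw + ssb) / (n - 2)
    se = math.sqrt(2.0 * var_e / (nc * n_cl))
    return _wald(
        "lmm_intercept", est, se, math.inf, alpha,
        varcomp={"var_e": var_e, "var_u0": var_u0},
        n_obs=n, n_clusters=n_cl,
    )


def lmm_intercept_slope(
    data: NestedDataset,
    alpha: Optional[float] = 0.05,
    reml: bool = True,
    estimate_covariance: bool = True,
) -> FitResult:
    """Random-intercept + random-slope mixed model
    ``y ~ condition + (condition | cluster)``, Wald z on the condition effect.

    Balanced design-B REML in closed form through the per-cluster condition
    means: the fixed-effect estimate and its standard error coincide with the
    paired-means t quantities, and the variance components follow from the
    cell-mean covariance matrix after removing the within-cell noise share.
    """
    if data.design != "B":
        raise UsageError("lmm_intercept_slope requires design-B data")
    ids, counts, means, sse_cells = _cells(data)
    _require_both_conditions(ids, counts)
    if counts.min() < 2:
        raise UsageError("need at least 2 observations per condition per cluster")
    if not (reml and estimate_covariance and data.is_balanced()):
        return _fit_mixedlm(
            data, alpha, "lmm_intercept_slope", reml,
            random_slope=True, estimate_covariance=estimate_covariance,
        )
    nc = int(counts[0, 0])
    n_cl = ids.size
    a = means[:, 0]
    b = means[:, 1]
    d = b - a
    est = float(d.mean())
    var_d = float(d.var(ddof=1))
    var_e = sse_cells / (2.0 * n_cl * (nc - 1))
    s = var_e / nc
    if var_d - 2.0 * s <= 0.0:
        # slope variance truncates at 0: REML collapses to the
        # random-intercept model, whose SE applies
        ri = lmm_intercept(data, alpha, reml=True)
        ri.method = "lmm_intercept_slope"
        ri.varcomp.update({"var_u1": 0.0, "cov_u0u1": 0.0})
        return ri
    se = math.sqrt(var_d / n_cl)
    s11 = float(a.var(ddof=1))
    s12 = float(np.cov(a, b, ddof=1)[0, 1])
    var_u0 = max(s11 - s, 0.0)
    var_u1 = var_d - 2.0 * s
    cov = s12 - s11 + s
    bound = math.sqrt(var_u0 * var_u1)
    cov = min(max(cov, -bound), bound)
    return _wald(
        "lmm_intercept_slope", est, se, math.inf, alpha,
        varcomp={"var_e": var_e, "var_u0": var_u0, "var_u1": var_u1, "cov_u0u1": cov},
        n_obs=len(data), n_clusters=n_cl,
    )


def fixed_effects_dummies(data: NestedDataset, alpha: Optional[float] = 0.05) -> FitResult:
    """OLS of y on the condition code plus N-1 cluster-membership indicators.

    Computed by within-cluster demeaning (Frisch-Waugh); t test on the
    condition coefficient with ``df = n_total - N - 1``.
    """
    if data.design != "B":
        raise UsageError("fixed_effects_dummies requires design-B data")
    ids, inv = np.unique(data.cluster, return_inverse=True)
    n = len(data)
    n_cl = ids.size
    counts = np.bincount(inv)
    y_mean = np.bincount(inv, weights=data.y) / counts
    x = data.condition.astype(np.float64)
    x_mean = np.bincount(inv, weights=x) / counts
    y_t = data.y - y_mean[inv]
    x_t = x - x_mean[inv]
    sxx = float(x_t @ x_t)
    df = n - n_cl - 1
    if sxx <= 0 or df <= 0:
        raise UsageError("design matrix is rank deficient (condition constant within clusters?)")
    est = float(x_t @ y_t) / sxx
    resid = y_t - est * x_t
    sigma2 = float(resid @ resid) / df
    se = math.sqrt(sigma2 / sxx)
    return _wald(
        "fixed_effects_dummies", est, se, df, alpha,
        varcomp={"var_e": sigma2}, n_obs=n, n_clusters=n_cl,
    )


def lmm_covariate(
    data: NestedDataset, alpha: Optional[float] = 0.05, reml: bool = True
) -> FitResult:
    """Random-intercept + random-slope model extended with the cluster-level
    covariate ``w`` and its interaction with the condition.

    Reports the conditional main effect of the condition (at ``w = 0``);
    ``varcomp['var_u1']`` is the residual slope variance after the covariate.
    """
    if data.w is None:
        raise UsageError("lmm_covariate requires a dataset with covariate w")
    if data.design != "B":
        raise UsageError("lmm_covariate requires design-B data")
    ids, inv = np.unique(data.cluster, return_inverse=True)
    w_cl = np.empty(ids.size)
    w_cl[inv[::-1]] = data.w[::-1]
    if not np.allclose(w_cl[inv], data.w, equal_nan=True):
        raise UsageError("covariate w must be constant within each cluster")
    _, counts, means, sse_cells = _cells(data)
    _require_both_conditions(ids, counts)
    if not (reml and data.is_balanced() and counts.min() >= 2):
        return _fit_mixedlm(
            data, alpha, "lmm_covariate", reml,
            random_slope=True, with_covariate=True,
        )
    nc = int(counts[0, 0])
    n_cl = ids.size
    if n_cl < 3:
        raise UsageError("covariate model needs at least 3 clusters")
    a = means[:, 0]
    d = means[:, 1] - means[:, 0]
    design = np.column_stack([np.ones(n_cl), w_cl])
    # equation-by-equation OLS == GLS (identical regressors in both equations)
    coef_d, _, _, _ = np.linalg.lstsq(design, d, rcond=None)
    coef_a, _, _, _ = np.linalg.lstsq(design, a, rcond=None)
    resid_d = d - design @ coef_d
    resid_a = a - design @ coef_a
    df_between = n_cl - 2
    s2_d = float(resid_d @ resid_d) / df_between
    xtx_inv = np.linalg.inv(design.T @ design)
    se = math.sqrt(s2_d * xtx_inv[0, 0])
    est = float(coef_d[0])
    var_e = sse_cells / (2.0 * n_cl * (nc - 1))
    s = var_e / nc
    s2_a = float(resid_a @ resid_a) / df_between
    s_ad = float(resid_a @ resid_d) / df_between
    var_u0 = max(s2_a - s, 0.0)
    var_u1 = max(s2_d - 2.0 * s, 0.0)
    cov = s_ad + s
    bound = math.sqrt(var_u0 * var_u1)
    cov = min(max(cov, -bound), bound)
    return _wald(
        "lmm_covariate", est, se, math.inf, alpha,
        varcomp={"var_e": var_e, "var_u0": var_u0, "var_u1": var_u1, "cov_u0u1": cov},
        n_obs=len(data), n_clusters=n_cl,
    )


METHODS: Dict[str, Callable[..., FitResult]] = {
    "ttest_individual": ttest_individual,
    "paired_ttest_means": paired_ttest_means,
    "ttest_cluster_means": ttest_cluster_means,
    "lmm_intercept": lmm_intercept,
    "lmm_intercept_slope": lmm_intercept_slope,
    "fixed_effects_dummies": fixed_effects_dummies,
    "lmm_covariate": lmm_covariate,
}
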
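"""Synthetic nested-data generators.

Design B: ``y = gamma00 + u0j + (gamma10 + u1j) * x + e`` with
``(u0j, u1j)`` bivariate normal and ``x`` a 0/1 dummy varying within
cluster.  Design A: ``y = gamma00 + gamma10 * z_j + u0j + e`` with the
condition ``z_j`` constant within cluster (first half of clusters control,
second half experimental).

All generators are deterministic given a seed.  A seed may be an integer,
a :class:`numpy.random.SeedSequence`, or a :class:`numpy.random.Generator`
(the latter allows a Monte-Carlo driver to hand out spawned child streams).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError, UsageError
from .params import DesignSpec, PopulationParams

__all__ = [
    "NestedDataset",
    "generate_design_a",
    "generate_design_b",
    "generate_with_cluster_covariate",
]

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]


def _as_rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class NestedDataset:
    """Long-format nested observations backed by flat numpy arrays.

    ``cluster`` holds non-negative integer cluster ids, ``condition`` the 0/1
    condition code (observation-level for design B, cluster-level for
    design A), ``y`` the response and ``w`` an optional cluster-level
    covariate (constant within cluster).
    """

    cluster: np.ndarray
    condition: np.ndarray
    y: np.ndarray
    design: str
    w: Optional[np.ndarray] = None
    balanced: bool = True

    def __post_init__(self) -> None:
        self.cluster = np.asarray(self.cluster, dtype=np.int64)
        self.condition = np.asarray(self.condition, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.w is not None:
            self.w = np.asarray(self.w, dtype=np.float64)
        n = self.cluster.shape[0]
        if not (self.condition.shape[0] == n == self.y.shape[0]):
            raise InvalidParameterError("cluster, condition and y must have equal length")
        if self.w is not None and self.w.shape[0] != n:
            raise InvalidParameterError("w must have the same length as y")

    def __len__(self) -> int:
        return int(self.y.shape[0])

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.cluster).size)

    def validate(self) -> "NestedDataset":
        """Check the structural invariants of the declared design; return self."""
        if self.design not in ("A", "B"):
            raise InvalidParameterError(f"unknown design {self.design!r}")
        if not np.isin(self.condition, (0, 1)).all():
            raise InvalidParameterError("condition codes must be 0 or 1")
        if (self.cluster < 0).any():
            raise InvalidParameterError("cluster ids must be non-negative integers")
        ids, inv = np.unique(self.cluster, return_inverse=True)
        cond_min = np.full(ids.size, 2, dtype=np.int64)
        cond_max = np.full(ids.size, -1, dtype=np.int64)
        np.minimum.at(cond_min, inv, self.condition)
        np.maximum.at(cond_max, inv, self.condition)
        if self.design == "B":
            if not ((cond_min == 0) & (cond_max == 1)).all():
                bad = ids[(cond_min != 0) | (cond_max != 1)][0]
                raise UsageError(f"design B requires both conditions in every cluster; cluster {bad} lacks one")
        else:
            if not (cond_min == cond_max).all():
                bad = ids[cond_min != cond_max][0]
                raise UsageError(f"design A requires a single condition per cluster; cluster {bad} mixes both")
        if self.w is not None:
            w_first = np.empty(ids.size)
            w_first[inv[::-1]] = self.w[::-1]
            if not np.array_equal(w_first[inv], self.w, equal_nan=True):
                raise InvalidParameterError("covariate w must be constant within each cluster")
        return self

    def is_balanced(self) -> bool:
        """True when every (cluster, condition) cell has the same size."""
        ids, inv = np.unique(self.cluster, return_inverse=True)
        counts = np.bincount(inv * 2 + self.condition, minlength=ids.size * 2)
        counts = counts.reshape(ids.size, 2)
        if self.design == "B":
            return bool((counts == counts[0, 0]).all())
        per_cluster = counts.sum(axis=1)
        return bool((per_cluster == per_cluster[0]).all())

    def to_frame(self) -> pd.DataFrame:
        cols = {"cluster": self.cluster, "condition": self.condition, "y": self.y}
        if self.w is not None:
            cols["w"] = self.w
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, design: str = "B") -> "NestedDataset":
        w = frame["w"].to_numpy() if "w" in frame.columns else None
        ds = cls(
            cluster=frame["cluster"].to_numpy(),
            condition=frame["condition"].to_numpy(),
            y=frame["y"].to_numpy(),
            design=design,
            w=w,
        )
        ds.validate()
        ds.balanced = ds.is_balanced()
        return ds

    def __eq__(self, other: object) -> bool:  # value equality, for round-trip tests
        if not isinstance(other, NestedDataset):
            return NotImplemented
        same_w = (self.w is None and other.w is None) or (
            self.w is not None
            and other.w is not None
            and np.array_equal(self.w, other.w)
        )
        return (
            self.design == other.design
            and np.array_equal(self.cluster, other.cluster)
            and np.array_equal(self.condition, other.condition)
            and np.array_equal(self.y, other.y)
            and same_w
        )


def _design_b_layout(spec: DesignSpec) -> tuple[np.ndarray, np.ndarray]:
    """Cluster-major layout: nc control rows then nc experimental rows per cluster."""
    n, nc = spec.n_clusters, spec.n_per_condition
    cluster = np.repeat(np.arange(n, dtype=np.int64), 2 * nc)
    condition = np.tile(np.repeat(np.array([0, 1], dtype=np.int64), nc), n)
    return cluster, condition


def _draw_random_effects(
    params: PopulationParams, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (u0, u1) via the Cholesky-like factor of the 2x2 covariance.

    Handles singular covariances (zero variances) without error.
    """
    z = rng.standard_normal((n, 2))
    s0 = math.sqrt(params.var_u0)
    u0 = s0 * z[:, 0]
    if params.var_u0 > 0:
        b = params.cov_u0u1 / params.var_u0
        resid = params.var_u1 - b * params.cov_u0u1
        u1 = b * u0 + math.sqrt(max(resid, 0.0)) * z[:, 1]
    else:
        u1 = math.sqrt(params.var_u1) * z[:, 1]
    return u0, u1


def generate_design_b(
    spec: DesignSpec, params: PopulationParams, seed: SeedLike
) -> NestedDataset:
    """Generate a balanced design-B dataset (both conditions in every cluster)."""
    if spec.design != "B":
        raise UsageError("generate_design_b requires a design-B spec")
    rng = _as_rng(seed)
    n, nc = spec.n_clusters, spec.n_per_condition
    cluster, condition = _design_b_layout(spec)
    u0, u1 = _draw_random_effects(params, n, rng)
    e = rng.standard_normal(cluster.size) * math.sqrt(params.var_e)
    x = condition.astype(np.float64)
    y = params.gamma00 + u0[cluster] + (params.gamma10 + u1[cluster]) * x + e
    return NestedDataset(cluster, condition, y, design="B", balanced=True)


def generate_design_a(
    spec: DesignSpec, params: PopulationParams, seed: SeedLike
) -> NestedDataset:
    """Generate a design-A dataset: condition constant within cluster.

    The first half of the clusters is assigned to control, the second half to
    the experimental condition (a convention; equal group sizes required).
    """
    if spec.design != "A":
        raise UsageError("generate_design_a requires a design-A spec")
    if params.var_u1 != 0:
        raise UsageError("design A has no random slope; params.var_u1 must be 0")
    rng = _as_rng(seed)
    n, nc = spec.n_clusters, spec.n_per_condition
    cluster = np.repeat(np.arange(n, dtype=np.int64), nc)
    z_cluster = np.repeat(np.array([0, 1], dtype=np.int64), n // 2)
    condition = z_cluster[cluster]
    u0 = rng.standard_normal(n) * math.sqrt(params.var_u0)
    e = rng.standard_normal(cluster.size) * math.sqrt(params.var_e)
    y = params.gamma00 + params.gamma10 * condition + u0[cluster] + e
    return NestedDataset(cluster, condition, y, design="A", balanced=True)


def generate_with_cluster_covariate(
    spec: DesignSpec,
    params: PopulationParams,
    explained_fraction: float,
    seed: SeedLike,
    covariate_slope: Optional[float] = None,
) -> NestedDataset:
    """Design-B data where a standard-normal cluster covariate w explains part
    of the slope variance.

    The cluster slope is ``gamma10 + covariate_slope * w_j + u1j`` with
    ``var(u1j) = (1 - explained_fraction) * var_u1`` and, by default,
    ``covariate_slope = sqrt(explained_fraction * var_u1)`` so the marginal
    slope variance across clusters stays ``var_u1``.
    """
    if spec.design != "B":
        raise UsageError("generate_with_cluster_covariate requires a design-B spec")
    if params.var_u1 <= 0:
        raise UsageError("cluster covariate generation requires params.var_u1 > 0")
    if not 0.0 <= explained_fraction < 1.0:
        raise InvalidParameterError(
            f"explained_fraction must lie in [0, 1), got {explained_fraction!r}"
        )
    rng = _as_rng(seed)
    if covariate_slope is None:
        covariate_slope = math.sqrt(explained_fraction * params.var_u1)
    residual_params = replace(
        params,
        var_u1=(1.0 - explained_fraction) * params.var_u1,
        # scale the covariance to keep the matrix PSD after shrinking var_u1
        cov_u0u1=params.cov_u0u1 * math.sqrt(1.0 - explained_fraction),
    )
    n = spec.n_clusters
    cluster, condition = _design_b_layout(spec)
    w_cluster = rng.standard_normal(n)
    u0, u1 = _draw_random_effects(residual_params, n, rng)
    e = rng.standard_normal(cluster.size) * math.sqrt(params.var_e)
    x = condition.astype(np.float64)
    slope = params.gamma10 + covariate_slope * w_cluster + u1
    y = params.gamma00 + u0[cluster] + slope[cluster] * x + e
    return NestedDataset(
        cluster, condition, y, design="B", w=w_cluster[cluster], balanced=True
    )
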
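"""Monte-Carlo harness: rejection rates of the estimator battery over
parameter grids (type-I error when d = 0, power when d > 0).

All requested methods are fitted on the *same* replicate datasets (common
random numbers), which sharpens power differences without biasing marginal
rates.  Replicate r of a run depends only on ``(master_seed, r)`` through
spawned :class:`numpy.random.SeedSequence` child streams.

Results are plain :class:`pandas.DataFrame` tables with one row per
(cell, method) and columns::

    study, N, nc, d, icc, var_u1, method,
    reps_used, rejections, rate, ci_low, ci_high, n_nonconverged

``ci_low``/``ci_high`` form the 95 % Wilson score interval.  Non-converged
mixed-model fits are excluded from a method's denominator (``reps_used``)
and counted in ``n_nonconverged``; a warning is logged when more than 2 %
of replicates drop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from . import datagen
from .datagen import NestedDataset
from .estimators import METHODS
from .exceptions import UsageError
from .params import DesignSpec, PopulationParams, resolve_params

__all__ = [
    "StudyGrid",
    "RejectionRateTable",
    "rejection_rate",
    "replicate_study",
    "power_difference",
    "STUDY_IDS",
    "DEFAULT_METHODS",
]

logger = logging.getLogger(__name__)

RejectionRateTable = pd.DataFrame
Cell = Tuple[PopulationParams, DesignSpec]
SeedLike = Union[int, np.random.SeedSequence]

STUDY_IDS = ("1a", "1b", "2a", "2b")

#: the four analyses compared in the simulation studies
DEFAULT_METHODS = (
    "ttest_individual",
    "paired_ttest_means",
    "lmm_intercept",
    "lmm_intercept_slope",
)

TABLE_COLUMNS = [
    "study", "N", "nc", "d", "icc", "var_u1", "method",
    "reps_used", "rejections", "rate", "ci_low", "ci_high", "n_nonconverged",
]

NONCONVERGENCE_WARN_FRACTION = 0.02


@dataclass
class StudyGrid:
    """A resolved simulation study: parameter cells x methods."""

    study_id: str
    cells: list  # of (PopulationParams, DesignSpec)
    methods: Sequence[str] = DEFAULT_METHODS
    alpha: float = 0.05
    n_reps: int = 10_000
    master_seed: int = 0

    def run(self) -> RejectionRateTable:
        frames = []
        for i, cell in enumerate(self.cells):
            seed = np.random.SeedSequence(self.master_seed, spawn_key=(i,))
            frames.append(
                rejection_rate(
                    cell, self.methods, self.n_reps, alpha=self.alpha,
                    master_seed=seed, study_id=self.study_id,
                )
            )
        return pd.concat(frames, ignore_index=True)


def _default_generator(
    spec: DesignSpec, params: PopulationParams, rng: np.random.Generator
) -> NestedDataset:
    if spec.design == "B":
        return datagen.generate_design_b(spec, params, rng)
    return datagen.generate_design_a(spec, params, rng)


def rejection_rate(
    cell: Cell,
    methods: Sequence[str],
    n_reps: int,
    alpha: float = 0.05,
    master_seed: SeedLike = 0,
    study_id: str = "custom",
    generator: Optional[Callable] = None,
) -> RejectionRateTable:
    """Empirical rejection rates of ``methods`` on ``n_reps`` datasets drawn
    from one parameter cell.

    ``generator(spec, params, rng)`` may override the dataset source (e.g. to
    include a cluster covariate); by default it dispatches on the design.
    """
    params, spec = cell
    if n_reps < 1:
        raise UsageError("n_reps must be >= 1")
    unknown = [m for m in methods if m not in METHODS]
    if unknown:
        raise UsageError(
            f"unknown method(s) {unknown}; valid names: {sorted(METHODS)}"
        )
    if generator is None:
        generator = _default_generator
    ss = (
        master_seed
        if isinstance(master_seed, np.random.SeedSequence)
        else np.random.SeedSequence(master_seed)
    )
    rejections = {m: 0 for m in methods}
    n_used = {m: 0 for m in methods}
    n_bad = {m: 0 for m in methods}
    for child in ss.spawn(n_reps):
        rng = np.random.default_rng(child)
        data = generator(spec, params, rng)
        for m in methods:
            fit = METHODS[m](data, alpha)
            if not fit.converged:
                n_bad[m] += 1
                continue
            n_used[m] += 1
            rejections[m] += int(fit.p_value < alpha)
    rows = []
    for m in methods:
        if n_bad[m] > NONCONVERGENCE_WARN_FRACTION * n_reps:
            logger.warning(
                "method %s: %d/%d replicates failed to converge in cell "
                "(N=%d, nc=%d, d=%g, icc=%g, var_u1=%g)",
                m, n_bad[m], n_reps, spec.n_clusters, spec.n_per_condition,
                params.effect_size_d, params.icc, params.var_u1,
            )
        used = n_used[m]
        rate = rejections[m] / used if used else np.nan
        if used:
            lo, hi = proportion_confint(rejections[m], used, alpha=0.05, method="wilson")
        else:
            lo = hi = np.nan
        rows.append(
            {
                "study": study_id,
                "N": spec.n_clusters,
                "nc": spec.n_per_condition,
                "d": params.effect_size_d,
                "icc": params.icc,
                "var_u1": params.var_u1,
                "method": m,
                "reps_used": used,
                "rejections": rejections[m],
                "rate": rate,
                "ci_low": lo,
                "ci_high": hi,
                "n_nonconverged": n_bad[m],
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


_STUDY_DEFAULTS: Mapping[str, dict] = {
    "1a": dict(d=(0.20, 0.50), icc=(0.0,), var_u1=(0.0,), N=(10, 30),
               nc=tuple(range(5, 51, 10))),
    "1b": dict(d=(0.20, 0.50), icc=(0.25, 0.50), var_u1=(0.0,), N=(10, 30),
               nc=tuple(range(5, 51, 10))),
    "2a": dict(d=(0.0,), icc=(0.0,), var_u1=(0.025, 0.05, 0.10, 0.15), N=(50,),
               nc=tuple(range(5, 106, 10))),
    "2b": dict(d=(0.0,), icc=(0.50,), var_u1=(0.025, 0.05, 0.10, 0.15), N=(50,),
               nc=tuple(range(5, 106, 10))),
}


def study_cells(
    study_id: str,
    nc_grid: Optional[Iterable[int]] = None,
    overrides: Optional[Mapping[str, Iterable]] = None,
) -> list:
    """Expand a study's default parameter grid into (params, spec) cells."""
    if study_id not in _STUDY_DEFAULTS:
        raise UsageError(f"unknown study {study_id!r}; valid: {list(_STUDY_DEFAULTS)}")
    grid = dict(_STUDY_DEFAULTS[study_id])
    if nc_grid is not None:
        grid["nc"] = tuple(int(v) for v in nc_grid)
    for key, values in (overrides or {}).items():
        if key not in grid:
            raise UsageError(f"unknown grid dimension {key!r}; valid: {list(grid)}")
        grid[key] = tuple(values)
    cells = []
    for d in grid["d"]:
        for icc in grid["icc"]:
            for var_u1 in grid["var_u1"]:
                for n in grid["N"]:
                    for nc in grid["nc"]:
                        cells.append(
                            (
                                resolve_params(d=d, icc=icc, var_u1=var_u1),
                                DesignSpec(design="B", n_clusters=n, n_per_condition=nc),
                            )
                        )
    if not cells:
        raise UsageError("empty parameter grid")
    return cells


def replicate_study(
    study_id: str,
    n_reps: int = 10_000,
    master_seed: int = 0,
    nc_grid: Optional[Iterable[int]] = None,
    overrides: Optional[Mapping[str, Iterable]] = None,
    methods: Sequence[str] = DEFAULT_METHODS,
    alpha: float = 0.05,
) -> RejectionRateTable:
    """Run one of the canned simulation studies (1a, 1b, 2a, 2b) and return
    the full rejection-rate table.  Deterministic given ``master_seed``."""
    cells = study_cells(study_id, nc_grid=nc_grid, overrides=overrides)
    grid = StudyGrid(
        study_id=study_id, cells=cells, methods=methods,
        alpha=alpha, n_reps=n_reps, master_seed=master_seed,
    )
    return grid.run()


_CELL_KEYS = ["study", "N", "nc", "d", "icc", "var_u1"]


def power_difference(
    table: RejectionRateTable, method_a: str, method_b: str
) -> pd.DataFrame:
    """Per-cell ``rate(method_a) - rate(method_b)`` with a propagated 95 %
    normal-approximation confidence interval.

    The propagation treats the two rates as independent binomials, which is
    conservative under common random numbers.
    """
    for m in (method_a, method_b):
        if m not in set(table["method"]):
            raise UsageError(f"method {m!r} not present in table")
    a = table[table["method"] == method_a].set_index(_CELL_KEYS)
    b = table[table["method"] == method_b].set_index(_CELL_KEYS)
    joined = a.join(b, lsuffix="_a", rsuffix="_b", how="inner")
    diff = joined["rate_a"] - joined["rate_b"]
    var_a = joined["rate_a"] * (1 - joined["rate_a"]) / joined["reps_used_a"]
    var_b = joined["rate_b"] * (1 - joined["rate_b"]) / joined["reps_used_b"]
    half = 1.959963984540054 * np.sqrt(var_a + var_b)
    out = joined.reset_index()[_CELL_KEYS].copy()
    out["method_a"] = method_a
    out["method_b"] = method_b
    out["diff"] = diff.to_numpy()
    out["ci_low"] = (diff - half).to_numpy()
    out["ci_high"] = (diff + half).to_numpy()
    return out
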
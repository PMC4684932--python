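"""Flat key-value run configuration (YAML; JSON is a YAML subset).

All CLI flags override config values.  Unknown keys are rejected with the
list of valid keys, and a loaded config round-trips losslessly through
:func:`dump_config`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional, Union

import yaml

from .exceptions import DataFormatError, InvalidParameterError
from .params import DesignSpec, PopulationParams, resolve_params

__all__ = ["RunConfig", "load_config", "dump_config"]

_SUBCOMMANDS = ("simulate", "fit", "replicate", "power")


@dataclass
class RunConfig:
    """Validated run settings: model parameters plus execution knobs."""

    subcommand: Optional[str] = None
    # parameter section
    design: str = "B"
    n_clusters: int = 10
    n_per_condition: int = 5
    d: float = 0.0
    icc: float = 0.0
    var_u1: float = 0.0
    cov_u0u1: float = 0.0
    var_e: float = 1.0
    gamma00: float = 0.0
    alpha: float = 0.05
    # execution section
    study: Optional[str] = None
    method: Optional[str] = None
    reps: int = 10_000
    seed: int = 0
    workers: int = 1
    out: Optional[str] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.subcommand is not None and self.subcommand not in _SUBCOMMANDS:
            raise InvalidParameterError(
                f"subcommand must be one of {_SUBCOMMANDS}, got {self.subcommand!r}"
            )
        if not 0.0 < self.alpha < 1.0:
            raise InvalidParameterError(f"alpha must lie in (0, 1), got {self.alpha!r}")
        if self.reps < 1:
            raise InvalidParameterError("reps must be >= 1")
        # delegate parameter-domain checks (raises on e.g. icc >= 1)
        self.population_params()
        self.design_spec()

    def population_params(self) -> PopulationParams:
        return resolve_params(
            d=self.d, icc=self.icc, var_u1=self.var_u1,
            cov_u0u1=self.cov_u0u1, var_e=self.var_e, gamma00=self.gamma00,
        )

    def design_spec(self) -> DesignSpec:
        return DesignSpec(
            design=self.design,
            n_clusters=self.n_clusters,
            n_per_condition=self.n_per_condition,
        )

    def to_dict(self) -> dict:
        return asdict(self)


_VALID_KEYS = tuple(f.name for f in fields(RunConfig))


def load_config(path: Union[str, Path]) -> RunConfig:
    """Parse and validate a config file; unknown keys are an error."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" (line {mark.line + 1})" if mark is not None else ""
        raise DataFormatError(f"{path}: cannot parse config{where}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise DataFormatError(f"{path}: config must be a flat key-value mapping")
    unknown = sorted(set(raw) - set(_VALID_KEYS))
    if unknown:
        raise DataFormatError(
            f"{path}: unknown key(s) {unknown}; valid keys: {list(_VALID_KEYS)}"
        )
    try:
        return RunConfig(**raw)
    except (InvalidParameterError, TypeError) as exc:
        raise DataFormatError(f"{path}: invalid config: {exc}") from exc


def dump_config(config: RunConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
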
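"""Canonical small datasets for tests and examples, generated on the fly.

Each fixture carries the exact generating manifest (spec, params, seed), so
any fixture can be regenerated bit-for-bit from its manifest alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

from . import datagen
from .datagen import NestedDataset
from .params import DesignSpec, PopulationParams, resolve_params

__all__ = ["Fixture", "make_fixtures", "regenerate"]


@dataclass(frozen=True)
class Fixture:
    name: str
    dataset: NestedDataset
    spec: DesignSpec
    params: PopulationParams
    seed: int
    explained_fraction: float = 0.0  # only used by the covariate fixture


def _generate(spec: DesignSpec, params: PopulationParams, seed: int,
              explained_fraction: float = 0.0) -> NestedDataset:
    if explained_fraction > 0:
        return datagen.generate_with_cluster_covariate(
            spec, params, explained_fraction, seed
        )
    if spec.design == "A":
        return datagen.generate_design_a(spec, params, seed)
    return datagen.generate_design_b(spec, params, seed)


def regenerate(fixture: Fixture) -> NestedDataset:
    """Rebuild a fixture's dataset from its manifest (determinism contract)."""
    return _generate(fixture.spec, fixture.params, fixture.seed,
                     fixture.explained_fraction)


def make_fixtures(seed: int = 0) -> Dict[str, Fixture]:
    """Small canonical datasets: noiseless designs A/B, one cell per study at
    N=10, nc=5, plus a large-N study-2a variant for moment checks and a
    covariate dataset."""
    noiseless = PopulationParams(gamma00=1.0, gamma10=2.0, var_e=1e-300)
    recipes = {
        "noiseless_a": (DesignSpec("A", 4, 5), noiseless, 0.0),
        "noiseless_b": (DesignSpec("B", 4, 5), noiseless, 0.0),
        "study_1a": (DesignSpec("B", 10, 5), resolve_params(d=0.20, icc=0.0), 0.0),
        "study_1b": (DesignSpec("B", 10, 5), resolve_params(d=0.20, icc=0.50), 0.0),
        "study_2a": (DesignSpec("B", 10, 5), resolve_params(d=0.0, icc=0.0, var_u1=0.025), 0.0),
        "study_2b": (DesignSpec("B", 10, 5), resolve_params(d=0.0, icc=0.50, var_u1=0.15), 0.0),
        "study_2a_large": (
            DesignSpec("B", 2000, 5), resolve_params(d=0.0, icc=0.0, var_u1=0.15), 0.0,
        ),
        "covariate": (
            DesignSpec("B", 50, 5), resolve_params(d=0.5, icc=0.25, var_u1=0.10), 0.64,
        ),
    }
    out: Dict[str, Fixture] = {}
    for i, (name, (spec, params, frac)) in enumerate(recipes.items()):
        fixture_seed = seed * 1000 + i
        out[name] = Fixture(
            name=name,
            dataset=_generate(spec, params, fixture_seed, frac),
            spec=spec,
            params=params,
            seed=fixture_seed,
            explained_fraction=frac,
        )
    return out
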
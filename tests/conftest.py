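"""Shared fixtures: small phantoms for unit tests and a cached standard-run
pipeline (registration + fusion + single-atlas runs) reused across tests so
each seed's registrations are computed once per session."""

from __future__ import annotations

from dataclasses import replace
from functools import lru_cache
from types import SimpleNamespace

import pytest

from likefusion.fusion import FusionConfig, register_atlases, run_fusion, single_atlas_map
from likefusion.synthetic import (
    PhantomSpec,
    PopulationSpec,
    StructureSpec,
    default_phantom_spec,
    generate_phantom,
    generate_population,
)


def mini_phantom_spec(seed: int = 0, noise_sd: float = 5.0) -> PhantomSpec:
    """32^3 three-structure phantom for fast unit tests."""
    structures = (
        StructureSpec("hippocampus", (20.0, 15.0, 15.0), (4.0, 3.0, 3.0), 65.0),
        StructureSpec("putamen", (11.0, 13.0, 16.0), (3.0, 3.0, 3.0), 78.0),
        StructureSpec("ventricle", (16.0, 20.0, 13.0), (3.0, 4.0, 3.0), 30.0),
    )
    return PhantomSpec(dims=(32, 32, 32), structures=structures,
                       noise_sd=noise_sd, seed=seed)


@lru_cache(maxsize=16)
def standard_run(seed: int) -> SimpleNamespace:
    """Standard fixture (48^3, 5 structures, 5 atlases) fully processed."""
    target, gold = generate_phantom(default_phantom_spec(seed))
    atlases = generate_population((target, gold),
                                  PopulationSpec(n_atlases=5, seed=seed + 100))
    regs = register_atlases(target, atlases)
    fusion = run_fusion(target, atlases, registrations=regs)
    return SimpleNamespace(seed=seed, target=target, gold=gold, atlases=atlases,
                           regs=regs, fusion=fusion)


@lru_cache(maxsize=16)
def standard_singles(seed: int) -> list:
    run = standard_run(seed)
    return [single_atlas_map(run.target, a, registration=run.regs[i])
            for i, a in enumerate(run.atlases)]


@lru_cache(maxsize=16)
def standard_run_no_tissue(seed: int):
    run = standard_run(seed)
    return run_fusion(run.target, run.atlases,
                      fusion_config=FusionConfig(use_tissue_charts=False),
                      registrations=run.regs)


@pytest.fixture(scope="session")
def mini_fixture():
    """Noise-bearing 32^3 phantom plus a 3-atlas population."""
    spec = mini_phantom_spec(seed=7)
    target, gold = generate_phantom(spec)
    atlases = generate_population((target, gold),
                                  PopulationSpec(n_atlases=3, amplitude=3.0, seed=17))
    return SimpleNamespace(spec=spec, target=target, gold=gold, atlases=atlases)


@pytest.fixture(scope="session")
def noise_free_mini():
    """Deterministic noise-free phantom: atlas == target self-consistency runs."""
    spec = replace(mini_phantom_spec(seed=3, noise_sd=0.0),
                   tissue_sds=(0.0, 0.0, 0.0))
    return generate_phantom(spec)
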
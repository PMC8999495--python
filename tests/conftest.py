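"""Shared fixtures: default material table and cached phantom solves.

Phantom FEM solves take ~1-2 s each, so solved models are cached per
(fracture type, implant, seed) at session scope and shared across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from xray2fem.materials import build_material_table
from xray2fem.phantom import Implant, PhantomSpec, generate_phantom
from xray2fem.pipeline import solve_radiograph
from xray2fem.stress import Region, summarize_region


@pytest.fixture(scope="session")
def default_table():
    return build_material_table()


@pytest.fixture(scope="session")
def solved_phantom_cache():
    """Memoised phantom solves: call with (ftype, implant, seed)."""
    cache = {}

    def solve(ftype: str, implant: str, seed: int = 1):
        key = (ftype, implant, seed)
        if key not in cache:
            spec = PhantomSpec(fracture_type=ftype, implant=Implant(implant), seed=seed)
            rad, mask = generate_phantom(spec)
            mesh, result, stress = solve_radiograph(rad)
            cache[key] = (spec, rad, mask, mesh, result, stress)
        return cache[key]

    return solve


@pytest.fixture(scope="session")
def gnf_a2_model(solved_phantom_cache):
    """One representative implant-bearing solved model."""
    return solved_phantom_cache("A2", "GNF", seed=1)
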
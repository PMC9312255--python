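"""Shared fixtures: material library, coarse meshes and short ablation runs.

Everything is generated programmatically; expensive simulations are
session-scoped so several tests can interrogate the same run.
"""

from __future__ import annotations

import numpy as np
import pytest

from rfasim.geometry import CatheterSpec, Resolution, ScenarioGeometry, build_geometry
from rfasim.materials import load_default_library
from rfasim.solver import EnergySetting, run_simulation


@pytest.fixture(scope="session")
def lib():
    return load_default_library()


@pytest.fixture(scope="session")
def coarse_res():
    """Fast unit-test resolution (not convergence-grade)."""
    return Resolution(h_min=0.3, h_max=5.0, h_min_3d=1.0, h_max_3d=8.0)


@pytest.fixture(scope="session")
def bh_mesh(coarse_res):
    return build_geometry(ScenarioGeometry(model="BH"), coarse_res)


@pytest.fixture(scope="session")
def tm_mesh(coarse_res):
    return build_geometry(ScenarioGeometry(model="TM"), coarse_res)


@pytest.fixture(scope="session")
def bh_short_run(coarse_res):
    """Short low-dose BH ablation: 16 W for 2 s, observed to 5 s."""
    return run_simulation(
        ScenarioGeometry(model="BH"),
        EnergySetting(20.0, 2.0, observation_time=5.0),
        resolution=coarse_res,
    )
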
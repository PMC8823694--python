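"""Shared fixtures: physics table, model, geometry, and benchmark runs.

The scaled benchmark runs (n = 500 photons, 200 Monte Carlo realizations,
1-keV lookup-table step) are expensive and session-scoped; several tests
assert different properties of the same run.
"""

import numpy as np
import pytest
from hypothesis import settings

import comptrack as ct

settings.register_profile("suite", derandomize=True, max_examples=25)
settings.load_profile("suite")

BENCH_N = 500
BENCH_SEED = 11
SIM_SEED = 101


@pytest.fixture(scope="session")
def physics():
    return ct.load_silicon()


@pytest.fixture(scope="session")
def model():
    return ct.ComptonModel()


@pytest.fixture(scope="session")
def geometry():
    return ct.DetectorGeometry()


@pytest.fixture(scope="session")
def cfg200():
    return ct.EstimatorConfig(mc_realizations=200)


@pytest.fixture(scope="session")
def lookup(geometry, physics, model):
    return ct.build_deposit_tables(
        800, 1.0, geometry, physics, model, seed=23
    )


@pytest.fixture(scope="session")
def batch10k(geometry, physics, model):
    return ct.simulate_batch(10_000, 60.0, geometry, physics, model, seed=SIM_SEED)


@pytest.fixture(scope="session")
def ideal_report(geometry, physics, model, cfg200, lookup):
    return ct.run_benchmark(
        BENCH_N, 60.0, geometry, physics, model, config=cfg200,
        methods=("ml", "alternative", "baseline"), detector_mode="ideal",
        seed=BENCH_SEED, lookup=lookup,
    )


@pytest.fixture(scope="session")
def realistic_report(geometry, physics, model, cfg200, lookup):
    return ct.run_benchmark(
        BENCH_N, 60.0, geometry, physics, model, config=cfg200,
        methods=("ml", "alternative", "baseline"), detector_mode="realistic",
        seed=BENCH_SEED, lookup=lookup,
    )
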
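"""Shared fixtures: architectures and simulated populations at several scales.

The expensive simulations are session-scoped so the acceptance tests and
the integration-level property tests share one run each.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from lodsim import (
    AlleleGrid,
    PopulationState,
    build_architecture,
    gompertz_makeham_table,
    run_simulation,
    synthetic_high_incidence,
)


@pytest.fixture(scope="session")
def default_grid() -> AlleleGrid:
    return AlleleGrid()


@pytest.fixture(scope="session")
def small_spec():
    """A 100-SNP architecture (lung-cancer-scale heritability), cheap to simulate."""
    return build_architecture(0.095)


@pytest.fixture(scope="session")
def stroke_spec():
    """The 625-SNP, h2=0.41 architecture."""
    return build_architecture(0.41)


@pytest.fixture(scope="session")
def small_sim(small_spec):
    """20k individuals, 100 SNPs, high-incidence hazard: a fast full run."""
    rng = np.random.default_rng(101)
    state = PopulationState.from_architecture(small_spec, 20_000, rng)
    trace = run_simulation(
        state, synthetic_high_incidence(), gompertz_makeham_table(), seed=rng
    )
    return state, trace, small_spec


@pytest.fixture(scope="session")
def big_sim():
    """The high-incidence (4% max yearly hazard), h2=0.55 run at 2e5 individuals.

    This is the desk-scale stand-in for the production-size runs: large
    enough that pool frequencies are stable, small enough to simulate in
    seconds.
    """
    spec = build_architecture(0.55)
    rng = np.random.default_rng(2025)
    state = PopulationState.from_architecture(spec, 200_000, rng)
    trace = run_simulation(
        state, synthetic_high_incidence(), gompertz_makeham_table(), seed=rng
    )
    return state, trace, spec


@pytest.fixture(scope="session")
def null_sim(stroke_spec):
    """PRS-blind (uniform selection weight) run: no genotype-disease link."""
    rng = np.random.default_rng(404)
    state = PopulationState.from_architecture(stroke_spec, 100_000, rng)
    trace = run_simulation(
        state,
        synthetic_high_incidence(),
        gompertz_makeham_table(),
        seed=rng,
        weight_mode="uniform",
    )
    return state, trace, stroke_spec
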
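"""Shared fixtures: cached synthetic sessions and feature matrices."""

from __future__ import annotations

import numpy as np
import pytest

from emgait import pipeline, synth


@pytest.fixture(scope="session")
def small_config() -> synth.SimulationConfig:
    """A quick session: 12 cycles per terrain, default noise."""
    return synth.SimulationConfig(n_cycles_per_terrain=12, seed=11)


@pytest.fixture(scope="session")
def small_session(small_config):
    return synth.generate_session(small_config)


@pytest.fixture(scope="session")
def feature_matrix(small_config):
    """Full 175-column feature matrix for one simulated subject."""
    return pipeline.subject_feature_matrix(small_config, subject_id="S1")


@pytest.fixture(scope="session")
def cohort_matrices():
    """Default three-virtual-subject cohort at moderate scale (20 cycles)."""
    base = synth.SimulationConfig(n_cycles_per_terrain=20, seed=5)
    return pipeline.cohort_feature_matrices(3, base, seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def random_windows():
    """50 random 100-sample windows for oracle-equivalence checks."""
    r = np.random.default_rng(2024)
    return [r.standard_normal(100) for _ in range(50)]
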
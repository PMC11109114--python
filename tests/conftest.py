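import numpy as np
import pytest
from hypothesis import settings

from microdose import ScreeningConfig, ScSimConfig, build_distribution, simulate_sc_experiment

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def gamma_f1():
    """Single-event-like spectrum: gamma(2, 1) draws binned at width 0.25."""
    draws = np.random.default_rng(12345).gamma(2.0, 1.0, 100_000)
    return build_distribution(draws, bin_width=0.25, label="gamma(2,1) f1")


@pytest.fixture(scope="session")
def planted_experiment():
    """Small multi-group experiment with planted signal genes (shared)."""
    cfg = ScSimConfig(
        n_genes=400,
        n_cells_per_group=300,
        class_counts={"A": 50, "B": 50, "D": 30, "E": 20, "AD": 30},
        seed=2024,
    )
    groups, truth = simulate_sc_experiment(cfg)
    return cfg, groups, truth


@pytest.fixture(scope="session")
def planted_control(planted_experiment):
    return planted_experiment[1][0]


@pytest.fixture(scope="session")
def planted_groups(planted_experiment):
    return {g.dose_mGy: g for g in planted_experiment[1][1:]}
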
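import numpy as np
import pytest

from homoeoexpress.simulate import (SimulationConfig, simulate_expression,
                                    simulate_reference)


@pytest.fixture
def small_config():
    return SimulationConfig(n_anchor_pairs=50, n_modules=0, module_sizes=(),
                            module_trait_effect=(), seed=11)


@pytest.fixture
def small_panel(small_config):
    return simulate_reference(small_config)


@pytest.fixture
def module_config():
    """The planted-module regime: 3 modules, one trait-driven, 3+3 samples."""
    return SimulationConfig(n_anchor_pairs=100, seed=7)


@pytest.fixture
def module_data(module_config):
    panel = simulate_reference(module_config)
    expr, groups, truth = simulate_expression(panel, module_config)
    trait = (groups == "cave").astype(float)
    return expr, groups, trait, truth


@pytest.fixture
def rng():
    return np.random.default_rng(123)
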
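import numpy as np
import pytest

from intersim import (BetaConfig, ExperimentConfig, ParameterGrid,
                      PopulationSpec, draw_sample, generate_population)


@pytest.fixture(scope="session")
def default_grid():
    return ParameterGrid()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def table2_spec():
    """The worked-example configuration: beta=(0,1,1,-1), r~0, lambda=0.65."""
    return PopulationSpec(betas=BetaConfig(0.0, 1.0, 1.0, -1.0),
                          correlation=0.0001, noise_level=0.65,
                          size=100_000, cell_id="demo")


@pytest.fixture(scope="session")
def table2_population(table2_spec):
    return generate_population(table2_spec, seed=11)


@pytest.fixture
def sample_factory(table2_population):
    def make(n=100, seed=0, replicate_index=0):
        return draw_sample(table2_population, n, seed,
                           replicate_index=replicate_index)
    return make


@pytest.fixture
def tiny_grid():
    return ParameterGrid(noise_levels=(0.65,), correlations=(0.0001,),
                         beta1_values=(1.0,), beta2_values=(1.0,),
                         beta3_values=(-1.0,))


@pytest.fixture
def tiny_config(tiny_grid):
    return ExperimentConfig(grid=tiny_grid, population_size=2000, reps=5,
                            sample_sizes=(25, 100), master_seed=3)
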
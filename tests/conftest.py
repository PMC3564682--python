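import numpy as np
import pytest

from parscope.simulate import (
    SimulationConfig,
    annotate_from_truth,
    generate_truth,
    simulate_arrays,
)
from parscope.tiling import CloneInterval, FishStatus, TilingPath, annotate


@pytest.fixture
def boundary_flanking_path():
    """Two FISH-typed BACs flanking the pig pseudoautosomal boundary:
    an XY-homologous clone ending at 6.50 Mb and an X-only clone starting
    at 6.91 Mb (Sscrofa10.2 coordinates)."""
    path = TilingPath(
        "X",
        [
            CloneInterval("CH242-236H7", "X", 6_330_000, 6_500_000),
            CloneInterval("CH242-156O11", "X", 6_910_000, 7_080_000),
        ],
    )
    return annotate(path, [FishStatus.XY_HOMOLOGOUS, FishStatus.X_ONLY])


@pytest.fixture
def noise_free_config():
    return SimulationConfig(
        n_clones=200,
        spot_noise_sd=0.0,
        block_bias_sd=0.0,
        dropout_rate=0.0,
        seed=7,
    )


@pytest.fixture
def noise_free_run(noise_free_config):
    path, truth = generate_truth(noise_free_config)
    tables = simulate_arrays(path, truth, noise_free_config)
    return path, truth, tables, noise_free_config


@pytest.fixture
def default_run():
    cfg = SimulationConfig(seed=11)
    path, truth = generate_truth(cfg)
    tables = simulate_arrays(path, truth, cfg)
    return path, truth, tables, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
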
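import numpy as np
import pytest

from graincast.model import ModelConfig
from graincast.synth import KineticsConfig, generate_design, simulate_quality

ZERO_NOISE = {
    "germination_pct": 0.0,
    "fatty_acid_mg100g": 0.0,
    "bulk_density_gL": 0.0,
}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_panel():
    """Noisy 2x2x7x3 factorial panel (84 records)."""
    skeleton = generate_design(
        moistures=(12.5, 14.0),
        temperatures=(15.0, 30.0),
        time_nodes=range(0, 181, 30),
        replicates=3,
    )
    return simulate_quality(skeleton, KineticsConfig(), seed=7)


@pytest.fixture(scope="session")
def dense_clean_panel():
    """Zero-noise 3x3 condition grid with a dense time axis (for training)."""
    skeleton = generate_design(
        moistures=(12.5, 13.25, 14.0),
        temperatures=(15.0, 22.5, 30.0),
        time_nodes=range(0, 181, 6),
        replicates=1,
    )
    kin = KineticsConfig(noise_sd=dict(ZERO_NOISE))
    return simulate_quality(skeleton, kin, seed=7)


@pytest.fixture
def tiny_model_config():
    return ModelConfig(d_model=8, n_heads=2, d_ff=16, gcn_layers=2,
                       epochs=2, seed=0)
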
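import numpy as np
import pytest

from anodpore import dataset_io, synthetic_data


@pytest.fixture(scope="session")
def default_dataset():
    """99-record synthetic compilation with missingness, default calibration."""
    cfg = synthetic_data.GeneratorConfig()
    return synthetic_data.inject_missingness(synthetic_data.generate(cfg))


@pytest.fixture(scope="session")
def noise_free_config():
    """Exactly linear generator (no noise, no missingness, equal V slopes)."""
    return synthetic_data.GeneratorConfig(
        n_records=120,
        noise_sd=0.0,
        interpore_noise_sd=0.0,
        missing_rate_T=0.0,
        missing_rate_t=0.0,
        voltage_slope={"H2SO4": 1.2, "H2C2O4": 1.2, "H3PO4": 1.2},
        intercept={"H2SO4": 20.0, "H2C2O4": 40.0, "H3PO4": 60.0},
        voltage_range={"H2SO4": (15, 30), "H2C2O4": (30, 80),
                       "H3PO4": (80, 150)},
        time_range=(10.0, 600.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def noise_free_dataset(noise_free_config):
    return synthetic_data.generate(noise_free_config)


@pytest.fixture(scope="session")
def noise_free_fm(noise_free_dataset):
    return dataset_io.encode(noise_free_dataset.frame, mode="onehot")
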
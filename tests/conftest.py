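import numpy as np
import pytest

from nirsvft.config import SimulationConfig, WaveformConfig
from nirsvft.synthgen import generate_study


def make_config(**overrides) -> SimulationConfig:
    cfg = SimulationConfig()
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced cohort for fast pipeline-level tests."""
    return make_config(
        group_sizes={"SCZ": 6, "MDD": 4, "BIP": 4, "HC": 8},
        fh_fraction={"SCZ": 0.5, "MDD": 0.5, "BIP": 0.5, "HC": 0.0},
        sampling_interval_s=0.5,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


def clean_config(**overrides) -> SimulationConfig:
    """Deterministic noise-free generator: signals equal the kernel."""
    base = dict(
        noise_sd=0.0,
        amplitude_sd=0.0,
        latency_sd_s=0.0,
        artifact_channel_rate=0.0,
        seed=0,
    )
    base.update(overrides)
    return make_config(**base)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250926)


@pytest.fixture
def pre_baseline_wf() -> WaveformConfig:
    return WaveformConfig(baseline_mode="pre")
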
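import numpy as np
import pytest

from cpclock import OscillatorBank, SRNConfig


@pytest.fixture(scope="session")
def bank() -> OscillatorBank:
    return OscillatorBank()


@pytest.fixture(scope="session")
def quick_config() -> SRNConfig:
    """Small but non-trivial training configuration for fast tests."""
    return SRNConfig(
        hidden_size=16,
        epochs=20,
        fahlman_offset=0.06,
        attention_horizon_ms=1024,
        eval_horizon_ms=4096,
        seed=123,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
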
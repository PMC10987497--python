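"""Shared fixtures: a small default generator config and a step protocol."""

import numpy as np
import pytest

from circatemp.calcium import TemperatureProtocol
from circatemp.synth import SynthConfig


@pytest.fixture
def config() -> SynthConfig:
    return SynthConfig(master_seed=7)


@pytest.fixture
def heating_protocol() -> TemperatureProtocol:
    """22 → 30 °C step ramped over 80 s, 240-s recording."""
    return TemperatureProtocol(
        baseline_c=22.0, steps=[(60.0, 30.0, 80.0)], recording_span_s=240.0
    )


@pytest.fixture
def cooling_protocol() -> TemperatureProtocol:
    """24 → 18 °C step ramped over 80 s, 240-s recording."""
    return TemperatureProtocol(
        baseline_c=24.0, steps=[(60.0, 18.0, 80.0)], recording_span_s=240.0
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
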
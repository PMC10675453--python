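"""Shared fixtures: full-scale and reduced-scale synthetic material.

Reduced-scale fixtures (64 Hz, short records, 64/128-sample windows) keep the
suite fast while exercising the identical code paths as the 500 Hz / 2048
default configuration.
"""

import numpy as np
import pytest

from cowave.model import ModelConfig, TrainConfig
from cowave.preprocessing import normalize_segment, segment_record
from cowave.qc import screen_dataset
from cowave.synthetic import SimConfig, generate_case, generate_dataset


@pytest.fixture(scope="session")
def default_record():
    """One clean case at the full 500 Hz / 60 s study conditions."""
    return generate_case(SimConfig(seed=1))


@pytest.fixture(scope="session")
def tiny_sim():
    """Reduced-scale simulation conditions (64 Hz) for fast training tests."""
    return SimConfig(sampling_rate=64.0, duration=12.0, co_interval=2.0, seed=0)


@pytest.fixture(scope="session")
def tiny_model_config():
    return ModelConfig(
        input_length=64,
        depth=2,
        base_filters=4,
        bottleneck_lstm_units=8,
        head_lstm_units=8,
        seed=0,
    )


@pytest.fixture(scope="session")
def tiny_segments(tiny_sim):
    """32 clean, screened, normalized 64-sample segments from 6 tiny cases."""
    records = generate_dataset(tiny_sim, 6, seed=5)
    segments = []
    for rec in records:
        segments.extend(segment_record(rec, window=64))
    kept, _ = screen_dataset(segments)
    return [normalize_segment(s) for s in kept][:32]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
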
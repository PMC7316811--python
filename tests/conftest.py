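import numpy as np
import pytest

from ihcsync.syncytium_sim import SinusoidStimulus, SyncytiumConfig


@pytest.fixture
def fast_cfg() -> SyncytiumConfig:
    """Short-duration syncytium configuration for unit tests."""
    return SyncytiumConfig(
        seed=42,
        stimulus=SinusoidStimulus(duration_ms=30.0, onset_discard_ms=5.0),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
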
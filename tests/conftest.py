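import numpy as np
import pytest

from vasckit import SynthSpec, generate_frap_stack


@pytest.fixture(scope="session")
def frap_stack_13():
    """Noise-free FRAP stack at D = 13.2 µm²/s (70 kDa dextran regime)."""
    spec = SynthSpec(
        kind="frap",
        seed=7,
        shape=(96, 96),
        frame_interval=0.25,
        params={"D_true": 13.2, "roi_radius": 10.0, "bleach_depth": 0.9},
    )
    return generate_frap_stack(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
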
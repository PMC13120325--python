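import numpy as np
import pytest

from nirunet import PhantomParams, generate_glyph, tissue_forward


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def glyph96():
    return generate_glyph("stroke-digit", 96, np.random.default_rng(7))


@pytest.fixture
def small_pairs():
    """Eight 64x64 (target, captured) pairs under default phantom physics."""
    params = PhantomParams()
    targets, captured = [], []
    for i in range(8):
        g = generate_glyph("stroke-digit", 64, np.random.default_rng(50 + i))
        targets.append(g)
        captured.append(tissue_forward(g, params, np.random.default_rng(950 + i)))
    return (np.stack(targets).astype(np.float32),
            np.stack(captured).astype(np.float32))
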
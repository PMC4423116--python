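import numpy as np
import pytest

from paddleclamp import synthdata as sd


@pytest.fixture
def toy_complex():
    """Default helix (chain A) + nearby, non-clashing toxin ball (chain B)."""
    return sd.gen_toy_complex(sd.ToyComplexSpec())


@pytest.fixture
def far_complex():
    """Helix and toxin far beyond SASA occlusion range."""
    return sd.gen_toy_complex(sd.ToyComplexSpec(placement_offset=(30.0, 0.0, 0.0)))


@pytest.fixture
def contact_complex():
    """Toy complex with the toxin ball pressed against the helix."""
    return sd.gen_toy_complex(
        sd.ToyComplexSpec(placement_offset=(5.2, 0.0, 0.0))
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
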
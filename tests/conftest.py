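import numpy as np
import pytest

from srfam.synthetic import SyntheticSpec, generate_proteome


@pytest.fixture(scope="session")
def proteome_bundle():
    """A clear-margin synthetic proteome: 6 per subfamily plus 5 decoys."""
    return generate_proteome(SyntheticSpec(seed=101))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
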
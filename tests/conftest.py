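import numpy as np
import pytest

from sisca.simulate import CommunitySpec, NoiseModel, simulate_community


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Archetype panel (4 MAGs, 12 peptides each) with no spectral noise."""
    spec = CommunitySpec.archetype_panel(
        mags_per_archetype=1,
        n_peptides=12,
        noise=NoiseModel.noiseless(),
        seed=11,
    )
    return simulate_community(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
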
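import numpy as np
import pytest

from neurolsm import (
    AudioGenConfig,
    BoldGenConfig,
    RegionalBoldMatrix,
    gen_audio_dataset,
    gen_bold,
    gen_toy_fixtures,
)


@pytest.fixture(scope="session")
def fixtures():
    return gen_toy_fixtures()


@pytest.fixture(scope="session")
def bold_small():
    """Small synthetic BOLD matrix (5 regions x 10 samples)."""
    rng = np.random.default_rng(11)
    return RegionalBoldMatrix(
        values=rng.standard_normal((5, 10)),
        region_labels=[f"r{i}" for i in range(5)],
        sampling_interval=1.5,
    )


@pytest.fixture(scope="session")
def bold_subjects():
    return gen_bold(BoldGenConfig(n_subjects=3, seed=101))


@pytest.fixture(scope="session")
def audio_small():
    """Tiny audio dataset: 10 classes x 3 utterances."""
    return gen_audio_dataset(AudioGenConfig(per_class=3, seed=202))
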
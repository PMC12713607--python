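import numpy as np
import pytest

from nusched import SamplingSchedule


@pytest.fixture
def random_mask_factory():
    """Seeded random 0/1 masks with a given sample count."""

    def make(N: int, n: int, seed: int) -> SamplingSchedule:
        rng = np.random.default_rng(seed)
        idx = rng.choice(N, size=n, replace=False)
        return SamplingSchedule.from_indices(np.sort(idx), N)

    return make
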
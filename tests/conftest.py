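import numpy as np
import pytest

from tractprf import prf, synthetic_data


@pytest.fixture(scope="session")
def small_movie():
    """Compact bar movie used where fit accuracy is not the point."""
    return synthetic_data.make_aperture_movie("bar", 96, 32, 16.0)


@pytest.fixture(scope="session")
def canonical():
    return prf.canonical_hrf()


@pytest.fixture(scope="session")
def toy_anatomy_clean():
    return synthetic_data.make_toy_anatomy(
        n_streamlines_per_subfield=10, jitter_mm=0.0, seed=7
    )


@pytest.fixture(scope="session")
def small_bank(small_movie, canonical):
    grid = prf.GridSpec(
        ecc_values=np.geomspace(0.5, 7.0, 5),
        angle_values=np.linspace(0, 360, 8, endpoint=False),
        size_values=np.geomspace(0.5, 3.0, 3),
    )
    return prf.CandidateBank(small_movie, canonical, grid)
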
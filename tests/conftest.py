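import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from glomclass.synthesis import SynthesisParams, generate_dataset, generate_glomerulus
from glomclass.image_io import NON_SCLEROTIC, SCLEROTIC


@pytest.fixture(scope="session")
def fast_params() -> SynthesisParams:
    """Small, quick synthesis conditions for unit tests."""
    return SynthesisParams(
        image_size=64,
        glomerulus_radius_range=(14, 19),
        n_biopsies=4,
        glomeruli_per_biopsy=8,
        seed=7,
    )


@pytest.fixture(scope="session")
def fast_dataset(fast_params):
    return generate_dataset(fast_params)


@pytest.fixture(scope="session")
def one_crop_each(fast_params):
    """One non-sclerotic and one sclerotic crop at the fast conditions."""
    rng = np.random.default_rng(3)
    return (
        generate_glomerulus(NON_SCLEROTIC, fast_params, rng),
        generate_glomerulus(SCLEROTIC, fast_params, rng),
    )
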
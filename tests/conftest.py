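import numpy as np
import pytest

from cpgfuse.synthetic import (POOR, RICH, SyntheticConfig, block_coefficients)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_planted_config():
    """8 TFs, 10 bins: TF0 shared (+), TF1 poor-only (-), TF2 rich-only (+)."""
    k = 10
    planted = {
        POOR: [{0: block_coefficients(k, 0, 5, 2.0),
                1: block_coefficients(k, 0, 10, -1.5)}],
        RICH: [{0: block_coefficients(k, 0, 5, 2.0),
                2: block_coefficients(k, 3, 8, 1.8)}],
    }
    return SyntheticConfig(n_genes=400, n_tfs=8, n_bins=k, planted=planted,
                           noise_sd=0.2, seed=7)
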
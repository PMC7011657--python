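import warnings

import numpy as np
import pandas as pd
import pytest

from statefish.codebook import build_codebook

warnings.filterwarnings("ignore", message="bit .*all zero")


@pytest.fixture(scope="session")
def codebook16():
    """Small 16-bit weight-4 MHD4 codebook (fast to build and verify)."""
    return build_codebook(n_bits=16, weight=4, min_distance=4, n_genes=80, n_blanks=40, seed=0)


@pytest.fixture(scope="session")
def codebook24():
    """Study-scale 24-bit codebook: 150 genes + 144 blanks."""
    return build_codebook(n_bits=24, weight=4, min_distance=4, n_genes=150, n_blanks=144, seed=0)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest Poisson-mode synthetic dataset shared across tests."""
    from statefish.simulate import (
        default_gene_models,
        generate_cell_states,
        generate_expression,
    )

    states = generate_cell_states(1500, seed=11)
    models = default_gene_models(60, seed=21, mode="poisson")
    return generate_expression(states, models, seed=31)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
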
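import warnings

import numpy as np
import pytest

from alscreen.chem_core import ensure_fingerprint
from alscreen.synth_library import LibraryConfig, OracleParams, generate_library, score_tier1_batch


@pytest.fixture(scope="session")
def small_library():
    """2,000 molecules with fingerprints — cheap shared fixture."""
    config = LibraryConfig(n_molecules=2000, seed=11)
    records = generate_library(config)
    for rec in records:
        ensure_fingerprint(rec)
    return config, records


@pytest.fixture(scope="session")
def small_params(small_library):
    config, _ = small_library
    return OracleParams(seed=11, library_config=config)


@pytest.fixture(scope="session")
def mid_library():
    """11,000 molecules for learnability/correlation checks (no fingerprints)."""
    config = LibraryConfig(n_molecules=11_000, seed=7)
    return config, generate_library(config)


@pytest.fixture(scope="session")
def trained_surrogate(mid_library):
    """A ridge surrogate trained on 2,000 tier-1-scored molecules."""
    from alscreen.surrogate import SurrogateConfig, train_surrogate

    config, records = mid_library
    params = OracleParams(seed=7, library_config=config)
    subset = records[:2000]
    scores = score_tier1_batch(subset, params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = train_surrogate(subset, scores, SurrogateConfig(seed=3))
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
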
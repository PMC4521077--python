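import numpy as np
import pytest

import tempmort as tm


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def small_dataset():
    """8 locations x 3 years with the default known surface (session-cached)."""
    cfg = tm.default_scenario(n_locations=8, years=3, seed=42, n_countries=2)
    return tm.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_result(small_dataset):
    settings = tm.AnalysisSettings(n_sim=200, seed=7)
    return tm.analyze_dataset(small_dataset.series, small_dataset.metadata, settings)
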
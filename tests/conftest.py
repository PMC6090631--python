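import numpy as np
import pandas as pd
import pytest

from genepulse.histories import PublicationHistories
from genepulse.ratemodel import HUMAN_ML_PARAMS
from genepulse.simulate import SimulationConfig, simulate_histories


@pytest.fixture(scope="session")
def small_histories() -> PublicationHistories:
    """Deterministic 6-gene toy history, 2000-2009."""
    years = list(range(2000, 2010))
    counts = pd.DataFrame(
        [
            [0, 0, 0, 0, 0, 0, 0, 0, 0, 0],   # never studied
            [1, 1, 1, 1, 1, 1, 1, 1, 1, 1],   # steady
            [0, 2, 0, 1, 0, 3, 0, 0, 1, 0],   # sporadic
            [5, 5, 5, 5, 5, 5, 5, 5, 5, 5],   # heavily studied
            [0, 0, 0, 0, 10, 10, 10, 0, 0, 0],  # burst in 2004-2006
            [1, 0, 1, 0, 1, 0, 1, 0, 1, 0],   # alternating
        ],
        index=pd.Index([1, 2, 3, 4, 5, 6], name="gene_id"),
        columns=years,
    )
    baseline = pd.Series([0, 2, 0, 10, 0, 0], index=counts.index)
    return PublicationHistories(counts, baseline)


@pytest.fixture(scope="session")
def simulated_histories() -> PublicationHistories:
    """Medium simulation from the published parameter values (pure model)."""
    cfg = SimulationConfig(
        n_genes=800, year_range=(1950, 2015), params=HUMAN_ML_PARAMS, seed=42
    )
    return simulate_histories(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
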
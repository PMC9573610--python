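import numpy as np
import pandas as pd
import pytest

from peaheat import simdata


@pytest.fixture(scope="session")
def two_pop_metadata() -> pd.DataFrame:
    """120-accession panel with two planted subpopulations and tolerance classes."""
    n = 120
    return pd.DataFrame(
        {
            "accession": [f"G{i:03d}" for i in range(n)],
            "subpopulation": ["P1"] * (n // 2) + ["P2"] * (n // 2),
            "latent_class": (["HT", "HS"] * n)[:n],
        }
    )


@pytest.fixture(scope="session")
def small_genotypes(two_pop_metadata):
    cfg = simdata.GenotypeSimConfig(
        n_markers_neutral=20, n_markers_ht=8, fst=0.2, seed=42, missing_rate=0.05
    )
    return simdata.simulate_genotypes(two_pop_metadata, cfg)


@pytest.fixture(scope="session")
def constant_series():
    dates = np.datetime64("2018-03-01") + np.arange(153).astype("timedelta64[D]")
    return simdata.TemperatureSeries("const", dates, np.full(153, 20.0))
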
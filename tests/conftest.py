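import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import hemkit as hk

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config() -> hk.PopulationConfig:
    """A scaled-down repeated cross-section: 6 years x 3000 children."""
    return hk.PopulationConfig(
        years=tuple(range(1997, 2003)), n_per_year=3000, n_imputations=3, seed=42
    )


@pytest.fixture(scope="session")
def small_coded(small_config) -> pd.DataFrame:
    return hk.code_dataframe(hk.generate_population(small_config))


def make_design_frame(values, weights=None, year=2000, **cols) -> pd.DataFrame:
    """One-year microdata frame with each record its own PSU in one stratum."""
    n = len(values)
    df = pd.DataFrame(
        {
            "year": year,
            "weight": weights if weights is not None else [1.0] * n,
            "stratum": 0,
            "psu": range(n),
            "general_health": values,
        }
    )
    for name, vals in cols.items():
        df[name] = vals
    return df
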
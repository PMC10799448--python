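import numpy as np
import pandas as pd
import pytest

from bivpois import ModelSpec, CovariateSpec, default_scenario, fit, simulate


@pytest.fixture(scope="session")
def default_records():
    """One seeded draw from the default DHS-like scenario."""
    cfg = default_scenario(n_records=4000, seed=11)
    return cfg, simulate(cfg)


@pytest.fixture(scope="session")
def default_fit(default_records):
    cfg, records = default_records
    spec = cfg.model_spec()
    result = fit(records, spec)
    return cfg, records, result


@pytest.fixture
def tiny_spec():
    return ModelSpec(
        outcome1="schooling_years",
        outcome2="children_ever_born",
        covariates=[CovariateSpec("residence", "categorical", reference="urban")],
    )


@pytest.fixture
def tiny_records():
    return pd.DataFrame(
        {
            "record_id": [0, 1, 2, 3],
            "schooling_years": [4, 0, 9, 2],
            "children_ever_born": [1, 3, 0, 2],
            "residence": ["urban", "rural", "urban", "rural"],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
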
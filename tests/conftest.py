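import numpy as np
import pandas as pd
import pytest

from icefalcon import ScenarioConfig, TwinPairDataset, preset_scenarios


def make_dataset(rows, traits=("x", "y"), covariates=("age", "height")):
    """Build a TwinPairDataset from (pair_id, twin, zyg, dict-of-values) rows."""
    recs = []
    for pair_id, twin, zyg, values in rows:
        rec = {"pair_id": pair_id, "twin_index": twin, "zygosity": zyg}
        rec.update(values)
        recs.append(rec)
    df = pd.DataFrame(recs)
    for v in (*traits, *covariates):
        if v not in df.columns:
            df[v] = 0.0
    return TwinPairDataset(df, trait_names=traits, covariate_names=covariates)


@pytest.fixture
def two_pair_dataset():
    return make_dataset(
        [
            ("p1", 1, "MZ", {"x": 1.0, "y": 2.0, "age": 50.0, "height": 160.0}),
            ("p1", 2, "MZ", {"x": 1.5, "y": 2.5, "age": 50.0, "height": 161.0}),
            ("p2", 1, "DZ", {"x": -1.0, "y": 0.5, "age": 44.0, "height": 170.0}),
            ("p2", 2, "DZ", {"x": 0.5, "y": 1.0, "age": 44.0, "height": 168.0}),
        ]
    )


@pytest.fixture(scope="session")
def cohort_scenarios():
    """Preset scenario suite at the motivating cohort's 98 MZ / 54 DZ size."""
    return preset_scenarios()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20200730)
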
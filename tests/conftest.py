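import numpy as np
import pandas as pd
import pytest

from eradiff import feature_table as ft
from eradiff import synthetic_cohort as sc


@pytest.fixture()
def toy_table() -> ft.CountTable:
    counts = pd.DataFrame(
        [[10, 20, 30, 40], [5, 5, 5, 5], [100, 0, 50, 25]],
        index=["s1", "s2", "s3"],
        columns=["g__a", "g__b", "f__c", "o__d"],
    )
    counts.index.name = "sample_id"
    metadata = pd.DataFrame(
        {
            "patient_id": ["p1", "p1", "p2"],
            "era": ["pre", "pre", "covid"],
            "admission_day": [-1, -1, 0],
            "collection_day": [3, 7, 5],
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    return ft.CountTable(counts=counts, metadata=metadata)


def make_cohort(seed=1, planted=True, **overrides):
    defaults = dict(
        n_patients_pre=15,
        n_patients_covid=15,
        patient_sd_clr=0.5,
        seed=seed,
    )
    if planted:
        defaults.update(effect_taxa=(0, 1, 2, 3), effect_size_clr=(3.0, 3.0, -3.0, -3.0))
    defaults.update(overrides)
    return sc.CohortConfig(**defaults)


@pytest.fixture(scope="session")
def planted_cohort():
    config = make_cohort(seed=11)
    table, exposures, truth = sc.simulate_cohort(config)
    return table, exposures, truth


@pytest.fixture(scope="session")
def null_cohort():
    config = make_cohort(seed=12, planted=False)
    table, exposures, truth = sc.simulate_cohort(config)
    return table, exposures, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
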
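import warnings

import pandas as pd
import pytest
from hypothesis import settings

from mutualinet.core_data import sqrt_transform
from mutualinet.synthetic_data import ScenarioConfig, simulate_dataset

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def small_dataset():
    """A compact three-mutualism dataset shared across read-only tests."""
    cfg = ScenarioConfig(
        seed=101,
        mutualisms={"bird-fruit": 12, "bird-flower": 10, "insect-flower": 10},
        n_sites_total=18,
        n_plants=25,
        n_animals=25,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def transformed(small_dataset):
    plants, animals, interactions, covariates, truth = small_dataset
    return sqrt_transform(plants), sqrt_transform(animals), interactions, covariates


@pytest.fixture()
def toy_records():
    """Two plants x two animals at two sites, three observed pairs."""
    return pd.DataFrame(
        {
            "site_id": ["s1", "s1", "s2", "s2"],
            "mutualism": ["bird-fruit"] * 4,
            "plant_id": ["p1", "p2", "p1", "p1"],
            "animal_id": ["a1", "a1", "a2", "a1"],
            "count": [3, 2, 4, 5],
        }
    )


def random_rlq_instance(rng, m, n, p=3, a=3):
    """Random complete RLQ problem with no zero-degree species."""
    while True:
        L = (rng.random((m, n)) < 0.45).astype(int)
        if (L.sum(axis=1) > 0).all() and (L.sum(axis=0) > 0).all():
            break
    Ldf = pd.DataFrame(
        L, index=[f"p{i}" for i in range(m)], columns=[f"a{j}" for j in range(n)]
    )
    R = pd.DataFrame(
        rng.normal(size=(m, p)), index=Ldf.index, columns=[f"rt{k}" for k in range(p)]
    )
    Q = pd.DataFrame(
        rng.normal(size=(n, a)), index=Ldf.columns, columns=[f"qt{k}" for k in range(a)]
    )
    return R, Ldf, Q
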
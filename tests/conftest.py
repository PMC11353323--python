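import numpy as np
import pandas as pd
import pytest

from mmhurdle import GeneratorConfig, generate


@pytest.fixture(scope="session")
def small_dataset():
    """A small but structurally complete synthetic register."""
    return generate(GeneratorConfig(n_individuals=800), seed=42)


@pytest.fixture(scope="session")
def medium_dataset():
    """Large enough for stable model fits; shared across model tests."""
    return generate(GeneratorConfig(n_individuals=3000), seed=7)


@pytest.fixture()
def tiny_visits():
    return pd.DataFrame(
        {
            "individual_id": ["a", "b", "b", "c", "c", "c"],
            "hcp_id": ["h1", "h1", "h2", "h1", "h2", "h3"],
            "care_units": [5.0, 3.0, 3.0, 2.0, 1.0, 1.0],
        }
    )


@pytest.fixture()
def tiny_hcps():
    return pd.DataFrame(
        {
            "hcp_id": ["h1", "h2", "h3"],
            "hcp_type": ["GP", "community", "hospital_department"],
            "municipality_id": ["G", "V", "G"],
            "beds": [10.0, 30.0, 50.0],
        }
    )


def random_membership(rng: np.random.Generator, n_ind: int, n_hcp: int, max_k: int = 6):
    """Random visits table: each individual attends 1..max_k providers."""
    rows = []
    for i in range(n_ind):
        k = rng.integers(1, max_k + 1)
        hcps = rng.choice(n_hcp, size=k, replace=False)
        for h in hcps:
            rows.append((f"i{i}", f"h{h}", float(rng.integers(1, 20))))
    return pd.DataFrame(rows, columns=["individual_id", "hcp_id", "care_units"])
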
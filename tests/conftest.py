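import numpy as np
import pandas as pd
import pytest

from divstab.diversity import TraitTable, TraitType


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def two_species_matrix():
    """Hand-checkable 3-year, 2-species abundance matrix."""
    return pd.DataFrame({"A": [2.0, 2.0, 2.0], "B": [1.0, 3.0, 5.0]})


@pytest.fixture
def mixed_traits():
    """Six species with numeric, ordinal and nominal traits."""
    data = pd.DataFrame(
        {
            "body_mass": [1.0, 2.0, 4.0, 8.0, 16.0, 32.0],
            "generation_length": [0.5, 0.9, 1.5, 2.5, 4.0, 7.0],
            "voltinism": ["uni", "uni", "bi", "bi", "multi", "multi"],
            "overwintering": ["egg", "larva", "pupa", "adult", "egg", "larva"],
        },
        index=pd.Index([f"sp{i}" for i in range(1, 7)], name="species_id"),
    )
    schema = {
        "body_mass": TraitType("numeric"),
        "generation_length": TraitType("numeric"),
        "voltinism": TraitType("ordinal", levels=("uni", "bi", "multi")),
        "overwintering": TraitType("nominal"),
    }
    return TraitTable(data, schema)


def random_trait_table(rng, n_species):
    """Random mixed-type trait table for oracle-equivalence checks."""
    idx = pd.Index([f"sp{i}" for i in range(n_species)], name="species_id")
    data = pd.DataFrame(
        {
            "num1": rng.normal(size=n_species),
            "num2": rng.exponential(size=n_species),
            "ord1": rng.choice(["low", "mid", "high"], size=n_species),
            "nom1": rng.choice(["a", "b", "c"], size=n_species),
        },
        index=idx,
    )
    schema = {
        "num1": TraitType("numeric"),
        "num2": TraitType("numeric"),
        "ord1": TraitType("ordinal", levels=("low", "mid", "high")),
        "nom1": TraitType("nominal"),
    }
    return TraitTable(data, schema)
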
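import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from diatomring import (
    AbundanceTable,
    TraitTable,
    make_reference_communities,
    study_manifest,
    synthetic_traits,
)


@pytest.fixture(scope="session")
def communities():
    """Default reference communities (R, L, M, W) at a fixed seed."""
    return make_reference_communities(seed=7)


@pytest.fixture(scope="session")
def taxa(communities):
    return sorted(set().union(*(p.index for p in communities.values())))


@pytest.fixture(scope="session")
def traits(taxa):
    return synthetic_traits(taxa, seed=11)


@pytest.fixture(scope="session")
def manifest():
    return study_manifest()


@pytest.fixture
def small_counts():
    """A 5-taxon x 4-sample count table on valid manifest keys."""
    rng = np.random.default_rng(3)
    cols = ["E1/A/R/1", "E1/A/L/1", "E1/B/R/1", "E1/B/L/1"]
    df = pd.DataFrame(
        rng.integers(0, 500, size=(5, 4)),
        index=[f"t{i}" for i in range(5)],
        columns=cols,
    )
    return AbundanceTable(df, mode="counts")


@pytest.fixture
def simple_traits():
    """Three taxa spanning the sensitivity scale, no profiles."""
    return TraitTable(
        s=pd.Series([5.0, 3.0, 1.0], index=["a", "b", "c"]),
        v=pd.Series([1, 2, 3], index=["a", "b", "c"]),
    )
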
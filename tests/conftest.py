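import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rhizomics import synthetic as syn
from rhizomics.containers import CommunityMatrix

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_design():
    return syn.StudyDesign(
        n_treatments=2, n_replicates=2, n_taxa=80, depth_mean=800, seed=11
    )


@pytest.fixture(scope="session")
def small_truth(small_design):
    return syn.default_truth(small_design)


@pytest.fixture(scope="session")
def small_communities(small_design, small_truth):
    return syn.generate_communities(small_design, small_truth)


@pytest.fixture(scope="session")
def small_tree(small_design):
    return syn.generate_phylogeny(small_design.n_taxa, small_design.seed)


@pytest.fixture()
def random_matrix():
    rng = np.random.default_rng(3)
    counts = rng.poisson(8.0, size=(15, 40)) + rng.integers(0, 2, size=(15, 40))
    counts[counts.sum(axis=1) == 0, 0] = 1
    return CommunityMatrix(
        counts=pd.DataFrame(
            counts,
            index=[f"s{i:02d}" for i in range(15)],
            columns=[f"t{j:02d}" for j in range(40)],
        )
    )
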
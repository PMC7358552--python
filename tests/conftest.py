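import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

import metahab as mh


@pytest.fixture
def rng():
    return np.random.default_rng(20170613)


@pytest.fixture
def tiny_table():
    """3 samples x 4 OTUs, hand-checkable."""
    counts = np.array(
        [
            [6, 2, 0, 0],
            [2, 2, 0, 0],
            [0, 0, 5, 5],
        ]
    )
    return mh.OtuTable(["s1", "s2", "s3"], ["o1", "o2", "o3", "o4"], counts)


@pytest.fixture
def four_tip_tree():
    return TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1);"])


def random_table(rng, n_samples=8, n_otus=20, depth=500):
    """Random multinomial table with heterogeneous profiles."""
    counts = np.vstack(
        [rng.multinomial(depth, rng.dirichlet(np.full(n_otus, 0.5))) for _ in range(n_samples)]
    )
    return mh.OtuTable(
        [f"s{i}" for i in range(n_samples)], [f"o{j}" for j in range(n_otus)], counts
    )


def habitat_meta(sample_ids, habitats, weights=None, site="S1", month="June"):
    w = weights if weights is not None else [100.0] * len(sample_ids)
    return mh.validate_metadata(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "habitat": habitats,
                "body_weight_g": [None if h == "water" else wi for h, wi in zip(habitats, w)],
                "site": site,
                "month": month,
            }
        )
    )


@pytest.fixture(scope="session")
def sim_dataset():
    """Shared mid-size synthetic metacommunity (3 fish habitats)."""
    params = mh.SimulationParams(
        n_habitats=3,
        fish_per_habitat=6,
        pool_size=120,
        selection_strength=10.0,
        dispersal_rate=0.05,
        weight_slope=0.001,
        reads_per_sample=2000,
        seed=42,
    )
    tree = mh.simulate_phylogeny(params.pool_size, seed=42)
    table, meta, truth = mh.simulate_metacommunity(params, tree)
    return params, tree, table, meta, truth
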
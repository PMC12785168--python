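import numpy as np
import pandas as pd
import pytest

import organgrn as og


@pytest.fixture(scope="session")
def small_cfg():
    """Small, fast simulation: 8 TFs, 40 genes, 60 samples per organ."""
    return og.SimulationConfig(
        n_tf=8, n_gene=40, n_samples_per_organ=60, n_studies=3,
        mean_outdegree=5, organs=("root", "leaf", "fruit"), seed=11,
    )


@pytest.fixture(scope="session")
def small_truth(small_cfg):
    return og.generate_truth(small_cfg)


@pytest.fixture(scope="session")
def small_expression(small_truth, small_cfg):
    return og.simulate_expression(small_truth, "leaf", small_cfg)


@pytest.fixture(scope="session")
def small_ranked(small_truth, small_expression):
    abund, _, _, _ = small_expression
    return og.infer_grn(abund, set(small_truth.tf_ids), n_trees=100, seed=1)


@pytest.fixture
def toy_genes():
    return {
        "g1": og.GeneModel("g1", "chr1", 1000, 2000, "+"),
        "g2": og.GeneModel("g2", "chr1", 5000, 6000, "-"),
        "g3": og.GeneModel("g3", "chr2", 100, 900, "+"),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
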
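import networkx as nx
import numpy as np
import pytest

import dtiwalk
from dtiwalk.boosting import BoosterSpec
from dtiwalk.embedding import Node2VecConfig
from dtiwalk.evaluation import PipelineConfig, make_random_pair_folds, run_cv
from dtiwalk.graph import GraphBuildConfig, HeterogeneousGraph


def make_plain_graph(edges, kinds=None) -> HeterogeneousGraph:
    """Wrap a weighted edge list in a HeterogeneousGraph for walk tests."""
    g = nx.Graph()
    for a, b, w in edges:
        g.add_edge(a, b, weight=float(w), kind="x")
    for v in g.nodes:
        g.nodes[v]["kind"] = (kinds or {}).get(v, "drug")
    return HeterogeneousGraph(g=g)


@pytest.fixture(scope="session")
def tiny_dataset():
    """30x30 block dataset used by fast pipeline-level tests."""
    cfg = dtiwalk.SyntheticConfig(
        m=30, n=30, B=3, pi_in=0.6, pi_out=0.02, seed=5
    )
    return dtiwalk.generate_block_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_pipeline():
    return PipelineConfig(
        graph=GraphBuildConfig(k_drug=3, k_target=3),
        node2vec=Node2VecConfig(
            d=16, walk_length=30, num_walks=5, window=5, epochs=3, seed=0
        ),
        fusion="hadamard",
        booster=BoosterSpec("xgboost", {}, 0),
    )


@pytest.fixture(scope="session")
def block_dataset():
    """The 60x60 four-block study-condition dataset."""
    cfg = dtiwalk.SyntheticConfig(
        m=60, n=60, B=4, pi_in=0.5, pi_out=0.01, seed=11
    )
    return dtiwalk.generate_block_dataset(cfg)


@pytest.fixture(scope="session")
def block_pipeline():
    return PipelineConfig(
        graph=GraphBuildConfig(k_drug=5, k_target=5),
        node2vec=Node2VecConfig(
            d=32, walk_length=80, num_walks=10, window=5, epochs=5, seed=0
        ),
        fusion="hadamard",
        booster=BoosterSpec("xgboost", {}, 0),
    )


@pytest.fixture(scope="session")
def block_cv_report(block_dataset, block_pipeline):
    """One full 5-fold CV run on the study conditions, shared across tests."""
    net, dd, tt = block_dataset
    plan = make_random_pair_folds(net, 5, seed=3)
    return run_cv(net, dd, tt, block_pipeline, plan)
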
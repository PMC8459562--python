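"""KNN similarity sparsification and heterogeneous graph assembly.

Dense similarity matrices carry many near-zero scores that add noise and
cost; keeping only each node's k most similar neighbours bounds each
similarity subgraph at k*m edges (union symmetrization: an edge survives if
either endpoint selects the other).  The heterogeneous graph combines the
two sparsified similarity subgraphs with the *training* interaction edges —
test interactions never enter the graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from dtiwalk.data_io import DrugTargetNetwork, SimilarityMatrix

logger = logging.getLogger(__name__)

DRUG = "drug"
TARGET = "target"


@dataclass
class GraphBuildConfig:
    """Neighbour counts for the two similarity networks."""

    k_drug: int = 5
    k_target: int = 5


@dataclass
class SimilarityEdgeList:
    """Undirected weighted edges within one node family.

    No self-loops, no duplicate unordered pairs, weights in (0, 1].
    ``universe`` records every node the list was built over, including nodes
    left without edges.
    """

    edges: list[tuple[str, str, float]]
    universe: list[str] = field(default_factory=list)


def knn_filter(sim: SimilarityMatrix, k: int) -> SimilarityEdgeList:
    """Keep each node's k most similar neighbours.

    Ties in similarity are broken by ascending identifier; neighbours with
    similarity exactly 0 are dropped even when inside the top k (edge
    weights must be strictly positive).  The result is the union over all
    per-node selections, so the edge count is at most ``k * len(sim.ids)``.
    """
    n = len(sim.ids)
    if not (1 <= k <= n - 1):
        raise ValueError(f"k={k} out of range [1, {n - 1}]")
    order = np.argsort(sim.ids)  # ascending-identifier rank for tie-breaks
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    selected: set[tuple[int, int]] = set()
    for i in range(n):
        scores = sim.S[i].copy()
        scores[i] = -np.inf  # never select self
        # sort by (-similarity, identifier-rank): lexsort uses last key first
        neighbour_order = np.lexsort((rank, -scores))
        for j in neighbour_order[:k]:
            if scores[j] <= 0:
                continue
            selected.add((min(i, j), max(i, j)))
    edges = sorted(
        (*sorted((sim.ids[a], sim.ids[b])), float(sim.S[a, b]))
        for a, b in selected
    )
    return SimilarityEdgeList(edges=edges, universe=list(sim.ids))


@dataclass
class HeterogeneousGraph:
    """Typed, weighted, undirected graph of drugs, targets and their edges.

    Interaction (drug-target) edges carry weight exactly 1; similarity edges
    carry their similarity score in (0, 1].  Backed by a networkx Graph with
    ``kind`` node attributes and ``weight`` edge attributes.
    """

    g: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return list(self.g.nodes)

    def node_kind(self, node: str) -> str:
        return self.g.nodes[node]["kind"]

    def non_isolated_nodes(self) -> list[str]:
        return [v for v in self.g.nodes if self.g.degree(v) > 0]

    def edge_count(self, kind: str | None = None) -> int:
        if kind is None:
            return self.g.number_of_edges()
        return sum(1 for *_, d in self.g.edges(data=True) if d["kind"] == kind)


def build_heterogeneous_graph(
    train_pairs: list[tuple[str, str]],
    dd_edges: SimilarityEdgeList,
    tt_edges: SimilarityEdgeList,
) -> HeterogeneousGraph:
    """Assemble training interactions plus the two KNN similarity subgraphs.

    Nodes with no edge remain present as isolated vertices.  A training pair
    duplicating an existing edge is dropped with a warning.
    """
    g = nx.Graph()
    for d in dd_edges.universe:
        g.add_node(d, kind=DRUG)
    for t in tt_edges.universe:
        g.add_node(t, kind=TARGET)
    for a, b, w in dd_edges.edges:
        g.add_node(a, kind=DRUG)
        g.add_node(b, kind=DRUG)
        g.add_edge(a, b, weight=float(w), kind="drug_sim")
    for a, b, w in tt_edges.edges:
        g.add_node(a, kind=TARGET)
        g.add_node(b, kind=TARGET)
        g.add_edge(a, b, weight=float(w), kind="target_sim")
    for d, t in train_pairs:
        if g.has_edge(d, t):
            logger.warning("duplicate interaction edge (%s, %s) ignored", d, t)
            continue
        g.add_node(d, kind=DRUG)
        g.add_node(t, kind=TARGET)
        g.add_edge(d, t, weight=1.0, kind="interaction")
    return HeterogeneousGraph(g=g)


def select_k(
    net: DrugTargetNetwork,
    dd: SimilarityMatrix,
    tt: SimilarityMatrix,
    candidate_ks: list[int],
    pipeline_config,
    folds: int = 10,
    seed: int = 0,
):
    """Pick the neighbour count k by cross-validated mean AUPR.

    Runs the full pipeline CV for every candidate (applied to both the drug
    and the target network) and returns ``(best_k, {k: mean_aupr})``.  Ties
    are broken toward the smaller k.
    """
    from dtiwalk.evaluation import make_random_pair_folds, run_cv

    if not candidate_ks:
        raise ValueError("need at least one candidate k")
    scores: dict[int, float] = {}
    for k in candidate_ks:
        cfg = pipeline_config.with_k(k_drug=k, k_target=k)
        plan = make_random_pair_folds(net, folds, seed=seed)
        report = run_cv(net, dd, tt, cfg, plan)
        scores[k] = report.mean_aupr
        logger.info("select_k: k=%d mean AUPR=%.4f", k, scores[k])
    best = min(scores, key=lambda k: (-scores[k], k))
    return best, scores
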
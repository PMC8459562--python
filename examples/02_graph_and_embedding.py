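"""Sparsify similarities, assemble the heterogeneous graph, embed its nodes.

Each similarity matrix is reduced to every node's k most similar
neighbours (bounding the subgraph at k*m edges), combined with the known
interaction edges into one weighted graph, and embedded with p/q-biased
random walks plus skip-gram.
"""

import numpy as np

import dtiwalk

net, drug_sim, target_sim = dtiwalk.generate_block_dataset(
    dtiwalk.SyntheticConfig(m=60, n=60, B=4, pi_in=0.5, pi_out=0.01, seed=11)
)

dd_edges = dtiwalk.knn_filter(drug_sim, k=5)
tt_edges = dtiwalk.knn_filter(target_sim, k=5)
graph = dtiwalk.build_heterogeneous_graph(net.positive_pairs(), dd_edges, tt_edges)
print(f"graph: {len(graph.nodes)} nodes, "
      f"{graph.edge_count('interaction')} interaction edges, "
      f"{graph.edge_count('drug_sim')} drug-sim edges (<= {5 * net.n_drugs}), "
      f"{graph.edge_count('target_sim')} target-sim edges")

table = dtiwalk.embed(
    graph,
    dtiwalk.Node2VecConfig(d=32, walk_length=80, num_walks=10, seed=0),
)
print(f"embedding: {table.vectors.shape[0]} nodes x {table.d} dimensions")

# same-block drugs should sit closer in embedding space than cross-block ones
def cosine(u, v):
    a, b = table[u], table[v]
    return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))

same = cosine("d0000", "d0004")   # both in block 0
cross = cosine("d0000", "d0001")  # blocks 0 and 1
print(f"cosine same-block {same:.3f} vs cross-block {cross:.3f}")
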
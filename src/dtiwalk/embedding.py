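"""Node embeddings via p/q-biased second-order random walks and skip-gram.

The walk interpolates breadth-first and depth-first exploration: having
stepped t -> v, the unnormalized probability of continuing to a neighbour x
of v is alpha(t, x) * w(v, x), where alpha = 1/p for returning to t, 1 for
x adjacent to t, and 1/q otherwise.  Walk biases multiply the edge weight,
so similarity scores shape the sampled neighbourhoods.  All transition
distributions are stored as alias tables for O(1) sampling; walk sequences
are fed to a skip-gram model with negative sampling trained by sequential
(deterministic) stochastic gradient descent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from dtiwalk.graph import HeterogeneousGraph

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class Node2VecConfig:
    """Walk and skip-gram hyperparameters.

    ``p`` (return) and ``q`` (in-out) steer the walk between revisiting and
    exploring; ``d`` is the embedding dimension; ``num_walks`` walks of
    ``walk_length`` nodes start from every non-isolated node.  Skip-gram uses
    ``negative`` noise samples per positive pair and an initial learning rate
    ``alpha`` decayed linearly over training.  Training is sequential, so
    results are reproducible from ``seed``; ``workers`` is accepted for
    interface compatibility but does not parallelize training.
    """

    p: float = 1.0
    q: float = 1.0
    d: int = 64
    walk_length: int = 80
    num_walks: int = 10
    window: int = 5
    epochs: int = 5
    workers: int = 1
    seed: int = 0
    negative: int = 5
    alpha: float = 0.025

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ConfigError("p and q must be > 0")
        if min(self.d, self.walk_length, self.num_walks, self.window,
               self.epochs, self.workers) < 1:
            raise ConfigError("d, walk_length, num_walks, window, epochs and "
                              "workers must all be >= 1")


# ---------------------------------------------------------------------------
# alias tables


def _alias_setup(probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vose alias construction for one categorical distribution."""
    n = len(probs)
    prob = np.zeros(n)
    alias = np.zeros(n, dtype=np.int64)
    scaled = probs * n
    small = [i for i in range(n) if scaled[i] < 1.0]
    large = [i for i in range(n) if scaled[i] >= 1.0]
    while small and large:
        s, l = small.pop(), large.pop()
        prob[s] = scaled[s]
        alias[s] = l
        scaled[l] = scaled[l] - (1.0 - scaled[s])
        (small if scaled[l] < 1.0 else large).append(l)
    for i in large:
        prob[i] = 1.0
    for i in small:
        prob[i] = 1.0
    return prob, alias


@dataclass
class TransitionModel:
    """Alias-table transition structure over a heterogeneous graph.

    CSR adjacency (``indptr``, ``nbr``, ``wgt``) with neighbour lists sorted
    by node index.  First-step tables occupy CSR slots; the second-step table
    for the directed-edge state t -> v held in CSR slot j covers the
    neighbours of v and starts at ``state_offset[j]``.
    """

    ids: list[str]
    index: dict[str, int]
    indptr: np.ndarray
    nbr: np.ndarray
    wgt: np.ndarray
    first_prob: np.ndarray
    first_alias: np.ndarray
    second_prob: np.ndarray
    second_alias: np.ndarray
    state_offset: np.ndarray
    p: float
    q: float
    kinds: list[str] = field(default_factory=list)

    # -- analytic distributions (used to build the tables and as oracles) --

    def _neighbour_slice(self, v: int) -> slice:
        return slice(int(self.indptr[v]), int(self.indptr[v + 1]))

    def first_step_probs(self, node: str) -> dict[str, float]:
        """Weight-proportional distribution over the node's neighbours."""
        v = self.index[node]
        sl = self._neighbour_slice(v)
        w = self.wgt[sl]
        return {
            self.ids[x]: float(wi / w.sum())
            for x, wi in zip(self.nbr[sl], w)
        }

    def second_step_probs(self, prev: str, cur: str) -> dict[str, float]:
        """alpha-biased distribution over cur's neighbours given prev."""
        t, v = self.index[prev], self.index[cur]
        sl = self._neighbour_slice(v)
        t_nbrs = self.nbr[self._neighbour_slice(t)]
        mass = np.empty(sl.stop - sl.start)
        for i, (x, w) in enumerate(zip(self.nbr[sl], self.wgt[sl])):
            if x == t:
                a = 1.0 / self.p
            elif t_nbrs[np.searchsorted(t_nbrs, x) % len(t_nbrs)] == x:
                a = 1.0
            else:
                a = 1.0 / self.q
            mass[i] = a * w
        mass /= mass.sum()
        return {self.ids[x]: float(m) for x, m in zip(self.nbr[sl], mass)}

    # -- alias sampling (python-level; walks use the numba kernel) --

    def sample_next(
        self, prev: str | None, cur: str, size: int, rng: np.random.Generator
    ) -> list[str]:
        """Draw ``size`` next nodes from the stored alias tables."""
        v = self.index[cur]
        deg = int(self.indptr[v + 1] - self.indptr[v])
        if deg == 0:
            raise ValueError(f"node {cur} has no neighbours")
        if prev is None:
            off = int(self.indptr[v])
            prob, alias = self.first_prob, self.first_alias
        else:
            t = self.index[prev]
            sl = self._neighbour_slice(t)
            j = sl.start + int(np.searchsorted(self.nbr[sl], v))
            if j >= sl.stop or self.nbr[j] != v:
                raise ValueError(f"no edge {prev} -> {cur}")
            off = int(self.state_offset[j])
            prob, alias = self.second_prob, self.second_alias
        i = rng.integers(deg, size=size)
        u = rng.random(size)
        picked = np.where(u < prob[off + i], i, alias[off + i])
        base = int(self.indptr[v])
        return [self.ids[self.nbr[base + k]] for k in picked]


def _graph_to_csr(graph: HeterogeneousGraph):
    ids = sorted(graph.g.nodes)
    index = {v: i for i, v in enumerate(ids)}
    n = len(ids)
    rows: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for a, b, data in graph.g.edges(data=True):
        w = float(data["weight"])
        rows[index[a]].append((index[b], w))
        rows[index[b]].append((index[a], w))
    indptr = np.zeros(n + 1, dtype=np.int64)
    nbr_parts, wgt_parts = [], []
    for i, row in enumerate(rows):
        row.sort()
        indptr[i + 1] = indptr[i] + len(row)
        nbr_parts.extend(x for x, _ in row)
        wgt_parts.extend(w for _, w in row)
    return ids, index, indptr, np.array(nbr_parts, dtype=np.int64), np.array(
        wgt_parts, dtype=np.float64
    )


def build_transition_model(
    graph: HeterogeneousGraph, p: float, q: float
) -> TransitionModel:
    """Precompute first- and second-order alias tables for the whole graph.

    Isolated nodes get no tables.  Every stored distribution is normalized
    exactly (sums to 1 within 1e-12) before alias construction.
    """
    if p <= 0 or q <= 0:
        raise ConfigError("p and q must be > 0")
    ids, index, indptr, nbr, wgt = _graph_to_csr(graph)
    nnz = len(nbr)
    first_prob = np.zeros(nnz)
    first_alias = np.zeros(nnz, dtype=np.int64)
    for v in range(len(ids)):
        sl = slice(int(indptr[v]), int(indptr[v + 1]))
        if sl.stop == sl.start:
            continue
        probs = wgt[sl] / wgt[sl].sum()
        first_prob[sl], first_alias[sl] = _alias_setup(probs)

    # second-order: one table per directed edge t->v (CSR slot j), over v's
    # neighbours
    state_offset = np.zeros(nnz + 1, dtype=np.int64)
    for j in range(nnz):
        v = nbr[j]
        state_offset[j + 1] = state_offset[j] + (indptr[v + 1] - indptr[v])
    second_prob = np.zeros(int(state_offset[nnz]))
    second_alias = np.zeros(int(state_offset[nnz]), dtype=np.int64)
    for t in range(len(ids)):
        t_nbrs = nbr[indptr[t]:indptr[t + 1]]
        for j in range(int(indptr[t]), int(indptr[t + 1])):
            v = nbr[j]
            sl = slice(int(indptr[v]), int(indptr[v + 1]))
            xs, ws = nbr[sl], wgt[sl]
            alpha = np.where(
                xs == t,
                1.0 / p,
                np.where(np.isin(xs, t_nbrs), 1.0, 1.0 / q),
            )
            mass = alpha * ws
            mass /= mass.sum()
            off = int(state_offset[j])
            second_prob[off:off + len(xs)], second_alias[off:off + len(xs)] = (
                _alias_setup(mass)
            )
    return TransitionModel(
        ids=ids, index=index, indptr=indptr, nbr=nbr, wgt=wgt,
        first_prob=first_prob, first_alias=first_alias,
        second_prob=second_prob, second_alias=second_alias,
        state_offset=state_offset, p=p, q=q,
        kinds=[graph.node_kind(v) for v in ids],
    )


# ---------------------------------------------------------------------------
# walk simulation


@njit(cache=True)
def _simulate_kernel(indptr, nbr, first_prob, first_alias, second_prob,
                     second_alias, state_offset, starts, num_walks,
                     walk_length, seed):  # pragma: no cover - numba
    np.random.seed(seed)
    n_start = starts.shape[0]
    walks = np.full((num_walks * n_start, walk_length), -1, dtype=np.int64)
    w = 0
    for _ in range(num_walks):
        for s_i in range(n_start):
            s = starts[s_i]
            walks[w, 0] = s
            deg = indptr[s + 1] - indptr[s]
            if deg > 0 and walk_length > 1:
                i = np.random.randint(deg)
                off = indptr[s]
                if np.random.random() >= first_prob[off + i]:
                    i = first_alias[off + i]
                slot = indptr[s] + i
                cur = nbr[slot]
                walks[w, 1] = cur
                step = 2
                while step < walk_length:
                    degv = indptr[cur + 1] - indptr[cur]
                    if degv == 0:
                        break
                    i = np.random.randint(degv)
                    off = state_offset[slot]
                    if np.random.random() >= second_prob[off + i]:
                        i = second_alias[off + i]
                    slot = indptr[cur] + i
                    cur = nbr[slot]
                    walks[w, step] = cur
                    step += 1
            w += 1
    return walks


@dataclass
class WalkCorpus:
    """Sampled node sequences ("sentences") plus the id vocabulary."""

    walks: list[list[str]]

    def __len__(self) -> int:
        return len(self.walks)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for walk in self.walks:
                fh.write(" ".join(walk) + "\n")


def simulate_walks(model: TransitionModel, cfg: Node2VecConfig) -> WalkCorpus:
    """Run ``cfg.num_walks`` biased walks from every non-isolated node.

    A walk ends early only upon reaching a node with no neighbours (cannot
    happen on an undirected graph once started).  Reproducible from
    ``cfg.seed``.
    """
    degrees = np.diff(model.indptr)
    starts = np.flatnonzero(degrees > 0).astype(np.int64)
    raw = _simulate_kernel(
        model.indptr, model.nbr, model.first_prob, model.first_alias,
        model.second_prob, model.second_alias, model.state_offset,
        starts, cfg.num_walks, cfg.walk_length, cfg.seed % (2**31),
    )
    walks = []
    for row in raw:
        walks.append([model.ids[x] for x in row if x >= 0])
    return WalkCorpus(walks=walks)


# ---------------------------------------------------------------------------
# skip-gram with negative sampling


@njit(cache=True)
def _sgns_kernel(walks, counts, d, window, epochs, negative, alpha0,
                 seed):  # pragma: no cover - numba
    np.random.seed(seed)
    n_nodes = counts.shape[0]
    syn0 = (np.random.random((n_nodes, d)) - 0.5) / d
    syn1 = np.zeros((n_nodes, d))
    # unigram^0.75 cumulative noise distribution
    noise = counts.astype(np.float64) ** 0.75
    cdf = np.cumsum(noise)
    cdf /= cdf[-1]
    n_tokens = 0
    for wi in range(walks.shape[0]):
        for pos in range(walks.shape[1]):
            if walks[wi, pos] >= 0:
                n_tokens += 1
    total = epochs * n_tokens
    processed = 0
    grad = np.zeros(d)
    for _ in range(epochs):
        for wi in range(walks.shape[0]):
            length = walks.shape[1]
            for pos in range(walks.shape[1]):
                if walks[wi, pos] < 0:
                    length = pos
                    break
            for pos in range(length):
                center = walks[wi, pos]
                alpha = alpha0 * (1.0 - processed / (total + 1.0))
                if alpha < alpha0 * 1e-4:
                    alpha = alpha0 * 1e-4
                processed += 1
                b = np.random.randint(window)
                lo = pos - window + b
                if lo < 0:
                    lo = 0
                hi = pos + window - b + 1
                if hi > length:
                    hi = length
                for cpos in range(lo, hi):
                    if cpos == pos:
                        continue
                    ctx = walks[wi, cpos]
                    for k in range(d):
                        grad[k] = 0.0
                    for neg in range(negative + 1):
                        if neg == 0:
                            tgt = center
                            label = 1.0
                        else:
                            r = np.random.random()
                            tgt = np.searchsorted(cdf, r)
                            if tgt >= n_nodes:
                                tgt = n_nodes - 1
                            if tgt == center:
                                continue
                            label = 0.0
                        f = 0.0
                        for k in range(d):
                            f += syn0[ctx, k] * syn1[tgt, k]
                        if f > 6.0:
                            g = (label - 1.0) * alpha
                        elif f < -6.0:
                            g = label * alpha
                        else:
                            g = (label - 1.0 / (1.0 + np.exp(-f))) * alpha
                        for k in range(d):
                            grad[k] += g * syn1[tgt, k]
                            syn1[tgt, k] += g * syn0[ctx, k]
                    for k in range(d):
                        syn0[ctx, k] += grad[k]
    return syn0


@dataclass
class EmbeddingTable:
    """The learned mapping node_id -> R^d."""

    ids: list[str]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self._index = {v: i for i, v in enumerate(self.ids)}

    @property
    def d(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def __getitem__(self, node: str) -> np.ndarray:
        try:
            return self.vectors[self._index[node]]
        except KeyError:
            raise KeyError(f"no embedding for node {node!r}") from None

    def write(self, path) -> None:
        """Export in word2vec text format: header 'count dim', then rows."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)} {self.d}\n")
            for node, vec in zip(self.ids, self.vectors):
                fh.write(node + " " + " ".join(f"{x:.8g}" for x in vec) + "\n")


def train_skipgram(corpus: WalkCorpus, cfg: Node2VecConfig) -> EmbeddingTable:
    """Train skip-gram with negative sampling on the walk corpus.

    Every node appearing in the corpus receives a vector of length ``d``.
    Training is a single sequential pass per epoch with linearly decayed
    learning rate, hence bit-reproducible from ``cfg.seed``.
    """
    if not corpus.walks:
        raise ValueError("cannot train on an empty walk corpus")
    vocab = sorted({v for walk in corpus.walks for v in walk})
    index = {v: i for i, v in enumerate(vocab)}
    if cfg.d >= len(vocab):
        logger.warning(
            "embedding dimension d=%d >= vocabulary size %d", cfg.d, len(vocab)
        )
    max_len = max(len(w) for w in corpus.walks)
    walks = np.full((len(corpus.walks), max_len), -1, dtype=np.int64)
    counts = np.zeros(len(vocab), dtype=np.int64)
    for i, walk in enumerate(corpus.walks):
        for j, v in enumerate(walk):
            walks[i, j] = index[v]
            counts[index[v]] += 1
    vectors = _sgns_kernel(
        walks, counts, cfg.d, cfg.window, cfg.epochs, cfg.negative,
        cfg.alpha, (cfg.seed + 1) % (2**31),
    )
    return EmbeddingTable(ids=vocab, vectors=np.asarray(vectors))


def embed(graph: HeterogeneousGraph, cfg: Node2VecConfig) -> EmbeddingTable:
    """Full embedding pipeline: transition model -> walks -> skip-gram.

    Isolated nodes cannot appear in any walk and are absent from the table;
    they are reported in the log.
    """
    isolated = [v for v in graph.g.nodes if graph.g.degree(v) == 0]
    if isolated:
        logger.warning(
            "%d isolated nodes will have no embedding: %s",
            len(isolated), ", ".join(sorted(isolated)[:10]),
        )
    model = build_transition_model(graph, cfg.p, cfg.q)
    corpus = simulate_walks(model, cfg)
    return train_skipgram(corpus, cfg)
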
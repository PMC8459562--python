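# Methods

## Model and assumptions

The package treats DTI prediction as supervised link prediction on a
weighted heterogeneous graph. The working assumption is guilt by
association: similar drugs tend to interact with similar targets, so a
graph that couples interaction edges with (sparsified) similarity edges
places interacting drug–target pairs close in walk space, and a classifier
over fused node embeddings can rank unknown pairs. Negative labels are
*unknown* pairs, not verified non-interactions; reported AUPR therefore
measures ranking of known positives against a universe that may contain
undiscovered positives.

The embedding step assumes the graph is largely connected: nodes reachable
only through zero-weight or filtered-out similarities become isolated,
receive no embedding, and are reported rather than silently imputed.

## Pipeline parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `k_drug`, `k_target` | 5 | neighbours kept per node when sparsifying each similarity matrix; bounds the subgraph at k·m edges. Selected in practice by `select_k` (CV mean AUPR, ties to smaller k). |
| `p`, `q` | 1.0, 1.0 | node2vec return and in–out bias; α multiplies the edge weight so similarity scores shape transitions. p=q=1 reduces to a first-order weighted walk. |
| `d` | 64 | embedding dimension (dimensionless); 32–128 is the useful range at benchmark scale. |
| `walk_length`, `num_walks` | 80, 10 | nodes per walk and walks per source node — the node2vec reference defaults. |
| `window`, `negative`, `alpha`, `epochs` | 5, 5, 0.025, 5 | skip-gram context size, negative samples per pair, initial SGD learning rate (decayed linearly to 1e-4·alpha), training epochs — word2vec conventions, exposed in config. |
| `fusion` | hadamard | edge-feature operator; `average` is supported but known to perform worst, so sweeps typically exclude it. |
| booster | xgboost | `adaboost` uses depth-1 stumps (the canonical weak learner); XGBoost runs single-thread with the exact tree method so results are reproducible. Model selection criterion is AUPR throughout, since classes are heavily imbalanced. |

Master seed semantics: the CV orchestrator derives each fold's sub-seed as
`seed + fold_index` (mod 2³¹) and threads it through walk simulation,
skip-gram, oversampling and the booster, so a run is reproducible end to
end while folds stay decorrelated.

## Synthetic data: what it emulates, and what passing means

`generate_block_dataset` plants the guilt-by-association regularity
directly: drugs and targets are assigned round-robin to B blocks;
y_ij ~ Bernoulli(pi_in) within a block, Bernoulli(pi_out) across;
similarity is `sim_base` (+ `sim_bonus` for same-block pairs) with
symmetric Gaussian jitter, clipped into (0, 1] so every similarity edge
keeps a strictly positive weight. A repair pass gives every all-zero drug
row and target column one same-block interaction, because the random CV
setting requires every node to be seen in training. Defaults
(m=n=60, B=4, pi_in=0.5, pi_out=0.01, sim_base=0.2, sim_bonus=0.6,
sim_noise_sd=0.05) give prevalence ≈ 0.13 and a clearly recoverable but
noisy community signal.

**Performance ceiling.** In this generator, a held-out pair's label is
conditionally independent of *all* training data given block membership.
The Bayes-optimal scorer can therefore only rank same-block pairs above
cross-block pairs, and among same-block pairs precision is ≈ pi_in. With
pi_in = 0.5 the optimal mean AUPR is ≈ 0.50 (0.499 measured numerically on
the frozen folds); the pipeline reaches ≈ 0.51, i.e. it extracts the full
available signal, and the shuffled-label control collapses to prevalence.
Passing these checks shows the machinery recovers planted community
structure without leakage; it does **not** show benchmark-level AUPRs
(~0.9), which arise on real data where individual drugs and targets carry
far richer, non-exchangeable neighbourhood information than exchangeable
blocks provide. Real similarity distributions (heavy-tailed, block-free)
and hub-degree heterogeneity are deliberately not emulated.

## Numerical choices

- **KNN symmetrization by union**: an edge survives if either endpoint
  selected the other; this preserves every node's stated top-k
  neighbourhood and keeps the k·m bound. Ties break by ascending
  identifier; zero-similarity selections are dropped (edge weights must be
  strictly positive).
- **Alias tables** (Vose) give O(1) walk transitions; every distribution is
  normalized exactly before table construction (sums within 1e-12). Tables
  for all directed-edge states are built eagerly — at the graph sizes this
  package targets (≤ a few thousand directed states) the memory cost of
  Σ_v deg(v)² entries is trivial and eager construction keeps the sampler
  branch-free.
- **Skip-gram** is implemented in-package with negative sampling
  (unigram^0.75 noise distribution), a per-token linearly decayed learning
  rate and sequential single-threaded updates compiled with numba, so
  training is bit-reproducible from the seed. The `workers` field is
  accepted for interface compatibility but does not parallelize training.
- **Min–max normalization**: constant training features map to 0;
  out-of-range test values are *not* clipped, preserving out-of-range
  signal under the train-only fit.
- **Oversampling** appends exact copies of minority rows (sampled with
  replacement, seeded) after the normalization fit, on training rows only.
- **AUPR** uses the average-precision convention (precision summed at each
  newly recalled positive times the recall increment), matching a
  rank-by-rank oracle exactly on distinct scores; tied scores collapse to
  one threshold. ER + AUPR = 1 holds exactly by construction.
- **Wilcoxon tests** use exact small-sample null distributions (n ≤ 25);
  all-zero paired differences are signaled as undefined rather than
  returning a p-value.
- **Reported aggregates** round half-up (0.945 → 0.95), the convention of
  printed comparison tables, rather than banker's rounding.
- Similarity files with asymmetry ≤ 1e-6 are repaired by averaging with
  the transpose (distribution files carry rounding asymmetry); larger
  asymmetry is an error.

## Design choices where the design was open

- **New-drug rounds** keep held-out drugs' similarity edges (their
  interaction edges are removed): that is the only mechanism by which a
  drug with no known interactions can receive an embedding at all.
- **Negative universe**: all unknown pairs participate in CV; an optional
  `negative_cap` uniformly subsamples *training* negatives for very large
  synthetic runs and is off by default.
- **Novel-interaction ranking** uses a single seeded half/half split of the
  negatives (train/score) rather than reusing the CV machinery.
- **MAP** skips, for a given drug, folds in which that drug has no positive
  test pair, and averages over drugs with at least one contributing fold.
- **Concatenation order** is drug block first; weighted-L2 is the
  elementwise squared difference (a d-length vector, not a norm scalar).

## Problem sizes

Tests and the acceptance script run the full pipeline at m = n = 60 with
five folds (and 30×30 with three folds for fast unit-level checks); these
sizes give stable fold metrics (σ(AUPR) ≈ 0.05) while keeping a complete
run in tens of seconds. Transition-probability oracles use 10⁵ draws
(sampling error ≈ 0.003, well inside the 0.01 check).

## Known limitations

- New targets and new-drug/new-target pairs are out of scope: a target
  with no training interactions and no informative similarity neighbours
  cannot be ranked meaningfully.
- Chemical and sequence similarities are consumed as inputs, never
  computed; multi-similarity fusion (SNF-style) is intentionally absent —
  one similarity per node family.
- Skip-gram determinism relies on sequential training; there is no
  multi-worker mode.
- Scores are not calibrated probabilities; only their ranking is
  meaningful.
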
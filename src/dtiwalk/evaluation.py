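"""Evaluation protocols: splits, metrics, statistical comparison, CV runs.

Three regimes are supported.  The random setting removes random drug-target
pairs into stratified test folds (every node keeps at least one training
interaction, or a warning is raised).  The new-drug setting holds out whole
drugs per round: their interaction edges vanish from training and they stay
reachable only through similarity edges.  The hold-out regime is a single
stratified train/validation/test split.  In every regime the heterogeneous
graph is rebuilt per fold from training positives only, embeddings are
re-learned, normalization is fitted on training rows, and oversampling and
hyperparameters touch training data only — no test information leaks
upstream of scoring.

Metrics: ROC-AUC (trapezoidal), AUPR by the average-precision convention,
error rate ER = 1 - AUPR and relative error reduction
dER = (ER2 - ER1) / ER2, mean average precision per drug over folds, and
exact two-sided Wilcoxon tests on per-fold AUPRs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from dtiwalk.boosting import BoosterSpec, predict_scores, train_booster
from dtiwalk.data_io import DrugTargetNetwork, SimilarityMatrix
from dtiwalk.embedding import Node2VecConfig, embed
from dtiwalk.features import (
    apply_minmax,
    build_feature_set,
    fit_minmax,
    oversample_minority,
)
from dtiwalk.graph import GraphBuildConfig, build_heterogeneous_graph, knn_filter

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs besides the data and the split."""

    graph: GraphBuildConfig = field(default_factory=GraphBuildConfig)
    node2vec: Node2VecConfig = field(default_factory=Node2VecConfig)
    fusion: str = "hadamard"
    booster: BoosterSpec = field(default_factory=BoosterSpec)
    #: optional cap on training negatives (uniform subsample); None = use all
    negative_cap: int | None = None

    def with_k(self, k_drug: int, k_target: int) -> "PipelineConfig":
        return replace(self, graph=GraphBuildConfig(k_drug, k_target))


@dataclass
class SplitPlan:
    """Disjoint test index sets over the flattened pair universe.

    Pair (drug i, target j) has flat index ``i * n_targets + j``.  For
    ``holdout`` mode, ``folds`` holds [train, valid, test] index arrays.
    """

    mode: str
    folds: list[np.ndarray]
    seed: int
    n_drugs: int
    n_targets: int


def make_random_pair_folds(
    net: DrugTargetNetwork, n_folds: int, seed: int
) -> SplitPlan:
    """Stratified partition of all pairs into ``n_folds`` test sets.

    Positives and negatives are shuffled separately and dealt round-robin,
    so per-fold positive counts differ from the ideal quota by at most one.
    Warns when some drug or target loses all its positives from a training
    fold (random-setting violation).
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    flat = net.Y.ravel()
    pos = np.flatnonzero(flat == 1)
    neg = np.flatnonzero(flat == 0)
    if len(pos) < n_folds:
        raise ValueError(
            f"{len(pos)} positives cannot be stratified over {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    rng.shuffle(pos)
    rng.shuffle(neg)
    folds = [
        np.sort(np.concatenate([pos[f::n_folds], neg[f::n_folds]]))
        for f in range(n_folds)
    ]
    for f, test_idx in enumerate(folds):
        test_mask = np.zeros(flat.size, dtype=bool)
        test_mask[test_idx] = True
        train_Y = np.where(
            test_mask.reshape(net.Y.shape), 0, net.Y
        )
        if (train_Y.sum(axis=1) == 0).any() or (train_Y.sum(axis=0) == 0).any():
            logger.warning(
                "fold %d: some drug or target has no training positive", f
            )
    return SplitPlan(
        mode="random_pair_cv", folds=folds, seed=seed,
        n_drugs=net.n_drugs, n_targets=net.n_targets,
    )


def make_new_drug_folds(
    net: DrugTargetNetwork, n_rounds: int, seed: int
) -> SplitPlan:
    """Partition drugs into rounds; each round tests all pairs of its drugs."""
    if not (1 <= n_rounds <= net.n_drugs):
        raise ValueError("n_rounds must lie in [1, number of drugs]")
    rng = np.random.default_rng(seed)
    drug_order = rng.permutation(net.n_drugs)
    folds = []
    for r in range(n_rounds):
        held = drug_order[r::n_rounds]
        idx = (held[:, None] * net.n_targets + np.arange(net.n_targets)).ravel()
        folds.append(np.sort(idx))
    return SplitPlan(
        mode="new_drug_cv", folds=folds, seed=seed,
        n_drugs=net.n_drugs, n_targets=net.n_targets,
    )


def make_holdout_split(
    net: DrugTargetNetwork,
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> SplitPlan:
    """Single stratified train/validation/test split of the pair universe."""
    if abs(sum(fractions) - 1.0) > 1e-9 or min(fractions) <= 0:
        raise ValueError("fractions must be positive and sum to 1")
    flat = net.Y.ravel()
    rng = np.random.default_rng(seed)
    parts: list[list[np.ndarray]] = [[], [], []]
    for label in (1, 0):
        idx = np.flatnonzero(flat == label)
        rng.shuffle(idx)
        n = len(idx)
        c1 = int(round(fractions[0] * n))
        c2 = c1 + int(round(fractions[1] * n))
        parts[0].append(idx[:c1])
        parts[1].append(idx[c1:c2])
        parts[2].append(idx[c2:])
    folds = [np.sort(np.concatenate(p)) for p in parts]
    return SplitPlan(
        mode="holdout", folds=folds, seed=seed,
        n_drugs=net.n_drugs, n_targets=net.n_targets,
    )


# ---------------------------------------------------------------------------
# metrics


@dataclass
class MetricsReport:
    """Ranking metrics for one scored test set."""

    auc: float
    aupr: float
    er: float
    precision: np.ndarray
    recall: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        assert abs((self.er + self.aupr) - 1.0) < 1e-15


def compute_metrics(scores, labels) -> MetricsReport:
    """AUC (trapezoidal ROC) and AUPR (average-precision convention).

    Tied scores are treated as a single threshold.  Requires at least one
    positive and one negative label.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("metrics need both a positive and a negative label")
    auc = float(roc_auc_score(labels, scores))
    aupr = float(average_precision_score(labels, scores))
    precision, recall, _ = precision_recall_curve(labels, scores)
    fpr, tpr, _ = roc_curve(labels, scores)
    return MetricsReport(
        auc=auc, aupr=aupr, er=1.0 - aupr,
        precision=precision, recall=recall, fpr=fpr, tpr=tpr,
    )


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, the convention of printed report
    tables (banker's rounding would turn 0.945 into 0.94)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def error_rate(aupr: float) -> float:
    """ER = 1 - AUPR."""
    if not (0 <= aupr <= 1):
        raise ValueError("AUPR must lie in [0, 1]")
    return 1.0 - aupr


def error_reduction(er1: float, er2: float) -> float:
    """Relative error reduction (ER2 - ER1) / ER2 of best vs second best."""
    if er2 == 0:
        raise ValueError("error reduction undefined when the reference ER is 0")
    return (er2 - er1) / er2


def mean_average_precision(
    per_fold: list[dict[str, tuple[np.ndarray, np.ndarray]]]
) -> float:
    """MAP: per-drug average precision, averaged over folds then drugs.

    ``per_fold[f][drug] = (scores, labels)`` over that drug's test pairs in
    fold f.  A fold without a positive test pair for a drug is skipped for
    that drug; drugs with no contributing fold are excluded.
    """
    per_drug: dict[str, list[float]] = {}
    for fold in per_fold:
        for drug, (scores, labels) in fold.items():
            labels = np.asarray(labels)
            if labels.sum() == 0:
                continue
            ap = float(average_precision_score(labels, np.asarray(scores)))
            per_drug.setdefault(drug, []).append(ap)
    if not per_drug:
        raise ValueError("no drug has a positive test pair in any fold")
    return float(np.mean([np.mean(aps) for aps in per_drug.values()]))


def compare_folds(a, b, variant: str = "signed_rank") -> float:
    """Exact two-sided Wilcoxon p-value comparing two sets of fold AUPRs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if variant == "signed_rank":
        if len(a) != len(b):
            raise ValueError("signed-rank test requires paired samples")
        if np.all(a == b):
            raise ValueError(
                "signed-rank test undefined: all paired differences are zero"
            )
        return float(
            stats.wilcoxon(a, b, alternative="two-sided", method="exact").pvalue
        )
    if variant == "rank_sum":
        return float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        )
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# cross-validated pipeline runs


@dataclass
class CVReport:
    """Per-fold metrics plus aggregates and out-of-fold scores."""

    fold_metrics: list[MetricsReport]
    mean_aupr: float
    std_aupr: float
    mean_auc: float
    map: float
    oof_scores: np.ndarray
    config: PipelineConfig
    plan: SplitPlan

    def serialize(self) -> str:
        """Stable TSV rendering (byte-identical for identical runs)."""
        lines = ["fold\taupr\tauc\ter"]
        for f, m in enumerate(self.fold_metrics):
            lines.append(f"{f}\t{m.aupr:.6f}\t{m.auc:.6f}\t{m.er:.6f}")
        lines.append("")
        lines.append(f"mean_aupr\t{self.mean_aupr:.6f}")
        lines.append(f"std_aupr\t{self.std_aupr:.6f}")
        lines.append(f"mean_auc\t{self.mean_auc:.6f}")
        lines.append(f"map\t{self.map:.6f}")
        return "\n".join(lines) + "\n"


def _pairs_from_indices(
    net: DrugTargetNetwork, idx: np.ndarray
) -> tuple[list[tuple[str, str]], np.ndarray]:
    i, j = np.divmod(idx, net.n_targets)
    pairs = [(net.drug_ids[a], net.target_ids[b]) for a, b in zip(i, j)]
    labels = net.Y.ravel()[idx]
    return pairs, labels


def _run_fold(
    net: DrugTargetNetwork,
    dd_edges,
    tt_edges,
    config: PipelineConfig,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    fold_seed: int,
):
    """Train on the training indices, score the test indices.

    The graph holds training interaction edges only; embeddings,
    normalization parameters, oversampling and the booster never see a test
    pair.
    """
    flat = net.Y.ravel()
    train_pos_idx = train_idx[flat[train_idx] == 1]
    if config.negative_cap is not None:
        neg = train_idx[flat[train_idx] == 0]
        if len(neg) > config.negative_cap:
            rng = np.random.default_rng(fold_seed)
            neg = np.sort(rng.choice(neg, size=config.negative_cap, replace=False))
        train_idx = np.sort(np.concatenate([train_pos_idx, neg]))
    train_pos_pairs, _ = _pairs_from_indices(net, train_pos_idx)
    graph = build_heterogeneous_graph(train_pos_pairs, dd_edges, tt_edges)
    n2v = replace(config.node2vec, seed=fold_seed)
    table = embed(graph, n2v)

    train_pairs, train_labels = _pairs_from_indices(net, train_idx)
    test_pairs, test_labels = _pairs_from_indices(net, test_idx)
    train_fs = build_feature_set(table, train_pairs, train_labels, config.fusion)
    test_fs = build_feature_set(table, test_pairs, test_labels, config.fusion)
    params = fit_minmax(train_fs)
    train_fs = apply_minmax(train_fs, params)
    test_fs = apply_minmax(test_fs, params)
    train_fs = oversample_minority(train_fs, seed=fold_seed)
    spec = BoosterSpec(
        config.booster.algorithm, dict(config.booster.hyperparameters),
        seed=fold_seed,
    )
    model = train_booster(train_fs, spec)
    scores = predict_scores(model, test_fs.X)
    return scores, test_labels, test_pairs


def run_cv(
    net: DrugTargetNetwork,
    dd: SimilarityMatrix,
    tt: SimilarityMatrix,
    config: PipelineConfig,
    plan: SplitPlan,
) -> CVReport:
    """Run the full pipeline under a CV split plan.

    KNN similarity edges are computed once from the input similarity
    matrices (which are fixed inputs, not labels); per fold, the interaction
    graph is rebuilt from training positives, embeddings retrained, and test
    pairs scored out of fold.  Fully reproducible from ``plan.seed``.
    """
    if plan.mode not in ("random_pair_cv", "new_drug_cv"):
        raise ValueError(f"run_cv cannot handle split mode {plan.mode!r}")
    dd_edges = knn_filter(dd, config.graph.k_drug)
    tt_edges = knn_filter(tt, config.graph.k_target)
    universe = np.arange(net.n_drugs * net.n_targets)
    fold_metrics: list[MetricsReport] = []
    oof = np.full(universe.size, np.nan)
    per_fold_drug: list[dict[str, tuple[np.ndarray, np.ndarray]]] = []
    for f, test_idx in enumerate(plan.folds):
        train_mask = np.ones(universe.size, dtype=bool)
        train_mask[test_idx] = False
        fold_seed = (plan.seed + f) % _SEED_MOD
        scores, labels, pairs = _run_fold(
            net, dd_edges, tt_edges, config,
            universe[train_mask], test_idx, fold_seed,
        )
        oof[test_idx] = scores
        fold_metrics.append(compute_metrics(scores, labels))
        by_drug: dict[str, tuple[list, list]] = {}
        for (drug, _t), s, y in zip(pairs, scores, labels):
            by_drug.setdefault(drug, ([], []))[0].append(s)
            by_drug[drug][1].append(y)
        per_fold_drug.append(
            {d: (np.array(s), np.array(y)) for d, (s, y) in by_drug.items()}
        )
        logger.info(
            "fold %d: AUPR=%.4f AUC=%.4f", f, fold_metrics[-1].aupr,
            fold_metrics[-1].auc,
        )
    auprs = [m.aupr for m in fold_metrics]
    return CVReport(
        fold_metrics=fold_metrics,
        mean_aupr=float(np.mean(auprs)),
        std_aupr=float(np.std(auprs)),
        mean_auc=float(np.mean([m.auc for m in fold_metrics])),
        map=mean_average_precision(per_fold_drug),
        oof_scores=oof,
        config=config,
        plan=plan,
    )


@dataclass
class HoldoutReport:
    valid: MetricsReport
    test: MetricsReport


def run_holdout(
    net: DrugTargetNetwork,
    dd: SimilarityMatrix,
    tt: SimilarityMatrix,
    config: PipelineConfig,
    plan: SplitPlan,
) -> HoldoutReport:
    """Single train/validation/test run (hold-out regime)."""
    if plan.mode != "holdout":
        raise ValueError("run_holdout requires a holdout split plan")
    dd_edges = knn_filter(dd, config.graph.k_drug)
    tt_edges = knn_filter(tt, config.graph.k_target)
    train_idx, valid_idx, test_idx = plan.folds
    seed = plan.seed % _SEED_MOD
    eval_idx = np.sort(np.concatenate([valid_idx, test_idx]))
    scores, labels, _ = _run_fold(
        net, dd_edges, tt_edges, config, train_idx, eval_idx, seed
    )
    pos = {int(i): (s, l) for i, s, l in zip(eval_idx, scores, labels)}
    v_scores = np.array([pos[int(i)][0] for i in valid_idx])
    v_labels = np.array([pos[int(i)][1] for i in valid_idx])
    t_scores = np.array([pos[int(i)][0] for i in test_idx])
    t_labels = np.array([pos[int(i)][1] for i in test_idx])
    return HoldoutReport(
        valid=compute_metrics(v_scores, v_labels),
        test=compute_metrics(t_scores, t_labels),
    )


def rank_novel(
    net: DrugTargetNetwork,
    dd: SimilarityMatrix,
    tt: SimilarityMatrix,
    config: PipelineConfig,
    top_n: int = 5,
    seed: int = 0,
) -> list[tuple[int, str, str, float]]:
    """Rank unknown pairs as candidate novel interactions.

    All known positives plus a random half of the negatives train the model;
    the held-out negatives are scored and the ``top_n`` highest-scoring
    returned as (rank, drug_id, target_id, score).
    """
    flat = net.Y.ravel()
    pos = np.flatnonzero(flat == 1)
    neg = np.flatnonzero(flat == 0)
    rng = np.random.default_rng(seed)
    neg_shuffled = rng.permutation(neg)
    half = len(neg) // 2
    train_idx = np.sort(np.concatenate([pos, neg_shuffled[:half]]))
    test_idx = np.sort(neg_shuffled[half:])
    if top_n > len(test_idx):
        logger.warning(
            "top_n=%d exceeds %d held-out negatives; truncating",
            top_n, len(test_idx),
        )
        top_n = len(test_idx)
    dd_edges = knn_filter(dd, config.graph.k_drug)
    tt_edges = knn_filter(tt, config.graph.k_target)
    scores, _, pairs = _run_fold(
        net, dd_edges, tt_edges, config, train_idx, test_idx, seed % _SEED_MOD
    )
    order = np.argsort(-scores, kind="stable")[:top_n]
    return [
        (rank + 1, pairs[i][0], pairs[i][1], float(scores[i]))
        for rank, i in enumerate(order)
    ]
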
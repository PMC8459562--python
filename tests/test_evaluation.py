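import numpy as np
import pytest

import dtiwalk
from dtiwalk.data_io import DrugTargetNetwork
from dtiwalk.evaluation import (
    _run_fold,
    compare_folds,
    compute_metrics,
    error_rate,
    error_reduction,
    make_holdout_split,
    make_new_drug_folds,
    make_random_pair_folds,
    mean_average_precision,
    rank_novel,
    run_cv,
    run_holdout,
)
from dtiwalk.graph import knn_filter


def counts_net(m, n, n_pos, seed=0):
    rng = np.random.default_rng(seed)
    flat = np.zeros(m * n, dtype=np.int8)
    flat[rng.choice(m * n, n_pos, replace=False)] = 1
    return DrugTargetNetwork(
        [f"d{i}" for i in range(m)], [f"t{j}" for j in range(n)],
        flat.reshape(m, n),
    )


class TestRandomPairFolds:
    def test_even_stratification(self):
        plan = make_random_pair_folds(counts_net(10, 10, 20), 10, seed=1)
        for fold in plan.folds:
            assert len(fold) == 10
        net = counts_net(10, 10, 20)
        flat = net.Y.ravel()
        assert all(flat[f].sum() == 2 for f in plan.folds)

    def test_remainder_spread_within_one(self):
        net = counts_net(10, 10, 25)
        plan = make_random_pair_folds(net, 10, seed=2)
        pos_counts = [net.Y.ravel()[f].sum() for f in plan.folds]
        assert set(pos_counts) <= {2, 3}

    def test_folds_partition_pair_universe(self):
        plan = make_random_pair_folds(counts_net(8, 12, 30), 5, seed=3)
        allidx = np.concatenate(plan.folds)
        assert len(allidx) == 96
        assert len(np.unique(allidx)) == 96

    def test_too_few_positives_rejected(self):
        with pytest.raises(ValueError):
            make_random_pair_folds(counts_net(5, 5, 3), 10, seed=0)


class TestNewDrugFolds:
    def test_rounds_partition_drugs(self):
        net = counts_net(10, 6, 20)
        plan = make_new_drug_folds(net, 5, seed=4)
        drugs_per_round = [np.unique(f // 6) for f in plan.folds]
        assert all(len(d) == 2 for d in drugs_per_round)
        assert sorted(np.concatenate(drugs_per_round)) == list(range(10))

    def test_held_out_drug_pairs_never_in_training(self):
        net = counts_net(10, 6, 20)
        plan = make_new_drug_folds(net, 5, seed=4)
        universe = np.arange(60)
        for test in plan.folds:
            train = np.setdiff1d(universe, test)
            held_drugs = set(test // 6)
            assert not held_drugs & set(train // 6)


class TestHoldoutSplit:
    def test_three_way_stratified_partition(self):
        net = counts_net(10, 10, 20)
        plan = make_holdout_split(net, (0.7, 0.1, 0.2), seed=5)
        allidx = np.concatenate(plan.folds)
        assert len(np.unique(allidx)) == 100
        flat = net.Y.ravel()
        assert flat[plan.folds[0]].sum() == 14
        assert flat[plan.folds[1]].sum() == 2
        assert flat[plan.folds[2]].sum() == 4


def ap_oracle(scores, labels):
    """Rank-by-rank average precision; assumes strictly distinct scores."""
    order = np.argsort(-np.asarray(scores))
    tp, total = 0, 0.0
    for rank, i in enumerate(order, start=1):
        if labels[i] == 1:
            tp += 1
            total += tp / rank
    return total / max(tp, 1)


def auc_oracle(scores, labels):
    """Concordant-pair fraction with half weight for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestComputeMetrics:
    def test_perfect_ranking(self):
        m = compute_metrics([0.9, 0.8, 0.3, 0.1], [1, 1, 0, 0])
        assert (m.auc, m.aupr, m.er) == (1.0, 1.0, 0.0)

    def test_single_positive_at_second_rank(self):
        m = compute_metrics([0.7, 0.2], [0, 1])
        assert m.aupr == pytest.approx(0.5)

    def test_matches_bruteforce_oracles_on_small_inputs(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(2, 21))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = rng.permutation(n) / n  # distinct scores
            m = compute_metrics(scores, labels)
            assert m.aupr == pytest.approx(ap_oracle(scores, labels), abs=1e-12)
            assert m.auc == pytest.approx(auc_oracle(scores, labels), abs=1e-12)

    def test_tied_scores_treated_as_one_threshold(self):
        # permuting samples within a tie group cannot change the metrics
        scores = [0.9, 0.5, 0.5, 0.5, 0.1]
        labels = [1, 1, 0, 0, 0]
        m1 = compute_metrics(scores, labels)
        m2 = compute_metrics(scores, [1, 0, 0, 1, 0])
        assert m1.aupr == pytest.approx(m2.aupr)
        assert m1.auc == pytest.approx(m2.auc)
        assert m1.auc == pytest.approx(auc_oracle(scores, labels))

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(7)
        labels = (rng.random(10_000) < 0.05).astype(int)
        scores = rng.random(10_000)
        m = compute_metrics(scores, labels)
        assert m.aupr == pytest.approx(0.05, abs=0.02)

    def test_er_aupr_sum_exactly_one(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            labels = rng.integers(0, 2, 30)
            if labels.min() == labels.max():
                continue
            m = compute_metrics(rng.random(30), labels)
            assert m.er + m.aupr == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([0.1, 0.2], [1, 1])


class TestErrorRates:
    def test_error_rate_values(self):
        assert error_rate(0.92) == pytest.approx(0.08)
        assert error_rate(0.88) == pytest.approx(0.12)

    def test_error_reduction_holdout_value(self):
        assert error_reduction(0.18, 0.34) == pytest.approx(0.47, abs=0.005)

    def test_error_reduction_edge_cases(self):
        assert error_reduction(0.2, 0.2) == 0.0
        assert error_reduction(0.0, 0.3) == 1.0
        with pytest.raises(ValueError):
            error_reduction(0.1, 0.0)

    def test_error_reduction_monotone_in_best_er(self):
        ers = np.linspace(0, 0.5, 11)
        reductions = [error_reduction(e, 0.5) for e in ers]
        assert all(a >= b for a, b in zip(reductions, reductions[1:]))


class TestMeanAveragePrecision:
    def test_single_drug_examples(self):
        top = [{"d1": (np.array([0.9, 0.1]), np.array([1, 0]))}]
        assert mean_average_precision(top) == 1.0
        bottom = [{"d1": (np.array([0.9, 0.1]), np.array([0, 1]))}]
        assert mean_average_precision(bottom) == pytest.approx(0.5)

    def test_mean_over_drugs(self):
        folds = [{
            "d1": (np.array([0.9, 0.1]), np.array([1, 0])),
            "d2": (np.array([0.9, 0.1]), np.array([0, 1])),
        }]
        assert mean_average_precision(folds) == pytest.approx(0.75)

    def test_folds_without_positives_skipped(self):
        folds = [
            {"d1": (np.array([0.9, 0.1]), np.array([1, 0]))},
            {"d1": (np.array([0.9, 0.1]), np.array([0, 0]))},
        ]
        assert mean_average_precision(folds) == 1.0

    def test_no_positives_anywhere_rejected(self):
        with pytest.raises(ValueError):
            mean_average_precision(
                [{"d1": (np.array([0.5]), np.array([0]))}]
            )


class TestWilcoxon:
    def test_signed_rank_constant_shift(self):
        b = np.linspace(0.5, 0.9, 10)
        p = compare_folds(b + 0.1, b, "signed_rank")
        assert p == pytest.approx(2 / 1024, abs=1e-9)

    def test_identical_samples_signaled(self):
        a = np.linspace(0.5, 0.9, 10)
        with pytest.raises(ValueError):
            compare_folds(a, a, "signed_rank")

    def test_rank_sum_disjoint_ranges(self):
        p = compare_folds([1, 2, 3, 4, 5], [6, 7, 8, 9, 10], "rank_sum")
        assert p == pytest.approx(2 / 252, abs=1e-9)


class TestRunCV:
    def test_same_master_seed_identical_report(self, tiny_dataset, tiny_pipeline):
        net, dd, tt = tiny_dataset
        plan = make_random_pair_folds(net, 3, seed=9)
        r1 = run_cv(net, dd, tt, tiny_pipeline, plan)
        r2 = run_cv(net, dd, tt, tiny_pipeline, plan)
        assert r1.serialize() == r2.serialize()
        assert np.array_equal(r1.oof_scores, r2.oof_scores)

    def test_block_signal_recovered_above_prevalence(self, tiny_dataset, tiny_pipeline):
        """Block-structured data must be ranked far better than chance; the
        per-pair Bayes ceiling here is roughly pi_in, so mean AUPR should sit
        well above prevalence while staying below that ceiling."""
        net, dd, tt = tiny_dataset
        plan = make_random_pair_folds(net, 3, seed=9)
        report = run_cv(net, dd, tt, tiny_pipeline, plan)
        prevalence = net.n_known / (net.n_drugs * net.n_targets)
        assert report.mean_aupr >= 1.5 * prevalence
        assert 0 < report.map <= 1

    def test_no_test_leakage_into_training(self, tiny_dataset, tiny_pipeline):
        """Flipping a test-fold label leaves the fold's trained model (hence
        its scores) bit-identical — labels only reach metrics."""
        net, dd, tt = tiny_dataset
        plan = make_random_pair_folds(net, 3, seed=9)
        test_idx = plan.folds[0]
        universe = np.arange(net.n_drugs * net.n_targets)
        train_idx = np.setdiff1d(universe, test_idx)
        flipped = net.Y.ravel().copy()
        flipped[test_idx[0]] = 1 - flipped[test_idx[0]]
        net2 = DrugTargetNetwork(
            net.drug_ids, net.target_ids,
            flipped.reshape(net.Y.shape),
        )
        dd_e, tt_e = knn_filter(dd, 3), knn_filter(tt, 3)
        s1, _, _ = _run_fold(net, dd_e, tt_e, tiny_pipeline, train_idx, test_idx, 9)
        s2, _, _ = _run_fold(net2, dd_e, tt_e, tiny_pipeline, train_idx, test_idx, 9)
        assert np.array_equal(s1, s2)


class TestHoldoutAndNovel:
    def test_holdout_reports_valid_and_test(self, tiny_dataset, tiny_pipeline):
        net, dd, tt = tiny_dataset
        plan = make_holdout_split(net, (0.6, 0.2, 0.2), seed=1)
        report = run_holdout(net, dd, tt, tiny_pipeline, plan)
        for m in (report.valid, report.test):
            assert 0 <= m.aupr <= 1 and 0 <= m.auc <= 1

    def test_rank_novel_contract(self, tiny_dataset, tiny_pipeline):
        net, dd, tt = tiny_dataset
        ranked = rank_novel(net, dd, tt, tiny_pipeline, top_n=5, seed=0)
        assert len(ranked) == 5
        scores = [s for *_, s in ranked]
        assert scores == sorted(scores, reverse=True)
        for _, d, t, _s in ranked:
            assert net.Y[net.drug_ids.index(d), net.target_ids.index(t)] == 0

    def test_planted_pair_recovered_in_top_decile(self, tiny_pipeline):
        """Zero out one same-block positive; it should rank among the best
        held-out negatives."""
        cfg = dtiwalk.SyntheticConfig(
            m=30, n=30, B=3, pi_in=0.6, pi_out=0.02, seed=5
        )
        net, dd, tt = dtiwalk.generate_block_dataset(cfg)
        i, j = next(
            (i, j) for i in range(30) for j in range(30)
            if net.Y[i, j] == 1 and i % 3 == j % 3
        )
        net.Y[i, j] = 0
        ranked = rank_novel(net, dd, tt, tiny_pipeline, top_n=10**9, seed=0)
        target = (net.drug_ids[i], net.target_ids[j])
        ranks = [r for r, d, t, _ in ranked if (d, t) == target]
        assert ranks, "planted pair must be in the held-out half for this seed"
        assert ranks[0] <= len(ranked) / 10
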
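import numpy as np
import pytest

import elcda.evaluation as ev
from elcda import (build_dataset, compute_metrics, kfold_split, run_cv,
                   sample_negatives)
from elcda.hetnet import HeteroNetwork


def tiny_net(seed=0, m=12, p=6, n=9, density=0.25):
    rng = np.random.default_rng(seed)
    while True:
        A_CD = (rng.random((m, n)) < density).astype(int)
        if A_CD.sum() >= 10:  # enough positives for 5 folds
            break
    return HeteroNetwork(
        [f"c{i}" for i in range(m)], [f"m{i}" for i in range(p)],
        [f"d{i}" for i in range(n)],
        A_CD,
        (rng.random((m, p)) < 0.3).astype(int),
        (rng.random((p, n)) < 0.3).astype(int),
    )


class TestNegativeSampling:
    def test_exhaustive_draw(self):
        net = HeteroNetwork(["c0", "c1"], [], ["d0", "d1"],
                            np.array([[1, 0], [0, 0]]),
                            np.zeros((2, 0)), np.zeros((0, 2)))
        neg = sample_negatives(net, 3, seed=0)
        assert sorted(map(tuple, neg)) == [(0, 1), (1, 0), (1, 1)]

    def test_deterministic(self):
        net = tiny_net()
        assert np.array_equal(sample_negatives(net, 10, seed=4),
                              sample_negatives(net, 10, seed=4))

    def test_no_overlap_with_positives(self):
        net = tiny_net(3)
        k = int(net.A_CD.sum())
        neg = sample_negatives(net, k, seed=1)
        assert all(net.A_CD[i, j] == 0 for i, j in neg)
        assert len({tuple(x) for x in neg}) == k

    def test_oversized_request_rejected(self):
        net = tiny_net()
        with pytest.raises(ValueError):
            sample_negatives(net, net.n_circ * net.n_disease, seed=0)


class TestKFold:
    def test_balanced_fold_sizes(self):
        y = np.repeat([1, 0], 10)
        folds = kfold_split(y, k=5, seed=0)
        for f in range(5):
            assert (y[folds == f] == 1).sum() == 2
            assert (y[folds == f] == 0).sum() == 2

    def test_union_covers_everything(self):
        y = np.repeat([1, 0], 13)
        folds = kfold_split(y, k=5, seed=1)
        assert set(folds) == set(range(5))
        assert len(folds) == 26

    def test_deterministic(self):
        y = np.repeat([1, 0], 20)
        assert np.array_equal(kfold_split(y, seed=7), kfold_split(y, seed=7))

    def test_too_few_positives_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(np.array([1, 0, 0, 0, 0, 0]), k=5)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(np.repeat([1, 0], 10), k=1)


def metrics_oracle(y, p, thr=0.5):
    tp = fp = tn = fn = 0
    for yi, pi in zip(y, p):
        pred = pi >= thr
        if yi == 1 and pred:
            tp += 1
        elif yi == 1:
            fn += 1
        elif pred:
            fp += 1
        else:
            tn += 1
    acc = (tp + tn) / len(y)
    rec = tp / (tp + fn) if tp + fn else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return tp, tn, fp, fn, acc, rec, prec, f1


def auc_mann_whitney(y, p):
    pos = p[y == 1]
    neg = p[y == 0]
    wins = sum((pos_i > neg_j) + 0.5 * (pos_i == neg_j)
               for pos_i in pos for neg_j in neg)
    return wins / (len(pos) * len(neg))


class TestMetrics:
    def test_worked_confusion_example(self):
        y = np.array([1, 1, 0, 0, 0, 0])
        p = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.1])
        rep = compute_metrics(y, p)
        assert (rep["TP"], rep["TN"], rep["FP"], rep["FN"]) == (2, 3, 1, 0)
        assert rep["accuracy"] == pytest.approx(5 / 6)
        assert rep["recall"] == 1.0
        assert rep["precision"] == pytest.approx(2 / 3)
        assert rep["f1"] == pytest.approx(0.8)

    def test_perfect_and_inverted_predictors(self):
        y = np.array([1, 1, 0, 0])
        assert compute_metrics(y, np.array([0.9, 0.8, 0.2, 0.1]))["auc"] == 1.0
        assert compute_metrics(y, np.array([0.9, 0.8, 0.2, 0.1]))["aupr"] == pytest.approx(1.0)
        assert compute_metrics(y, np.array([0.1, 0.2, 0.8, 0.9]))["auc"] == 0.0

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_confusion_and_rank_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 40))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        p = np.round(rng.random(n), 2)  # rounding forces ties sometimes
        rep = compute_metrics(y, p)
        tp, tn, fp, fn, acc, rec, prec, f1 = metrics_oracle(y, p)
        assert (rep["TP"], rep["TN"], rep["FP"], rep["FN"]) == (tp, tn, fp, fn)
        assert rep["accuracy"] == pytest.approx(acc)
        assert rep["recall"] == pytest.approx(rec)
        assert rep["precision"] == pytest.approx(prec)
        assert rep["f1"] == pytest.approx(f1)
        assert rep["auc"] == pytest.approx(auc_mann_whitney(y, p), abs=1e-10)

    def test_single_class_reports_absent_auc(self):
        rep = compute_metrics(np.ones(4), np.full(4, 0.6))
        assert rep["auc"] is None and rep["aupr"] is None

    def test_counts_partition_sample(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 30)
        rep = compute_metrics(y, rng.random(30))
        assert rep["TP"] + rep["TN"] + rep["FP"] + rep["FN"] == 30


FAST_PIPE = {
    "metapath_params": dict(embed_dim=6, heads=2, instance_cap=8, epochs=15),
    "mf_params": dict(rank=4, max_iter=60),
    "sage_params": dict(embed_dim=6, epochs=15),
}


class TestCrossValidation:
    def test_dataset_is_balanced_with_disjoint_folds(self):
        net = tiny_net(1)
        pairs, y, folds = build_dataset(net, seed=0)
        assert y.sum() * 2 == len(y)
        assert len({tuple(p) for p in pairs}) == len(pairs)
        assert set(folds) == set(range(5))

    def test_no_test_positive_reaches_similarity_computation(self, monkeypatch):
        """Leakage audit: every similarity bundle inside run_cv must be
        computed from a network whose association matrix is missing the
        held-out fold's positive edges."""
        net = tiny_net(2)
        pairs, y, folds = build_dataset(net, seed=5)
        seen = []
        real = ev.compute_similarity_bundle

        def spy(net_arg, *args, **kwargs):
            seen.append(net_arg.A_CD.copy())
            return real(net_arg, *args, **kwargs)

        monkeypatch.setattr(ev, "compute_similarity_bundle", spy)
        run_cv(net, seed=5, pipeline_params=FAST_PIPE)
        assert len(seen) == 5
        for fold, A in enumerate(seen):
            test_pos = [(i, j) for (i, j), label, f in zip(pairs, y, folds)
                        if label == 1 and f == fold]
            assert test_pos, "fold without positives would be vacuous"
            for i, j in test_pos:
                assert A[i, j] == 0

    def test_same_seed_reproduces_report(self):
        net = tiny_net(4)
        a, ta = run_cv(net, seed=2, pipeline_params=FAST_PIPE)
        b, tb = run_cv(net, seed=2, pipeline_params=FAST_PIPE)
        assert a.to_dict() == b.to_dict()
        assert ta.equals(tb)

    def test_paper_mode_uses_single_bundle(self, monkeypatch):
        net = tiny_net(2)
        calls = []
        real = ev.compute_similarity_bundle

        def spy(net_arg, *args, **kwargs):
            calls.append(1)
            return real(net_arg, *args, **kwargs)

        monkeypatch.setattr(ev, "compute_similarity_bundle", spy)
        run_cv(net, seed=1, paper_mode=True, pipeline_params=FAST_PIPE)
        assert len(calls) == 1

    def test_prediction_table_covers_all_pairs_once(self):
        net = tiny_net(6)
        _, table = run_cv(net, seed=3, pipeline_params=FAST_PIPE)
        n_pairs = 2 * int(net.A_CD.sum())
        assert len(table) == n_pairs
        assert set(table.columns) >= {"circRNA", "disease", "p_fused", "label"}
        assert table["p_fused"].between(0, 1).all()
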
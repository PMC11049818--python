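"""Balancing, splits, k-fold, metrics, AUC, attribution aggregation, baselines."""

import numpy as np
import pytest

from druggability import evaluation as ev
from druggability.evaluation import (
    AttributionMatrix,
    ConfusionCounts,
    aggregate_group_importance,
    balance_by_downsampling,
    compute_metrics,
    kfold_plan,
    roc_auc,
    stratified_three_way_split,
)
from druggability.sequence_io import ProteinRecord, ValidationError


def recs(n, label, prefix):
    return [ProteinRecord(id=f"{prefix}{i}", sequence="M", label=label) for i in range(n)]


class TestBalancing:
    def test_pharos_style_downsampling_to_704_per_class(self):
        balanced = balance_by_downsampling(recs(704, 1, "p"), recs(5516, 0, "n"), seed=42)
        labels = [r.label for r in balanced]
        assert labels.count(1) == 704 and labels.count(0) == 704

    def test_equal_classes_pass_through(self):
        pos, neg = recs(5, 1, "p"), recs(5, 0, "n")
        assert balance_by_downsampling(pos, neg, seed=0) == pos + neg

    def test_same_seed_same_selection_different_seed_differs(self):
        pos, neg = recs(10, 1, "p"), recs(400, 0, "n")
        a = balance_by_downsampling(pos, neg, seed=1)
        b = balance_by_downsampling(pos, neg, seed=1)
        c = balance_by_downsampling(pos, neg, seed=2)
        assert a == b
        assert {r.id for r in a} != {r.id for r in c}


class TestSplit:
    @pytest.mark.parametrize("n_pos,n_neg,expected", [
        (1224, 1319, {1: (784, 196, 244), 0: (845, 211, 263)}),
        (704, 704, {1: (452, 112, 140), 0: (452, 112, 140)}),
    ])
    def test_two_stage_floor_split_counts(self, n_pos, n_neg, expected):
        records = recs(n_pos, 1, "p") + recs(n_neg, 0, "n")
        sp = stratified_three_way_split(records, seed=0)
        for cls, (tr, va, te) in expected.items():
            assert sp.counts.train[cls] == tr
            assert sp.counts.val[cls] == va
            assert sp.counts.test[cls] == te

    def test_ten_samples_split_7_1_2(self):
        sp = stratified_three_way_split(recs(10, 1, "p") + recs(10, 0, "n"), seed=0)
        assert (sp.counts.train[1], sp.counts.val[1], sp.counts.test[1]) == (7, 1, 2)

    def test_index_sets_disjoint_and_exhaustive_and_seeded(self):
        records = recs(37, 1, "p") + recs(23, 0, "n")
        sp1 = stratified_three_way_split(records, seed=5)
        sp2 = stratified_three_way_split(records, seed=5)
        all_idx = np.concatenate([sp1.train_idx, sp1.val_idx, sp1.test_idx])
        assert sorted(all_idx.tolist()) == list(range(60))
        np.testing.assert_array_equal(sp1.train_idx, sp2.train_idx)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValidationError):
            stratified_three_way_split(recs(2, 1, "p") + recs(10, 0, "n"), seed=0)


class TestKFold:
    def test_even_division_gives_equal_holdouts(self):
        folds = kfold_plan(np.arange(10), [0, 1] * 5, k=5, seed=0)
        assert [len(h) for _, h in folds] == [2] * 5

    def test_remainder_spread_over_folds(self):
        folds = kfold_plan(np.arange(11), [0, 1] * 5 + [0], k=5, seed=0)
        assert sorted(len(h) for _, h in folds) == [2, 2, 2, 2, 3]

    def test_holdouts_partition_the_index_set(self):
        idx = np.arange(40, 63)
        y = np.r_[np.zeros(12), np.ones(11)].astype(int)
        folds = kfold_plan(idx, y, k=5, seed=1)
        union = np.sort(np.concatenate([h for _, h in folds]))
        np.testing.assert_array_equal(union, idx)
        for i, (_, a) in enumerate(folds):
            for _, b in folds[i + 1:]:
                assert not set(a) & set(b)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValidationError):
            kfold_plan(np.arange(10), [0, 1] * 5, k=1, seed=0)


def sklearn_metrics_oracle(c: ConfusionCounts):
    """Independent oracle: rebuild label vectors, use sklearn's metric suite."""
    from sklearn import metrics as skm

    y_true = [1] * c.TP + [1] * c.FN + [0] * c.TN + [0] * c.FP
    y_pred = [1] * c.TP + [0] * c.FN + [0] * c.TN + [1] * c.FP
    sn = c.TP / (c.TP + c.FN) if c.TP + c.FN else 0.0
    sp = c.TN / (c.TN + c.FP) if c.TN + c.FP else 0.0
    return {
        "ACC": skm.accuracy_score(y_true, y_pred),
        "P": skm.precision_score(y_true, y_pred, zero_division=0),
        "SN": sn,
        "SP": sp,
        "F1": skm.f1_score(y_true, y_pred, zero_division=0),
        "MCC": skm.matthews_corrcoef(y_true, y_pred),
    }


class TestMetrics:
    def test_perfect_prediction(self):
        r = compute_metrics(ConfusionCounts(TP=5, FP=0, TN=5, FN=0))
        assert (r.ACC, r.P, r.SN, r.SP, r.F1, r.MCC) == (1, 1, 1, 1, 1, 1)

    def test_worked_example(self):
        r = compute_metrics(ConfusionCounts(TP=2, FP=1, TN=3, FN=0))
        assert r.ACC == pytest.approx(5 / 6)
        assert r.P == pytest.approx(2 / 3)
        assert r.SN == 1.0
        assert r.SP == pytest.approx(3 / 4)
        assert r.F1 == pytest.approx(0.8)
        assert r.MCC == pytest.approx(6 / np.sqrt(72))

    def test_anti_perfect_prediction(self):
        r = compute_metrics(ConfusionCounts(TP=0, FP=3, TN=0, FN=3))
        assert r.ACC == 0.0 and r.MCC == -1.0

    def test_zero_denominator_mcc_convention(self):
        r = compute_metrics(ConfusionCounts(TP=0, FP=0, TN=4, FN=0))
        assert r.MCC == 0.0

    def test_agrees_with_sklearn_oracle_on_random_quadruples(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            c = ConfusionCounts(*[int(v) for v in rng.integers(0, 30, size=4)])
            if c.total == 0 or (c.TP + c.FN == 0) or (c.TN + c.FP == 0):
                continue
            ours = compute_metrics(c)
            oracle = sklearn_metrics_oracle(c)
            for m, val in oracle.items():
                assert getattr(ours, m) == pytest.approx(val, abs=1e-12), m


class TestROC:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.9, 0.8, 0.7, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_three_of_four_pairs_correct(self):
        _, auc = roc_auc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0])
        assert auc == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([0.5, 0.6], [1, 1])

    def test_trapezoid_under_roc_equals_pair_statistic(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = int(rng.integers(6, 40))
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            points, auc = roc_auc(scores, labels)
            trapezoid = np.trapezoid(points[:, 1], points[:, 0])
            assert abs(trapezoid - auc) < 1e-9

    def test_matches_sklearn_reference(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        scores = rng.random(50)
        labels = rng.integers(0, 2, size=50)
        labels[0], labels[1] = 0, 1
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestGroupImportance:
    def test_worked_example(self):
        a = AttributionMatrix(values=[[1, -1, 2, 0], [3, 1, -2, 0]],
                              group_tags=("g1", "g1", "g2", "g2"))
        out = dict(aggregate_group_importance(a))
        assert out["g1"] == pytest.approx(1.5)
        assert out["g2"] == pytest.approx(1.0)

    def test_sorted_descending_and_zero_case(self):
        a = AttributionMatrix(values=np.zeros((3, 6)),
                              group_tags=tuple(["a"] * 3 + ["b"] * 3))
        out = aggregate_group_importance(a)
        assert [s for _, s in out] == [0.0, 0.0]

    def test_homogeneity_under_scaling(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(5, 8))
        tags = tuple(["x"] * 4 + ["y"] * 4)
        base = dict(aggregate_group_importance(AttributionMatrix(vals, tags)))
        scaled = dict(aggregate_group_importance(AttributionMatrix(vals * -2.5, tags)))
        for g in base:
            assert scaled[g] == pytest.approx(2.5 * base[g])


class TestBaselines:
    def test_table_defaults_load_verbatim_into_estimators(self):
        svm = ev.make_baseline("svm")
        assert svm.C == 10 and svm.kernel == "rbf" and svm.gamma == "scale"
        rf = ev.make_baseline("rf")
        assert rf.n_estimators == 1000 and rf.max_depth == 3 and rf.random_state == 0
        nb = ev.make_baseline("nb")
        assert nb.var_smoothing == 1e-9 and nb.priors is None
        xgb = ev.make_baseline("xgb")
        assert xgb.max_depth == 15 and xgb.n_estimators == 2000
        assert xgb.reg_lambda == 0.4 and xgb.scale_pos_weight == 0.8

    def test_all_families_separate_synthetic_blobs(self):
        from sklearn.datasets import make_blobs

        X, y = make_blobs(n_samples=120, centers=2, cluster_std=1.0, random_state=0)
        shrink = {"rf": {"n_estimators": 50}, "xgb": {"n_estimators": 50}}
        out = ev.run_baselines(X, y, k=3, seed=0, overrides=shrink)
        for name, report in out.items():
            assert report.ACC >= 0.95, name

    def test_zero_variance_features_warn_but_nb_runs(self):
        X = np.ones((20, 4))
        y = np.array([0, 1] * 10)
        with pytest.warns(UserWarning, match="zero variance"):
            report = ev.evaluate_split(ev.make_baseline("nb"), X[:16], y[:16], X[16:], y[16:])
        assert 0.0 <= report.ACC <= 1.0
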
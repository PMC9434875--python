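"""Cross-validation protocol and metrics, checked against brute-force oracles."""

import numpy as np
import pytest

from sparseae.evaluation import (
    DEFAULT_METHODS,
    PLSDAClassifier,
    compute_metrics,
    cross_validate_all,
    make_folds,
    run_baseline,
)
from sparseae.sae_core import SAEConfig

FAST_CFG = SAEConfig(epochs=4, hidden_width=16, eta=8.0)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def auc_oracle(y_true, score):
    """Pairwise comparison count: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = score[y_true == 1]
    neg = score[y_true == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def f1_weighted_oracle(y_true, y_pred):
    classes = np.unique(y_true)
    total = 0.0
    for c in classes:
        tp = np.sum((y_pred == c) & (y_true == c))
        fp = np.sum((y_pred == c) & (y_true != c))
        fn = np.sum((y_pred != c) & (y_true == c))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        total += f1 * np.sum(y_true == c)
    return total / len(y_true)


# ---------------------------------------------------------------------------
# make_folds
# ---------------------------------------------------------------------------

class TestMakeFolds:
    def test_partition_property(self, blobs):
        data = blobs(m=8, d=3)
        folds = make_folds(data, 4, seed=0)
        tests = [te for _, te in folds]
        assert all(len(te) == 2 for te in tests)
        assert sorted(np.concatenate(tests)) == list(range(8))
        for tr, te in folds:
            assert not set(tr) & set(te)
            assert sorted(np.concatenate([tr, te])) == list(range(8))

    def test_deterministic_and_stratified(self, blobs):
        data = blobs(m=40, d=3)
        f1, f2 = make_folds(data, 4, seed=3), make_folds(data, 4, seed=3)
        for (a, b), (c, d) in zip(f1, f2):
            assert np.array_equal(a, c) and np.array_equal(b, d)
        for _, te in f1:  # stratification: both classes in every test fold
            assert set(data.y[te]) == {0, 1}

    def test_small_class_falls_back_unstratified(self, blobs):
        data = blobs(m=40, d=3)
        data.y[:] = 0
        data.y[:2] = 1  # class 1 has 2 members < 4 folds
        with pytest.warns(UserWarning):
            folds = make_folds(data, 4, seed=0)
        assert len(folds) == 4

    def test_twelve_splits_from_four_folds_three_seeds(self, blobs):
        data = blobs(m=24, d=3)
        splits = [
            (tuple(tr), tuple(te))
            for seed in (0, 1, 2)
            for tr, te in make_folds(data, 4, seed)
        ]
        assert len(splits) == 12
        assert len(set(splits)) == 12  # all distinct train/test evaluations


# ---------------------------------------------------------------------------
# compute_metrics
# ---------------------------------------------------------------------------

class TestComputeMetrics:
    def test_perfect_and_constant_predictions(self):
        y = np.array([0, 0, 1, 1])
        m = compute_metrics(y, y, np.array([0.1, 0.2, 0.8, 0.9]))
        assert m == {"accuracy": 1.0, "auc": 1.0, "f1": 1.0}
        const = compute_metrics(y, np.zeros(4, int), np.full(4, 0.5))
        assert const["accuracy"] == 0.5

    def test_hand_executed_example(self):
        y_true = np.array([0, 0, 1, 1])
        y_pred = np.array([0, 1, 0, 1])
        score = np.array([0.1, 0.6, 0.4, 0.9])
        m = compute_metrics(y_true, y_pred, score)
        # by hand: 2/4 correct; ROC pairs 3 of 4 ordered; both class F1 = 0.5
        assert m["accuracy"] == 0.5
        assert m["auc"] == 0.75
        assert m["f1"] == 0.5

    def test_agrees_with_bruteforce_oracle_on_random_cases(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            y_true = rng.integers(0, 2, n)
            if y_true.min() == y_true.max():
                y_true[0] = 1 - y_true[0]
            y_pred = rng.integers(0, 2, n)
            score = np.round(rng.random(n), 2)  # rounding forces some ties
            m = compute_metrics(y_true, y_pred, score)
            assert m["auc"] == pytest.approx(auc_oracle(y_true, score), abs=1e-12)
            assert m["f1"] == pytest.approx(
                f1_weighted_oracle(y_true, y_pred), abs=1e-12
            )
            assert m["accuracy"] == pytest.approx(np.mean(y_true == y_pred))

    def test_weighted_f1_on_fixed_confusion_table(self):
        # 3 of class 0 (2 right), 1 of class 1 (1 right):
        # class0: P=1, R=2/3, F1=0.8; class1: P=0.5, R=1, F1=2/3
        # weighted: 0.75*0.8 + 0.25*2/3 = 0.76666...
        y_true = np.array([0, 0, 0, 1])
        y_pred = np.array([0, 0, 1, 1])
        m = compute_metrics(y_true, y_pred, np.array([0.1, 0.1, 0.9, 0.9]))
        assert m["f1"] == pytest.approx(0.75 * 0.8 + 0.25 * (2 / 3), abs=1e-12)

    def test_single_class_auc_undefined(self):
        m = compute_metrics(np.zeros(3, int), np.zeros(3, int), np.full(3, 0.5))
        assert np.isnan(m["auc"])


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

class TestBaselines:
    def test_plsda_separable_blobs(self, blobs):
        data = blobs(m=40, d=5)
        folds = make_folds(data, 4, seed=0)
        rows = run_baseline("plsda", data, folds, seed=0)
        assert rows["accuracy"].mean() == 1.0

    def test_rf_uses_stated_settings(self):
        from sklearn.ensemble import RandomForestClassifier

        from sparseae.evaluation import _fit_predict_baseline  # noqa: F401

        clf = RandomForestClassifier(n_estimators=400, max_depth=3, random_state=0)
        X = np.random.default_rng(0).standard_normal((30, 4))
        y = (np.arange(30) % 2).astype(int)
        clf.fit(X, y)
        assert len(clf.estimators_) == 400
        assert all(t.get_depth() <= 3 for t in clf.estimators_)

    def test_unknown_method_rejected(self, blobs):
        data = blobs(m=16, d=3)
        with pytest.raises(ValueError):
            run_baseline("lda", data, make_folds(data, 2, 0), seed=0)

    def test_all_methods_share_fold_definitions(self, blobs):
        data = blobs(m=24, d=4)
        folds = make_folds(data, 3, seed=1)
        frames = [
            run_baseline(m, data, folds, seed=1, config=FAST_CFG)
            for m in ("plsda", "svm", "nn")
        ]
        for f in frames:
            assert list(f["fold"]) == [0, 1, 2]

    def test_plsda_feature_importance_nonnegative(self, blobs):
        data = blobs(m=30, d=6)
        clf = PLSDAClassifier().fit(data.X, data.y)
        imp = clf.feature_importances_
        assert imp.shape == (6,) and np.all(imp >= 0)


# ---------------------------------------------------------------------------
# the full benchmark
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def report():
    import sparseae.synthetic as syn

    table, _ = syn.generate(syn.preset("tiny"))
    return cross_validate_all(
        table, FAST_CFG, n_folds=4, seeds=(0, 1, 2), keep_details=True
    )


class TestCrossValidateAll:
    def test_twelve_records_per_method(self, report):
        counts = report.splits.groupby("method").size()
        assert set(counts.index) == set(DEFAULT_METHODS)
        assert (counts == 12).all()

    def test_folds_partition_and_disjoint(self, report):
        by_seed = {}
        for (seed, _), (tr, te) in report.folds.items():
            assert not set(tr) & set(te)
            by_seed.setdefault(seed, []).append(te)
        for tests in by_seed.values():
            assert sorted(np.concatenate(tests)) == list(range(60))

    def test_no_preprocessing_leakage(self, report):
        import sparseae.synthetic as syn

        table, _ = syn.generate(syn.preset("tiny"))
        assert report.details  # SAE split details were recorded
        for det in report.details:
            tr = det["train_indices"]
            assert np.allclose(det["pre_mean"], table.X[tr].mean(axis=0))
            assert np.allclose(
                det["pre_scale"],
                np.where(table.X[tr].std(axis=0) < 1e-12, 1.0, table.X[tr].std(axis=0)),
            )

    def test_aggregate_is_mean_of_splits(self, report):
        agg = report.aggregates
        for method in DEFAULT_METHODS:
            sub = report.splits[report.splits["method"] == method]
            assert agg.loc[method, "f1"] == pytest.approx(
                sub["f1"].mean(), abs=1e-12
            )
            assert agg.loc[method, "accuracy"] == pytest.approx(
                sub["accuracy"].mean(), abs=1e-12
            )

    def test_sae_variants_both_present(self, report):
        methods = set(report.splits["method"])
        assert {"sae_huber", "sae_mse"} <= methods
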
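import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcgvf.classify import (
    ConfusionCounts,
    evaluate,
    fit_predict,
    kfold_splits,
    loso_splits,
    metrics,
    undersample,
)


def metrics_oracle(tp, fp, fn, tn):
    """Formula-by-formula reimplementation, independent of bcgvf.classify."""
    sen = tp / (tp + fn) if tp + fn else 0.0
    spe = tn / (tn + fp) if tn + fp else 0.0
    pre = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * sen * pre / (sen + pre) if sen + pre else 0.0
    bacc = (sen + spe) / 2
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / den if den else 0.0
    return sen, spe, pre, f1, bacc, mcc


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(50, 0, 0, 50))
        assert all(v == 1.0 for v in m.as_dict().values())

    def test_hand_evaluated_case(self):
        m = metrics(ConfusionCounts(tp=90, fp=20, fn=10, tn=80))
        assert m.sen == pytest.approx(0.9)
        assert m.spe == pytest.approx(0.8)
        assert m.pre == pytest.approx(0.8182, abs=1e-4)
        assert m.f1 == pytest.approx(0.8571, abs=1e-4)
        assert m.bacc == pytest.approx(0.85)
        assert m.mcc == pytest.approx(0.7035, abs=1e-4)

    def test_all_predicted_positive_convention(self):
        m = metrics(ConfusionCounts(tp=10, fp=10, fn=0, tn=0))
        assert m.sen == 1.0 and m.spe == 0.0 and m.mcc == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 5)

    def test_against_oracle_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            tp, fp, fn, tn = (int(v) for v in rng.integers(0, 200, 4))
            if tp + fp + fn + tn == 0:
                continue
            m = metrics(ConfusionCounts(tp, fp, fn, tn))
            for got, want in zip(m.as_dict().values(), metrics_oracle(tp, fp, fn, tn)):
                assert got == pytest.approx(want, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.tuples(*[st.integers(0, 500)] * 4).filter(lambda c: sum(c) > 0))
    def test_bacc_identity(self, counts):
        m = metrics(ConfusionCounts(*counts))
        assert m.bacc == pytest.approx((m.sen + m.spe) / 2, abs=1e-12)


class TestUndersample:
    def _data(self, n_nvf=100, n_vf=20, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (n_nvf + n_vf, 3))
        y = np.array(["NVF"] * n_nvf + ["VF"] * n_vf)
        return X, y

    def test_balances_to_minority_count(self):
        X, y = self._data()
        Xb, yb = undersample(X, y, seed=1)
        assert np.sum(yb == "VF") == 20
        assert np.sum(yb == "NVF") == 20

    def test_already_balanced_unchanged_counts(self):
        X, y = self._data(30, 30)
        _, yb = undersample(X, y, seed=2)
        assert np.sum(yb == "VF") == 30 and np.sum(yb == "NVF") == 30

    def test_all_minority_rows_kept(self):
        X, y = self._data()
        Xb, yb = undersample(X, y, seed=3)
        minority_rows = {tuple(r) for r in X[y == "VF"]}
        kept = {tuple(r) for r in Xb[yb == "VF"]}
        assert kept == minority_rows

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            undersample(X, np.array(["VF"] * 10), seed=0)

    def test_seeded(self):
        X, y = self._data()
        a = undersample(X, y, seed=7)[0]
        b = undersample(X, y, seed=7)[0]
        np.testing.assert_array_equal(a, b)


class TestKfoldSplits:
    def test_even_folds(self):
        folds = kfold_splits(np.array(["a"] * 100), k=10, seed=0)
        assert len(folds) == 10
        assert all(f.size == 10 for f in folds)

    def test_disjoint_and_exhaustive(self):
        labels = np.array(["a", "b"] * 60)
        folds = kfold_splits(labels, k=10, seed=1)
        allidx = np.concatenate(folds)
        assert np.array_equal(np.sort(allidx), np.arange(120))

    def test_class_ratio_preserved(self):
        labels = np.array(["NVF"] * 120 + ["VF"] * 20)
        folds = kfold_splits(labels, k=10, seed=2)
        for f in folds:
            n_vf = int(np.sum(labels[f] == "VF"))
            assert abs(n_vf - 2) <= 1
            assert abs(np.sum(labels[f] == "NVF") - 12) <= 1

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            kfold_splits(np.array(["a"] * 5), k=10, seed=0)


class TestLosoSplits:
    def test_one_fold_per_subject(self):
        sid = np.repeat([f"S{i}" for i in range(23)], 4)
        folds = loso_splits(sid)
        assert len(folds) == 23

    def test_no_subject_overlap(self):
        sid = np.repeat(["A", "B", "C"], 5)
        folds = loso_splits(sid)
        for f in folds:
            test_subjects = set(sid[f])
            train_subjects = set(np.delete(sid, f))
            assert not test_subjects & train_subjects

    def test_union_covers_dataset(self):
        sid = np.array(["A", "B", "A", "C", "B"])
        folds = loso_splits(sid)
        assert np.array_equal(np.sort(np.concatenate(folds)), np.arange(5))

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            loso_splits(np.array(["A"] * 10))


class TestFitPredict:
    def _separable(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 0.3, (n, 2))
        X[n // 2 :] += 5.0
        y = np.array(["NVF"] * (n // 2) + ["VF"] * (n // 2))
        return X, y

    def test_lr_perfect_on_separable(self):
        X, y = self._separable()
        pred = fit_predict(X, y, X, model="lr", seed=0)
        assert np.all(pred == y)

    def test_rf_reproducible(self):
        X, y = self._separable(seed=1)
        Xt = np.random.default_rng(2).normal(2.5, 2.0, (30, 2))
        a = fit_predict(X, y, Xt, model="rf", seed=5)
        b = fit_predict(X, y, Xt, model="rf", seed=5)
        np.testing.assert_array_equal(a, b)

    def test_label_permutation_near_chance(self):
        rng = np.random.default_rng(3)
        baccs = []
        for rep in range(20):
            X = rng.normal(0, 1, (200, 4))
            y = np.array(["NVF", "VF"])[rng.integers(0, 2, 200)]
            pred = fit_predict(X[:150], y[:150], X[150:], model="lr", seed=rep)
            truth = y[150:]
            tp = np.sum((truth == "VF") & (pred == "VF"))
            fn = np.sum((truth == "VF") & (pred != "VF"))
            tn = np.sum((truth != "VF") & (pred != "VF"))
            fp = np.sum((truth != "VF") & (pred == "VF"))
            m = metrics(ConfusionCounts(int(tp), int(fp), int(fn), int(tn)))
            baccs.append(m.bacc)
        assert abs(np.mean(baccs) - 0.5) <= 0.1

    def test_single_class_train_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            fit_predict(X, np.array(["VF"] * 10), X, model="lr", seed=0)

    def test_unknown_model_rejected(self):
        X, y = self._separable()
        with pytest.raises(ValueError):
            fit_predict(X, y, X, model="svm", seed=0)


class TestEvaluate:
    def _dataset(self, seed=0):
        rng = np.random.default_rng(seed)
        n_sub, per = 6, 30
        X, y, sid = [], [], []
        for s in range(n_sub):
            for i in range(per):
                is_vf = i % 3 == 0
                mu = 3.0 if is_vf else 0.0
                X.append(rng.normal(mu, 1.0, 4))
                y.append("VF" if is_vf else ("SR" if i % 2 else "MA"))
                sid.append(f"S{s}")
        return np.array(X), np.array(y), np.array(sid)

    def test_report_structure(self):
        X, y, sid = self._dataset()
        rep = evaluate(X, y, sid, model="lr", paradigm="kfold10", repeats=2, seed=0)
        assert set(rep.mean) == {"SEN", "SPE", "PRE", "F1", "bACC", "MCC"}
        assert set(rep.sd) == set(rep.mean)
        assert len(rep.per_repeat) == 2

    def test_single_repeat_has_zero_sd(self):
        X, y, sid = self._dataset()
        rep = evaluate(X, y, sid, model="lr", paradigm="loso", repeats=1, seed=0)
        assert all(v == 0.0 for v in rep.sd.values())

    def test_seeded_reproducibility(self):
        X, y, sid = self._dataset()
        a = evaluate(X, y, sid, model="rf", paradigm="kfold10", repeats=2, seed=9)
        b = evaluate(X, y, sid, model="rf", paradigm="kfold10", repeats=2, seed=9)
        assert a.as_dict() == b.as_dict()

    def test_test_sets_never_rebalanced(self):
        # pooled confusion total must equal the full dataset size per repeat
        X, y, sid = self._dataset()
        rep = evaluate(X, y, sid, model="lr", paradigm="kfold10", repeats=2, seed=1)
        for c in rep.confusions:
            assert c.total == len(y)

    def test_separable_loso_high_scores(self):
        X, y, sid = self._dataset(seed=4)
        rep = evaluate(X, y, sid, model="lr", paradigm="loso", repeats=1, seed=0)
        assert rep.mean["SEN"] >= 0.9
        assert rep.mean["SPE"] >= 0.9

    def test_invalid_paradigm_rejected(self):
        X, y, sid = self._dataset()
        with pytest.raises(ValueError):
            evaluate(X, y, sid, paradigm="bootstrap", repeats=1, seed=0)

    def test_bacc_identity_on_reports(self):
        X, y, sid = self._dataset(seed=2)
        rep = evaluate(X, y, sid, model="rf", paradigm="kfold10", repeats=2, seed=3)
        for m in rep.per_repeat:
            assert m.bacc == pytest.approx((m.sen + m.spe) / 2, abs=1e-12)
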
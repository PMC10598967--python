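import numpy as np
import pytest

from m6amstack import evaluation as ev
from m6amstack.evaluation import (ConfusionCounts, auroc, aupr, confusion,
                                  cross_validate, evaluate_scores, metrics,
                                  negative_resampling_experiment)


# ---------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------

def loop_confusion(y, s, thr):
    tp = fp = tn = fn = 0
    for yi, si in zip(y, s):
        pred = si >= thr
        if pred and yi == 1:
            tp += 1
        elif pred and yi == 0:
            fp += 1
        elif not pred and yi == 0:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def pairwise_auroc(y, s):
    """Exhaustive positive/negative pair enumeration, ties count 1/2."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def sweep_aupr(y, s):
    """Explicit threshold sweep over unique scores, step integration."""
    y = np.asarray(y)
    s = np.asarray(s, dtype=float)
    thresholds = sorted(set(s), reverse=True)
    n_pos = int(y.sum())
    area = 0.0
    prev_recall = 0.0
    for t in thresholds:
        pred = s >= t
        tp = int(np.sum(pred & (y == 1)))
        precision = tp / pred.sum()
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


class TestConfusion:
    def test_perfect_scores(self):
        c = confusion([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2], 0.5)
        assert (c.TP, c.FP, c.TN, c.FN) == (2, 0, 2, 0)

    def test_tie_goes_positive(self):
        c = confusion([1, 0], [0.5, 0.5], 0.5)
        assert c.TP == 1 and c.FP == 1 and c.TN == 0 and c.FN == 0

    def test_matches_loop_oracle_random(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 30))
            y = rng.integers(0, 2, size=n)
            s = rng.random(n).round(1)  # coarse grid to force ties
            thr = float(rng.random())
            c = confusion(y, s, thr)
            assert (c.TP, c.FP, c.TN, c.FN) == loop_confusion(y, s, thr)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            confusion([], [], 0.5)

    def test_total_partition(self, rng):
        y = rng.integers(0, 2, size=50)
        s = rng.random(50)
        assert confusion(y, s, 0.5).total == 50


class TestMetrics:
    def test_perfect_classifier(self):
        r = metrics(ConfusionCounts(TP=5, FP=0, TN=5, FN=0))
        assert (r.Sn, r.Sp, r.ACC, r.MCC) == (1.0, 1.0, 1.0, 1.0)

    def test_hand_computed_case(self):
        # Sn=3/4, Sp=2/4, ACC=5/8, MCC=(6-2)/sqrt(4*3*5*4)=4/15.49=0.2582
        r = metrics(ConfusionCounts(TP=3, FN=1, TN=2, FP=2))
        assert r.Sn == pytest.approx(0.75)
        assert r.Sp == pytest.approx(0.5)
        assert r.ACC == pytest.approx(0.625)
        assert r.MCC == pytest.approx(0.2582, abs=5e-5)

    def test_zero_denominator_flagged(self):
        r = metrics(ConfusionCounts(TP=0, FN=0, TN=3, FP=1))
        assert r.Sn == 0.0 and "Sn" in r.degenerate
        assert r.MCC == 0.0 and "MCC" in r.degenerate

    def test_mcc_bounds_random(self, rng):
        for _ in range(500):
            tp, fp, tn, fn = rng.integers(0, 20, size=4)
            r = metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            assert -1.0 <= r.MCC <= 1.0

    def test_balanced_acc_identity(self, rng):
        # on balanced data ACC == (Sn+Sp)/2
        for _ in range(100):
            n = int(rng.integers(1, 15))
            y = np.r_[np.ones(n), np.zeros(n)]
            s = rng.random(2 * n)
            r = metrics(confusion(y, s, 0.5))
            assert r.ACC == pytest.approx((r.Sn + r.Sp) / 2)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_all_ties(self):
        assert auroc([1, 0, 1, 0], [0.5] * 4) == 0.5

    def test_matches_pair_enumeration(self, rng):
        for _ in range(500):
            n = int(rng.integers(2, 21))
            y = np.r_[1, 0, rng.integers(0, 2, size=n - 2)]
            s = rng.random(n).round(1)
            assert auroc(y, s) == pytest.approx(pairwise_auroc(y, s))

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auroc([1, 1], [0.5, 0.4])


class TestAupr:
    def test_perfect_separation(self):
        assert aupr([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == pytest.approx(1.0)

    def test_matches_sweep_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 21))
            y = np.r_[1, 0, rng.integers(0, 2, size=n - 2)]
            s = rng.random(n).round(1)
            assert aupr(y, s) == pytest.approx(sweep_aupr(y, s))

    def test_uninformative_scores_approach_prevalence(self, rng):
        n = 20000
        pi = 0.3
        y = (rng.random(n) < pi).astype(int)
        s = rng.random(n)
        assert aupr(y, s) == pytest.approx(pi, abs=0.03)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            aupr([0, 0], [0.5, 0.4])


class TestEvaluateScores:
    def test_report_fields(self, rng):
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        s = rng.random(40)
        r = evaluate_scores(y, s)
        assert 0 <= r.AUROC <= 1 and 0 <= r.AUPR <= 1
        assert r.n_pos + r.n_neg == 40

    def test_mcc_zero_for_label_independent_predictions(self, rng):
        vals = []
        for i in range(200):
            y = np.r_[np.ones(10), np.zeros(10)].astype(int)
            s = np.random.default_rng(i).random(20)
            vals.append(evaluate_scores(y, s).MCC)
        assert abs(np.mean(vals)) < 0.05  # Monte-Carlo null


# ---------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------

class _PerfectStub:
    """Scores equal a deterministic function of X that the labels follow."""

    def fit(self, X, y):
        return self

    def predict_scores(self, X):
        return X[:, 0]


class TestCrossValidate:
    def _xy(self, n=40):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=n)
        X = np.c_[y.astype(float), rng.random(n)]
        return X, y

    def test_perfect_stub_gives_acc_1_sd_0(self):
        X, y = self._xy()
        s = cross_validate(_PerfectStub, X, y, k=5, seed=0)
        assert s.mean["ACC"] == 1.0
        assert s.sd["ACC"] == 0.0

    def test_fold_count(self):
        X, y = self._xy()
        s = cross_validate(_PerfectStub, X, y, k=5, repeats=3, seed=0)
        assert len(s.folds) == 15

    def test_stratified_fold_sizes(self):
        X = np.zeros((30, 2))
        y = np.r_[np.ones(12), np.zeros(18)].astype(int)

        sizes = []

        class Spy:
            def fit(self, Xtr, ytr):
                sizes.append((int(ytr.sum()), int(len(ytr) - ytr.sum())))
                return self

            def predict_scores(self, X):
                return np.full(len(X), 0.5)

        cross_validate(Spy, X, y, k=3, seed=0)
        pos_counts = {p for p, _ in sizes}
        neg_counts = {n for _, n in sizes}
        assert max(pos_counts) - min(pos_counts) <= 1
        assert max(neg_counts) - min(neg_counts) <= 1

    def test_determinism(self):
        X, y = self._xy()
        s1 = cross_validate(_PerfectStub, X, y, k=4, seed=3)
        s2 = cross_validate(_PerfectStub, X, y, k=4, seed=3)
        assert s1.mean == s2.mean and s1.sd == s2.sd

    def test_k1_rejected(self):
        X, y = self._xy()
        with pytest.raises(ValueError):
            cross_validate(_PerfectStub, X, y, k=1)


class TestNegativeResampling:
    def test_deterministic_and_shapes(self):
        rng = np.random.default_rng(0)
        X_pos = np.c_[np.ones(20), rng.random(20)]
        X_neg = np.c_[np.zeros(100), rng.random(100)]
        out1 = negative_resampling_experiment(_PerfectStub, X_pos, X_neg,
                                              n_repeats=2, ratio=1.0, k=4,
                                              seed=5)
        out2 = negative_resampling_experiment(_PerfectStub, X_pos, X_neg,
                                              n_repeats=2, ratio=1.0, k=4,
                                              seed=5)
        assert len(out1) == 2
        assert out1[0].mean == out2[0].mean

    def test_ratio_4_shape(self):
        rng = np.random.default_rng(0)
        X_pos = np.c_[np.ones(10), rng.random(10)]
        X_neg = np.c_[np.zeros(50), rng.random(50)]

        seen = []

        class Spy(_PerfectStub):
            def fit(self, X, y):
                seen.append((int(y.sum()), int(len(y) - y.sum())))
                return self

        negative_resampling_experiment(Spy, X_pos, X_neg, n_repeats=1,
                                       ratio=4.0, k=2, seed=0)
        total_pos = sum(p for p, _ in seen)
        total_neg = sum(n for _, n in seen)
        assert total_neg == 4 * total_pos  # 1:4 design

    def test_insufficient_pool(self):
        X_pos = np.ones((10, 2))
        X_neg = np.zeros((5, 2))
        with pytest.raises(ValueError):
            negative_resampling_experiment(_PerfectStub, X_pos, X_neg,
                                           ratio=1.0)
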
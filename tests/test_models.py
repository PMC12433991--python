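import math

import numpy as np
import pandas as pd
import pytest

from rapep import evaluate_metrics, l1_select, mrmr_select, train_cv
from rapep.models import metrics_from_counts


def brute_metrics(tp, fp, tn, fn):
    """Direct transcription of the standard confusion-matrix formulas."""
    sens = 100 * tp / (tp + fn) if tp + fn else 0.0
    spec = 100 * tn / (tn + fp) if tn + fp else 0.0
    acc = 100 * (tp + tn) / (tp + tn + fp + fn)
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / den if den else 0.0
    n = tp + tn + fp + fn
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / n**2
    kappa = (p_o - p_e) / (1 - p_e) if p_e != 1 else 0.0
    return sens, spec, acc, f1, mcc, kappa


def auc_pair_counting(scores, labels):
    scores, labels = np.asarray(scores), np.asarray(labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    wins = sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in pos for b in neg)
    return wins / (len(pos) * len(neg))


class TestEvaluateMetrics:
    def test_perfect_classifier(self):
        r = evaluate_metrics([1.0] * 5 + [0.0] * 5, [1] * 5 + [0] * 5)
        assert (r.sensitivity, r.specificity, r.accuracy) == (100.0, 100.0, 100.0)
        assert (r.f1, r.mcc, r.auc) == (1.0, 1.0, 1.0)

    def test_inverted_labels_give_anti_classifier(self):
        r = evaluate_metrics([1.0] * 5 + [0.0] * 5, [0] * 5 + [1] * 5)
        assert r.mcc == -1.0 and r.auc == 0.0

    def test_hand_worked_confusion_matrix(self):
        # tp=3, fp=1, tn=2, fn=2
        scores = [1, 1, 1, 0, 0, 1, 0, 0]
        labels = [1, 1, 1, 1, 1, 0, 0, 0]
        r = evaluate_metrics(scores, labels)
        assert (r.tp, r.fp, r.tn, r.fn) == (3, 1, 2, 2)
        assert r.sensitivity == pytest.approx(60.0)
        assert r.specificity == pytest.approx(66.667, abs=1e-3)
        assert r.accuracy == pytest.approx(62.5)
        assert r.f1 == pytest.approx(0.667, abs=1e-3)
        assert r.mcc == pytest.approx(0.258, abs=1e-3)

    def test_counts_agree_with_brute_formulas(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            tp, fp, tn, fn = rng.integers(0, 25, size=4)
            if tp + fp + tn + fn == 0:
                continue
            r = metrics_from_counts(int(tp), int(fp), int(tn), int(fn))
            exp = brute_metrics(int(tp), int(fp), int(tn), int(fn))
            got = (r.sensitivity, r.specificity, r.accuracy, r.f1, r.mcc, r.kappa)
            assert got == pytest.approx(exp, abs=1e-12)

    def test_auc_equals_pair_counting_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = int(rng.integers(4, 50))
            labels = rng.integers(0, 2, n)
            labels[:2] = [0, 1]
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # force ties
            r = evaluate_metrics(scores, labels)
            assert r.auc == pytest.approx(auc_pair_counting(scores, labels), abs=1e-12)

    def test_single_class_auc_is_nan_but_counts_reported(self):
        r = evaluate_metrics([0.9, 0.2], [1, 1])
        assert math.isnan(r.auc) and r.tp == 1 and r.fn == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_metrics([0.5], [1, 0])


def _toy_matrix(n=200, informative=True, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([1, 0], n // 2)
    cols = {f"noise{i}": rng.normal(size=n) for i in range(5)}
    if informative:
        cols["signal"] = 3.0 * y + rng.normal(scale=0.1, size=n)
    return pd.DataFrame(cols), y


class TestTrainCV:
    def test_separable_data_reaches_perfect_ranking(self):
        m, y = _toy_matrix()
        bundle, report = train_cv(m, y, "LR", grid={"clf__C": [1.0]}, seed=0)
        assert report.aggregate.auc == 1.0
        assert len(report.per_fold) == 5

    def test_shuffled_labels_give_null_auc(self):
        m, y = _toy_matrix(seed=2)
        rng = np.random.default_rng(3)
        y = rng.permutation(y)
        _, report = train_cv(m, y, "LR", grid={"clf__C": [1.0]}, seed=0)
        assert 0.4 <= report.aggregate.auc <= 0.6

    def test_same_seed_reproduces_report(self):
        m, y = _toy_matrix(seed=5)
        _, r1 = train_cv(m, y, "RF", grid={"clf__n_estimators": [50]}, seed=9)
        _, r2 = train_cv(m, y, "RF", grid={"clf__n_estimators": [50]}, seed=9)
        assert r1.aggregate.as_dict() == r2.aggregate.as_dict()
        assert r1.best_params == r2.best_params

    def test_out_of_fold_predictions_do_not_leak(self):
        # a 1-NN memorizer scores ~perfectly in-fold; out-of-fold it must not
        m, y = _toy_matrix(informative=False, seed=7)
        _, report = train_cv(m, y, "KNN", grid={"clf__n_neighbors": [1]}, seed=0)
        assert report.aggregate.auc < 0.7

    def test_unknown_algorithm_rejected(self):
        m, y = _toy_matrix()
        with pytest.raises(ValueError, match="unknown algorithm"):
            train_cv(m, y, "SVM9000")

    def test_bundle_predicts_with_named_features_only(self):
        m, y = _toy_matrix()
        bundle, _ = train_cv(m, y, "LR", grid={"clf__C": [1.0]}, seed=0)
        with pytest.raises(ValueError, match="missing"):
            bundle.predict_proba(m.drop(columns=["signal"]))
        proba = bundle.predict_proba(m)
        assert proba.shape == (len(m),) and np.all((proba >= 0) & (proba <= 1))


class TestL1Select:
    def test_predictive_feature_selected(self):
        m, y = _toy_matrix(seed=4)
        selected = l1_select(m, y, C=1.0)
        assert "signal" in selected

    def test_extreme_penalty_empties_selection(self):
        m, y = _toy_matrix(seed=4)
        with pytest.warns(UserWarning, match="no features"):
            selected = l1_select(m, y, C=1e-6)
        assert selected == []

    def test_duplicated_informative_column_still_covered(self):
        m, y = _toy_matrix(seed=8)
        m = m.assign(signal_copy=m["signal"].to_numpy())
        selected = l1_select(m, y, C=1.0)
        assert {"signal", "signal_copy"} & set(selected)


class TestMrmrSelect:
    def _matrix(self):
        rng = np.random.default_rng(6)
        n = 120
        y = np.repeat([1, 0], n // 2)
        m = pd.DataFrame(
            {
                "best": y + rng.normal(scale=0.05, size=n),
                "dup_of_best": y + rng.normal(scale=0.05, size=n) * 1.0,
                "second": -1.0 * y + rng.normal(scale=0.4, size=n),
                "noise": rng.normal(size=n),
            }
        )
        m["dup_of_best"] = m["best"]  # exact duplicate
        return m, y

    def test_first_pick_is_max_relevance(self):
        m, y = self._matrix()
        assert mrmr_select(m, y, 1)[0] in ("best", "dup_of_best")

    def test_exact_duplicate_deferred_to_informative_feature(self):
        m, y = self._matrix()
        picked = mrmr_select(m, y, 2)
        assert set(picked) != {"best", "dup_of_best"}

    def test_selecting_all_is_a_permutation(self):
        m, y = self._matrix()
        assert sorted(mrmr_select(m, y, m.shape[1])) == sorted(m.columns)

    def test_bad_n_select(self):
        m, y = self._matrix()
        with pytest.raises(ValueError):
            mrmr_select(m, y, 0)
        with pytest.raises(ValueError):
            mrmr_select(m, y, 99)
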
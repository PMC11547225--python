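"""Logistic fitting, LOOCV, ROC/AUC, Youden cutoff, detection rates."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sermeth import classify


class TestFitLogistic:
    def test_matches_reference_optimizer(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 2))
        y = (X[:, 0] + 0.5 * rng.normal(size=20) > 0).astype(float)
        fit = classify.fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert np.allclose(fit.coef, ref.params, atol=1e-6)

    def test_symmetric_data_zero_intercept(self):
        X = np.array([-2.0, -1.0, 1.0, 2.0])
        y = np.array([0, 0, 1, 1])
        fit = classify.fit_logistic(X, y)
        assert abs(fit.coef[0]) < 1e-6

    def test_complete_separation_flagged_not_suppressed(self):
        X = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        fit = classify.fit_logistic(X, y)
        assert fit.separated
        p = classify.predict_proba(fit, X)
        assert (p[y == 1] > 0.99).all() and (p[y == 0] < 0.01).all()

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            classify.fit_logistic(np.arange(4.0), np.ones(4))


class TestLoocv:
    def test_three_samples_three_predictions(self):
        X = np.array([0.0, 1.0, 2.0])
        y = np.array([0, 1, 1])
        probs = classify.loocv_probabilities(X, y)
        assert probs.shape == (3,)
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_duplicated_rows_get_equal_probabilities(self):
        X = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0])
        y = np.array([0, 0, 0, 0, 1, 1])
        probs = classify.loocv_probabilities(X, y)
        assert probs[0] == pytest.approx(probs[1])
        assert probs[4] == pytest.approx(probs[5])

    def test_loocv_auc_no_better_than_resubstitution_when_separable(self):
        rng = np.random.default_rng(1)
        X = np.concatenate([rng.normal(0, 1, 10), rng.normal(3, 1, 10)])
        y = np.repeat([0, 1], 10)
        loo = classify.loocv_probabilities(X, y)
        fit = classify.fit_logistic(X, y)
        resub = classify.predict_proba(fit, X)
        auc_loo, _, _ = classify.roc_auc(loo, y)
        auc_res, _, _ = classify.roc_auc(resub, y)
        assert auc_loo <= auc_res + 1e-12

    def test_labels_independent_of_features_never_beat_chance(self):
        # pooled LOOCV probabilities are pessimistic under the null (the
        # held-out label anti-correlates with the training intercept), so
        # the check is one-sided: no optimistic bias
        rng = np.random.default_rng(2)
        aucs = []
        for _ in range(10):
            X = rng.normal(size=40)
            y = rng.integers(0, 2, size=40)
            if len(np.unique(y)) < 2:
                continue
            probs = classify.loocv_probabilities(X, y)
            aucs.append(classify.roc_auc(probs, y)[0])
        assert np.mean(aucs) <= 0.5 + 0.05


def auc_by_pair_counting(p, y):
    pos = p[y == 1]
    neg = p[y == 0]
    wins = sum(1.0 if a > b else 0.5 if a == b else 0.0
               for a in pos for b in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _, _ = classify.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_ties_give_half(self):
        auc, _, _ = classify.roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert auc == 0.5

    def test_four_sample_toy_and_swap(self):
        auc, _, _ = classify.roc_auc([0.9, 0.8, 0.7, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        auc2, _, _ = classify.roc_auc([0.9, 0.7, 0.8, 0.1], [1, 1, 0, 0])
        assert auc2 == 0.75

    def test_rank_auc_equals_pair_counting_on_random_fixtures(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(4, 13))
            y = np.zeros(n, dtype=int)
            y[: int(rng.integers(1, n))] = 1
            rng.shuffle(y)
            if y.sum() in (0, n):
                continue
            p = np.round(rng.uniform(size=n), 1)  # coarse grid forces ties
            auc, _, _ = classify.roc_auc(p, y)
            assert auc == pytest.approx(auc_by_pair_counting(p, y), abs=1e-12)

    def test_rank_auc_equals_trapezoidal_curve_area(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            y = np.array([1, 1, 1, 0, 0, 0, 1, 0])
            p = np.round(rng.uniform(size=8), 1)
            auc, _, curve = classify.roc_auc(p, y)
            area = np.trapezoid(curve["tpr"], curve["fpr"])
            assert auc == pytest.approx(area, abs=1e-12)

    def test_delong_interval_ordered_and_bounded(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=30)
        y = (p + rng.normal(0, 0.3, 30) > 0.5).astype(int)
        auc, (lo, hi), _ = classify.roc_auc(p, y)
        assert 0 <= lo <= auc <= hi <= 1


class TestYouden:
    def test_perfectly_separating_threshold_reaches_j_one(self):
        cutoff, sens, spec = classify.youden_cutoff([0.9, 0.8, 0.2, 0.1],
                                                    [1, 1, 0, 0])
        assert sens + spec - 1 == pytest.approx(1.0)
        assert 0.2 < cutoff <= 0.8

    def test_all_equal_probabilities_give_j_zero(self):
        _, sens, spec = classify.youden_cutoff([0.5] * 4, [1, 1, 0, 0])
        assert sens + spec - 1 == pytest.approx(0.0)

    def test_matches_exhaustive_threshold_scan(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = 10
            y = np.array([1] * 4 + [0] * 6)
            rng.shuffle(y)
            p = np.round(rng.uniform(size=n), 1)
            cutoff, sens, spec = classify.youden_cutoff(p, y)
            best_j = max(
                ((p >= t) & (y == 1)).sum() / y.sum()
                + ((p < t) & (y == 0)).sum() / (1 - y).sum() - 1
                for t in np.unique(p)
            )
            assert sens + spec - 1 == pytest.approx(best_j, abs=1e-12)


def fisher_exact_enumeration(a, b, c, d):
    import math

    row1, col1, n = a + b, a + c, a + b + c + d

    def pmf(k):
        return (math.comb(col1, k) * math.comb(n - col1, row1 - k)
                / math.comb(n, row1))

    obs = pmf(a)
    return sum(pmf(k) for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
               if pmf(k) <= obs + 1e-12)


class TestDetectionRates:
    def _setup(self):
        idx = [f"s{i}" for i in range(8)]
        probs = pd.Series([0.9, 0.8, 0.7, 0.2, 0.6, 0.1, 0.3, 0.4], index=idx)
        labels = pd.Series([1, 1, 1, 1, 1, 1, 0, 0], index=idx)
        subtype = pd.Series(["SSL", "SSL", "TSA", "TSA", "SSL", "TSA", "x", "x"],
                            index=idx)
        location = pd.Series(["distal", "proximal", "distal", "proximal",
                              "distal", "proximal", "distal", "distal"], index=idx)
        return probs, labels, subtype, location

    def test_cutoff_below_everything_detects_all(self):
        probs, labels, subtype, _ = self._setup()
        table, _ = classify.detection_rates(probs, labels, 0.0, subtype)
        assert (table["detection_rate_pct"] == 100.0).all()

    def test_rates_and_fisher_match_enumeration(self):
        probs, labels, subtype, location = self._setup()
        table, loc_p = classify.detection_rates(probs, labels, 0.5, subtype, location)
        ssl = table.set_index("subtype").loc["SSL"]
        assert ssl["detection_rate_pct"] == pytest.approx(100.0)
        # detected x distal table: (3,1 | 0,2)
        assert loc_p == pytest.approx(fisher_exact_enumeration(3, 1, 0, 2), abs=1e-12)
        assert loc_p == pytest.approx(
            stats.fisher_exact([[3, 1], [0, 2]])[1], abs=1e-12)

    def test_subtype_without_positives_reported_as_nan(self):
        probs, labels, subtype, _ = self._setup()
        table, _ = classify.detection_rates(
            probs, labels, 0.5, subtype.replace("x", "EMPTY"))
        assert "EMPTY" not in set(table["subtype"])  # only positives enumerated

    def test_missing_metadata_raises(self):
        probs, labels, subtype, _ = self._setup()
        with pytest.raises(KeyError):
            classify.detection_rates(probs, labels, 0.5, subtype.iloc[:2])


class TestEvaluateContrast:
    def test_synthetic_marker_panel_recovers_generating_separation(self):
        rng = np.random.default_rng(7)
        n = 80
        groups = np.array(["NCF"] * 25 + ["LR-SL"] * 15 + ["HR-HP"] * 20
                          + ["HR-SP"] * 20)
        mu = {"NCF": 0.3, "LR-SL": 0.35, "HR-HP": 1.2, "HR-SP": 1.4}
        feats = pd.DataFrame(
            {"DMR7": [rng.normal(mu[g], 0.35) for g in groups]},
            index=[f"s{i}" for i in range(n)])
        sheet = pd.DataFrame({"group": groups}, index=feats.index)
        spec = classify.ContrastSpec(
            "NSN_vs_HRSL", frozenset({"HR-HP", "HR-SP"}),
            frozenset({"NCF", "LR-SL"}), ("DMR7",))
        roc = classify.evaluate_contrast(feats, sheet, spec)
        # Bayes-optimal AUC for N(0.32,.35) vs N(1.3,.35) is ~0.975
        assert abs(roc.auc - 0.975) < 0.05
        assert roc.auc_ci[0] <= roc.auc <= roc.auc_ci[1]
        # reported operating point lies on the reported curve
        on_curve = np.isclose(roc.curve["tpr"], roc.sensitivity) & np.isclose(
            1 - roc.curve["fpr"], roc.specificity)
        assert on_curve.any()
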
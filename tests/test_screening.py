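"""MRMR ranking, logistic fitting, published model, CV metrics, ROC."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import mannwhitneyu

from pulsescreen.errors import SeparationError
from pulsescreen.screening import (
    PUBLISHED_FEATURES,
    evaluate_cv,
    fit_lra,
    mrmr_rank,
    published_model,
    roc_analysis,
    score,
    select_model_size,
)


def _oracle_mi(a, b):
    """Mutual information from the joint contingency table, nats."""
    a, b = np.asarray(a), np.asarray(b)
    mi = 0.0
    n = len(a)
    for va in np.unique(a):
        for vb in np.unique(b):
            p_ab = np.mean((a == va) & (b == vb))
            if p_ab > 0:
                mi += p_ab * np.log(p_ab / (np.mean(a == va) * np.mean(b == vb)))
    return mi


def _oracle_bins(x):
    edges = np.quantile(x, [0.25, 0.5, 0.75])
    return np.searchsorted(edges, x, side="right")


def _oracle_mrmr(X, y):
    """Independent brute-force evaluation of the greedy quotient criterion:
    at each step every remaining candidate is scored from scratch."""
    m = X.shape[1]
    binned = [_oracle_bins(X[:, j]) for j in range(m)]
    rel = [_oracle_mi(binned[j], y) for j in range(m)]
    order, remaining = [], list(range(m))
    while remaining:
        scores = []
        for j in remaining:
            if not order:
                s = rel[j]
            else:
                red = np.mean([_oracle_mi(binned[j], binned[s]) for s in order])
                s = rel[j] / (red + 1e-12)
            scores.append((s, rel[j], -j))
        best = max(zip(scores, remaining))[1]
        order.append(best)
        remaining.remove(best)
    return order


class TestMrmrRank:
    def test_perfect_feature_ranked_first(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 100)
        X = np.column_stack([rng.normal(size=100), y.astype(float),
                             rng.normal(size=100)])
        ranking = mrmr_rank(X, y)
        assert ranking[0][0] == 1

    def test_duplicate_informative_feature_penalized(self):
        rng = np.random.default_rng(1)
        n = 400
        y = rng.integers(0, 2, n)
        strong = y + rng.normal(0, 0.4, n)
        weak = y + rng.normal(0, 2.0, n)
        X = np.column_stack([strong, strong.copy(), weak, rng.normal(size=n)])
        order = [j for j, _ in mrmr_rank(X, y)]
        # the duplicate (index 1) must fall below the independent weak feature
        assert order.index(1) > order.index(2)

    @pytest.mark.parametrize("seed", range(5))
    def test_greedy_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 100
        y = rng.integers(0, 2, n)
        X = np.column_stack(
            [
                y + rng.normal(0, s, n)
                for s in (0.5, 0.8, 1.5, 3.0)
            ]
            + [rng.normal(size=n)]
        )
        got = [j for j, _ in mrmr_rank(X, y)]
        assert got == _oracle_mrmr(X, y)

    def test_constant_feature_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 50)
        X = np.column_stack([np.full(50, 3.0), y.astype(float)])
        with pytest.warns(UserWarning, match="constant"):
            ranking = mrmr_rank(X, y)
        assert [j for j, _ in ranking] == [1]


class TestSelectModelSize:
    def test_single_informative_feature_gives_k1(self):
        rng = np.random.default_rng(3)
        n = 200
        y = rng.integers(0, 2, n)
        # wide-margin informative feature: accuracy saturates at k = 1 and
        # ties at larger k resolve to the smallest model
        X = np.column_stack(
            [10.0 * y + rng.normal(0, 0.5, n)]
            + [rng.normal(size=n) for _ in range(3)]
        )
        k, curve, _ = select_model_size(X, y, max_k=4, folds=5, seed=0)
        assert k == 1
        assert len(curve) == 4

    def test_four_signal_features_recovered_most_seeds(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            n = 150
            X = rng.normal(size=(n, 8))
            y = (rng.random(n) < expit(X[:, :4] @ np.full(4, 1.5))).astype(int)
            k, _, _ = select_model_size(X, y, max_k=8, folds=5, seed=seed)
            hits += k == 4
        assert hits >= 0.8 * n_seeds


class TestFitLra:
    def test_null_data_gives_near_zero_coefficients(self):
        rng = np.random.default_rng(4)
        n = 500
        X = rng.normal(size=(n, 3))
        y = rng.integers(0, 2, n)
        model = fit_lra(X, y)
        assert np.all(np.abs(model.coefficients) < 3 * model.standard_errors[1:])

    def test_parameter_recovery_within_3_se(self):
        rng = np.random.default_rng(5)
        n = 2000
        beta = np.array([-1.0, 0.5, -0.25])
        X = rng.normal(size=(n, 2))
        y = (rng.random(n) < expit(beta[0] + X @ beta[1:])).astype(int)
        model = fit_lra(X, y)
        est = np.r_[model.intercept, model.coefficients]
        assert np.all(np.abs(est - beta) <= 3 * model.standard_errors)

    def test_matches_statsmodels_mle(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(6)
        n = 300
        X = rng.normal(size=(n, 2))
        y = (rng.random(n) < expit(0.5 + X @ np.array([1.0, -0.5]))).astype(int)
        ours = fit_lra(X, y)
        ref = statsmodels.Logit(y, statsmodels.add_constant(X)).fit(disp=0)
        assert np.allclose(
            np.r_[ours.intercept, ours.coefficients], ref.params, atol=1e-6
        )

    def test_complete_separation_is_an_error(self):
        X = np.array([[-1.0], [-0.5], [0.5], [1.0]])
        y = np.array([0, 0, 1, 1])
        with pytest.raises(SeparationError):
            fit_lra(X, y)

    def test_in_sample_probabilities_reproduce_to_1e8(self):
        rng = np.random.default_rng(7)
        n = 200
        X = rng.normal(size=(n, 2))
        y = (rng.random(n) < expit(X @ np.array([1.0, -1.0]))).astype(int)
        model = fit_lra(X, y, feature_names=("a", "b"))
        p1 = expit(model.intercept + X @ model.coefficients)
        p2 = np.array(
            [score(model, {"a": xa, "b": xb}).p for xa, xb in X]
        )
        assert np.abs(p1 - p2).max() < 1e-8


class TestPublishedModel:
    def test_zero_features_give_the_intercept(self):
        model = published_model()
        res = score(model, dict.fromkeys(PUBLISHED_FEATURES, 0.0))
        assert res.logit == pytest.approx(-1.2895, abs=1e-12)
        assert res.label == "healthy"
        assert res.p == pytest.approx(1.0 / (1.0 + np.exp(1.2895)))

    def test_four_coefficients(self):
        model = published_model()
        assert len(model.coefficients) == 4
        assert model.feature_names == PUBLISHED_FEATURES

    def test_missing_feature_is_an_error(self):
        with pytest.raises(KeyError):
            score(published_model(), {"HF_MT": 1.0})


class TestScore:
    def test_zero_logit_boundary_is_suspected(self):
        model = published_model()
        x = dict.fromkeys(PUBLISHED_FEATURES, 0.0)
        x["HF_MT"] = 1.2895 / 0.0013  # drives the logit exactly to 0
        res = score(model, x)
        assert res.logit == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(0.5)
        assert res.label == "suspected_mdd"

    def test_positive_weight_monotonicity(self):
        model = published_model()
        base = dict.fromkeys(PUBLISHED_FEATURES, 10.0)
        doubled = dict(base, HF_MT=20.0)
        assert score(model, doubled).p > score(model, base).p


class TestEvaluateCv:
    def test_separable_cohort_perfect_metrics(self):
        rng = np.random.default_rng(8)
        X = np.concatenate([rng.normal(-5, 0.5, 30), rng.normal(5, 0.5, 30)])
        y = np.r_[np.zeros(30), np.ones(30)].astype(int)
        m = evaluate_cv(X[:, None], y, folds=5, seed=0)
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_shuffled_labels_give_chance_metrics(self):
        rng = np.random.default_rng(9)
        n = 200
        X = rng.normal(size=(n, 3))
        y = rng.permutation(np.r_[np.zeros(n // 2), np.ones(n // 2)]).astype(int)
        m = evaluate_cv(X, y, folds=5, seed=0)
        for v in (m.sensitivity, m.specificity, m.ppv, m.npv):
            assert 0.35 <= v <= 0.65

    def test_confusion_counts_conserve_cohort_size(self):
        rng = np.random.default_rng(10)
        n = 80
        X = rng.normal(size=(n, 2))
        y = (rng.random(n) < expit(X[:, 0])).astype(int)
        m = evaluate_cv(X, y, folds=5, seed=0)
        assert m.n == n

    def test_ppv_npv_consistent_with_prevalence(self):
        rng = np.random.default_rng(11)
        n = 120
        X = rng.normal(size=(n, 2))
        y = (rng.random(n) < expit(1.2 * X[:, 0])).astype(int)
        m = evaluate_cv(X, y, folds=5, seed=0)
        prev = (m.tp + m.fn) / m.n
        bayes_ppv = (m.sensitivity * prev) / (
            m.sensitivity * prev + (1 - m.specificity) * (1 - prev)
        )
        assert m.ppv == pytest.approx(bayes_ppv, abs=1e-12)

    def test_one_class_cohort_rejected(self):
        X = np.random.default_rng(12).normal(size=(20, 2))
        with pytest.raises(ValueError):
            evaluate_cv(X, np.ones(20, dtype=int), folds=5, seed=0)


class TestRocAnalysis:
    def test_perfect_logits(self):
        labels = np.array([0, 0, 1, 1, 1])
        auc, _ = roc_analysis(labels.astype(float), labels)
        assert auc == 1.0

    def test_null_logits_near_half(self):
        rng = np.random.default_rng(13)
        n = 2000
        logits = rng.normal(size=n)
        labels = rng.integers(0, 2, n)
        auc, _ = roc_analysis(logits, labels)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_equals_mann_whitney_u_with_ties(self):
        rng = np.random.default_rng(14)
        logits = rng.integers(0, 5, 200).astype(float)  # heavy ties
        labels = rng.integers(0, 2, 200)
        auc, _ = roc_analysis(logits, labels)
        n1, n0 = labels.sum(), (1 - labels).sum()
        u = mannwhitneyu(logits[labels == 1], logits[labels == 0]).statistic
        assert auc == pytest.approx(u / (n1 * n0), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(15)
        logits = rng.normal(size=300)
        labels = (rng.random(300) < expit(logits)).astype(int)
        auc1, _ = roc_analysis(logits, labels)
        auc2, _ = roc_analysis(np.exp(3 * logits) + 7, labels)
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_youden_cutoff_separates_clusters(self):
        logits = np.r_[np.full(20, -3.0), np.full(20, 3.0)]
        labels = np.r_[np.zeros(20), np.ones(20)].astype(int)
        auc, cutoff = roc_analysis(logits, labels)
        assert auc == 1.0
        assert -3.0 < cutoff <= 3.0
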
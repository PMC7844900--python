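"""ROC/AUC, DeLong comparison, cross-validated forest and multi-omics
combination."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cfomics import diagnostic
from cfomics.diagnostic import (CvConfig, DiagnosticModel, delong_test,
                                marker_test, roc_auc, select_features)


def brute_force_auc(scores, labels):
    """Pair-counting oracle with ties worth 1/2."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for x in pos:
        for z in neg:
            total += 1.0 if x > z else (0.5 if x == z else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_worked_example(self):
        r = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert r.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        r = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_label_inversion_symmetry(self, rng):
        s = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        assert roc_auc(s, y).auc == pytest.approx(
            1.0 - roc_auc(s, 1 - y).auc)

    def test_matches_pair_counting_oracle_with_ties(self, rng):
        """Rank-formulation AUC equals brute-force pair counting on every
        random input up to 30 samples, ties included."""
        for _ in range(60):
            n = int(rng.integers(4, 31))
            s = rng.choice([0.1, 0.2, 0.3, 0.5, 0.7], size=n)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            assert roc_auc(s, y).auc == pytest.approx(
                brute_force_auc(s, y), abs=1e-12)

    def test_youden_ties_take_lower_cutoff(self):
        # cutoffs 2 and 3 both give J = 1; the lower must win
        r = roc_auc([1, 1, 2, 3, 3], [0, 0, 1, 1, 1])
        assert r.cutoff == 2

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 2, 3], [1, 1, 1])


def oracle_delong_variance(a, b, y):
    """Textbook placement-value variance of the AUC difference, computed
    with explicit loops."""
    a, b, y = np.asarray(a, float), np.asarray(b, float), np.asarray(y, int)
    out = []
    for s in (a, b):
        pos, neg = s[y == 1], s[y == 0]
        m, n = len(pos), len(neg)
        psi = np.array([[1.0 if x > z else 0.5 if x == z else 0.0
                         for z in neg] for x in pos])
        out.append((psi.mean(), psi.mean(axis=1), psi.mean(axis=0)))
    (_, v10a, v01a), (_, v10b, v01b) = out
    m, n = len(v10a), len(v01a)

    def cov(u, v):
        return np.sum((u - u.mean()) * (v - v.mean())) / (len(u) - 1)

    return (cov(v10a, v10a) + cov(v10b, v10b) - 2 * cov(v10a, v10b)) / m \
        + (cov(v01a, v01a) + cov(v01b, v01b) - 2 * cov(v01a, v01b)) / n


class TestDelong:
    def test_identical_scores_give_p_exactly_one(self, rng):
        s = rng.normal(size=30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        auc_a, auc_b, p = delong_test(s, s, y)
        assert auc_a == auc_b
        assert p == 1.0

    def test_symmetric_in_model_order(self, rng):
        a, b = rng.normal(size=25), rng.normal(size=25)
        y = rng.integers(0, 2, 25)
        y[:2] = [0, 1]
        assert delong_test(a, b, y)[2] == pytest.approx(
            delong_test(b, a, y)[2])

    def test_variance_matches_enumeration_oracle(self, rng):
        """Implementation variance equals the explicit placement-value
        oracle on small inputs, to 1e-8."""
        for _ in range(20):
            n = int(rng.integers(5, 12))
            a, b = rng.normal(size=n), rng.normal(size=n)
            y = rng.integers(0, 2, n)
            y[:2] = [0, 1]
            auc_a, auc_b, p = delong_test(a, b, y)
            var = oracle_delong_variance(a, b, y)
            if var > 0:
                z = (auc_a - auc_b) / np.sqrt(var)
                expected_p = 2 * stats.norm.sf(abs(z))
                assert p == pytest.approx(expected_p, abs=1e-8)

    def test_detects_a_real_auc_gap(self):
        """Power: with n=60 and a planted AUC gap of ~0.25 the test
        rejects at 0.05 in at least 80% of replicates."""
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            y = np.r_[np.zeros(30, int), np.ones(30, int)]
            good = y * 2.2 + r.normal(size=60)     # AUC ~ 0.94
            weak = y * 0.7 + r.normal(size=60)     # AUC ~ 0.69
            p = delong_test(good, weak, y)[2]
            hits += p < 0.05
        assert hits >= 80

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            delong_test([1, 2], [1, 2, 3], [0, 1, 1])


class TestSelectFeatures:
    def test_single_fold_returns_its_top_m(self):
        imp = pd.DataFrame([[0.5, 0.3, 0.2]], columns=list("abc"))
        assert select_features(imp, 2) == ["a", "b"]

    def test_union_over_folds(self):
        imp = pd.DataFrame([[0.5, 0.4, 0.1], [0.1, 0.5, 0.4]],
                           columns=list("ABC"))
        assert select_features(imp, 2) == ["A", "B", "C"]

    def test_ties_break_by_feature_id(self):
        imp = pd.DataFrame([[0.4, 0.4, 0.2]], columns=["z", "a", "b"])
        assert select_features(imp, 1) == ["a"]

    def test_oversized_m_selects_all(self):
        imp = pd.DataFrame([[0.6, 0.4]], columns=list("ab"))
        assert select_features(imp, 5) == ["a", "b"]

    def test_reduction_reporting(self):
        assert diagnostic.reduction_pct(47, 293) == 84.0


def make_features(rng, n, p, signal=0.0):
    y = np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)]
    X = rng.normal(size=(n, p))
    X[:, 0] += y * signal
    X[:, 1] += y * signal * 0.7
    idx = [f"s{i}" for i in range(n)]
    return pd.DataFrame(X, index=idx,
                        columns=[f"f{j}" for j in range(p)]), \
        pd.Series(y, index=idx)


class TestCrossValidation:
    def test_null_features_give_chance_auc(self):
        """Label-independent features: mean out-of-fold AUC across 10
        seeds stays within 0.5 +/- 0.07."""
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X, y = make_features(rng, 200, 50)
            res = DiagnosticModel(X, y, CvConfig(seed=seed)).fit()
            aucs.append(res.auc)
        assert abs(np.mean(aucs) - 0.5) < 0.07

    def test_planted_signal_gives_high_auc(self):
        rng = np.random.default_rng(1)
        X, y = make_features(rng, 150, 20, signal=4.0)
        res = DiagnosticModel(X, y, CvConfig(seed=1)).fit()
        assert res.auc >= 0.95

    def test_every_sample_scored_out_of_fold(self, rng):
        X, y = make_features(rng, 60, 10, signal=1.0)
        res = DiagnosticModel(X, y, CvConfig(k=6, seed=0)).fit()
        assert res.oof_scores.notna().all()

    def test_deterministic_given_seed(self, rng):
        X, y = make_features(rng, 80, 10, signal=1.0)
        r1 = DiagnosticModel(X, y, CvConfig(seed=3)).fit()
        r2 = DiagnosticModel(X, y, CvConfig(seed=3)).fit()
        assert (r1.oof_scores == r2.oof_scores).all()

    def test_in_fold_selection_does_not_leak(self):
        """Permuted labels with aggressive per-fold selection must stay
        at chance AUC — the classic selection-leakage check."""
        aucs = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X, y = make_features(rng, 120, 80)
            y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            res = DiagnosticModel(
                X, y_perm, CvConfig(seed=seed, n_trees=200,
                                    top_m_per_fold=5)).fit()
            aucs.append(res.auc)
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_missing_values_rejected(self, rng):
        X, y = make_features(rng, 30, 5)
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            DiagnosticModel(X, y)

    def test_unstratified_small_class_errors_helpfully(self):
        rng = np.random.default_rng(5)
        X, _ = make_features(rng, 30, 5)
        # a lone positive: its test fold leaves a single-class training set
        y = pd.Series(np.r_[np.ones(1, int), np.zeros(29, int)],
                      index=X.index)
        with pytest.raises(ValueError, match="stratif"):
            DiagnosticModel(X, y, CvConfig(k=6, stratified=False,
                                           seed=1)).fit()

    def test_summary_mentions_key_numbers(self, rng):
        X, y = make_features(rng, 60, 10, signal=2.0)
        res = DiagnosticModel(X, y, CvConfig(seed=0,
                                             top_m_per_fold=3)).fit()
        text = res.summary()
        assert "AUC" in text and "sensitivity" in text
        assert f"{res.config.k}" in text


class TestCombineOmics:
    def test_informative_analyte_raises_auc(self):
        """Adding an informative mutation score to noise methylation
        features increases the mean AUC over 20 seeds."""
        gains = []
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            X, y = make_features(rng, 120, 15)
            mut = pd.Series(y * 1.5 + rng.normal(size=len(y)),
                            index=X.index, name="wsumaf")
            evals = diagnostic.combine_omics(
                X, mut, None, y, CvConfig(seed=seed, n_trees=150))
            gains.append(evals["methylation+mutation"].auc
                         - evals["methylation"].auc)
        assert np.mean(gains) > 0.05

    def test_constant_analyte_changes_nothing_much(self):
        rng = np.random.default_rng(7)
        X, y = make_features(rng, 100, 10, signal=2.0)
        const = pd.Series(1.0, index=X.index, name="wsumaf")
        evals = diagnostic.combine_omics(X, const, None, y,
                                         CvConfig(seed=7, n_trees=150))
        assert abs(evals["methylation+mutation"].auc
                   - evals["methylation"].auc) < 0.05

    def test_all_analyte_subsets_evaluated_on_same_samples(self, rng):
        X, y = make_features(rng, 60, 8, signal=1.0)
        mut = pd.Series(rng.normal(size=len(y)), index=X.index)
        cea = pd.Series(rng.normal(size=len(y)), index=X.index)
        cea.iloc[:5] = np.nan      # incomplete measurements drop out
        evals = diagnostic.combine_omics(X, mut, cea, y,
                                         CvConfig(seed=0, n_trees=50))
        sizes = {len(ev.oof_scores) for ev in evals.values()}
        assert sizes == {55}
        assert set(evals) == {"methylation", "mutation", "cea",
                              "methylation+mutation",
                              "methylation+mutation+cea"}

    def test_empty_intersection_rejected(self, rng):
        X, y = make_features(rng, 20, 5)
        mut = pd.Series(np.nan, index=X.index)
        with pytest.raises(ValueError, match="complete"):
            diagnostic.combine_omics(X, mut, None, y)


class TestMarkerTest:
    def test_identical_groups_give_null_result(self):
        t, p, auc = marker_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert auc == pytest.approx(0.5)

    def test_matches_textbook_t_statistic(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        t, p, _ = marker_test(a, b)
        sp = np.sqrt(((a.var(ddof=1) * 2) + (b.var(ddof=1) * 2)) / 4)
        expected = (a.mean() - b.mean()) / (sp * np.sqrt(1 / 3 + 1 / 3))
        assert t == pytest.approx(expected, abs=1e-12)

    def test_auc_matches_binormal_closed_form(self):
        """For a location shift d between unit-variance normals, the
        marker AUC converges to Phi(d / sqrt(2))."""
        d = 0.5
        aucs = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            aucs.append(marker_test(r.normal(d, 1, 100),
                                    r.normal(0, 1, 100))[2])
        assert np.mean(aucs) == pytest.approx(stats.norm.cdf(d / np.sqrt(2)),
                                              abs=0.03)

    def test_degenerate_equal_constants(self):
        t, p, _ = marker_test([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)
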
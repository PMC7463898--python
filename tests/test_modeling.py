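"""Classifiers, cross-validation, metrics and threshold optimization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from rectomics.modeling import (CVConfig, GaussianQDA, Metrics,
                                confusion_from_rates, evaluate,
                                fit_final_model, mcc_from_confusion,
                                optimize_threshold,
                                rank_features_by_frequency, run_repeated_cv)

from conftest import make_gaussian_table


class TestGaussianQDA:
    def test_symmetric_1d_problem_has_midpoint_boundary(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(-1, 1, 500),
                            rng.normal(1, 1, 500)])[:, None]
        y = np.array(["a"] * 500 + ["b"] * 500)
        clf = GaussianQDA().fit(X, y)
        p = clf.predict_proba(np.array([[0.0]]))
        assert p[0, 0] == pytest.approx(0.5, abs=0.05)

    def test_refit_on_duplicated_data_identical(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        y = np.array(["a", "b"] * 20)
        c1 = GaussianQDA().fit(X, y)
        c2 = GaussianQDA().fit(np.vstack([X, X]), np.concatenate([y, y]))
        grid = rng.normal(size=(10, 3))
        # duplicated data halves the ddof correction; allow tiny drift
        np.testing.assert_allclose(c1.predict_proba(grid),
                                   c2.predict_proba(grid), atol=0.02)

    def test_posterior_matches_closed_form_gaussian_arithmetic(self):
        rng = np.random.default_rng(2)
        Xa = rng.normal(0, 1, size=(60, 2))
        Xb = rng.normal(2, 1.5, size=(60, 2))
        X = np.vstack([Xa, Xb])
        y = np.array(["a"] * 60 + ["b"] * 60)
        clf = GaussianQDA(eps=0).fit(X, y)
        x0 = np.array([0.7, 1.3])

        def logpdf(x, sample):
            mu = sample.mean(axis=0)
            cov = np.cov(sample, rowvar=False, ddof=1)
            d = x - mu
            return (-0.5 * d @ np.linalg.inv(cov) @ d
                    - 0.5 * np.linalg.slogdet(cov)[1])

        la, lb = logpdf(x0, Xa), logpdf(x0, Xb)
        expect = np.exp(la) / (np.exp(la) + np.exp(lb))
        assert clf.predict_proba(x0[None])[0, 0] == pytest.approx(expect,
                                                                  rel=1e-9)

    def test_agrees_with_sklearn_qda_oracle(self):
        from sklearn.discriminant_analysis import (
            QuadraticDiscriminantAnalysis)
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, (50, 3)),
                       rng.normal(1.5, 2, (50, 3))])
        y = np.array([0] * 50 + [1] * 50)
        ours = GaussianQDA(eps=0).fit(X, y)
        ref = QuadraticDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y)
        grid = rng.normal(0.5, 1.5, size=(20, 3))
        np.testing.assert_allclose(ours.predict_proba(grid),
                                   ref.predict_proba(grid), atol=1e-8)

    def test_singular_covariance_is_ridge_stabilized(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0],  # collinear class
                      [0.0, 1.0], [1.0, 3.0], [2.0, 0.0]])
        y = np.array(["a"] * 3 + ["b"] * 3)
        clf = GaussianQDA().fit(X, y)
        assert np.isfinite(clf.predict_proba(X)).all()


class TestMetrics:
    def test_mcc_direct_formula_evaluation(self):
        # confusion reconstructed from 81%/62% sensitivity/specificity on
        # a 16/26 class split
        assert mcc_from_confusion(13, 3, 16, 10) == pytest.approx(
            178 / np.sqrt(23 * 16 * 26 * 19))
        assert mcc_from_confusion(13, 3, 16, 10) == pytest.approx(0.42, abs=0.005)

    def test_perfect_and_degenerate_conventions(self):
        assert mcc_from_confusion(10, 0, 12, 0) == 1.0
        assert mcc_from_confusion(16, 0, 0, 26) == 0.0  # all-positive calls

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 50)] * 4))
    def test_mcc_bounded(self, counts):
        assert -1 - 1e-12 <= mcc_from_confusion(*counts) <= 1 + 1e-12

    def test_confusion_from_rates_roundtrip(self):
        tp, fn, tn, fp = confusion_from_rates(0.81, 0.62, 16, 26)
        assert (tp, fn, tn, fp) == (13, 3, 16, 10)
        m = Metrics(auc=None, tp=tp, fn=fn, tn=tn, fp=fp)
        assert m.sensitivity == pytest.approx(13 / 16)
        assert m.n == 42


class TestRepeatedCV:
    def test_each_case_tested_once_per_repeat(self, gaussian_table):
        cfg = CVConfig(repeats=2, k=2, seed=5)
        cv = run_repeated_cv(gaussian_table, cfg)
        # partition property: 3 folds x 2 repeats, fold sizes sum to n
        assert len(cv.records) == 6
        assert cv.records.groupby("repeat").size().eq(3).all()

    def test_separable_data_high_auc(self):
        t = make_gaussian_table(n_per_class=26, n_features=20,
                                effect={0: 5.0, 1: 5.0}, seed=6)
        cv = run_repeated_cv(t, CVConfig(repeats=5, k=2, seed=6))
        assert cv.mean_auc >= 0.95

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(7)
        t = make_gaussian_table(n_per_class=26, n_features=20,
                                effect={0: 3.0}, seed=7)
        perm = rng.permutation(t.meta["ypT_group"].to_numpy())
        t.meta["ypT_group"] = perm
        cv = run_repeated_cv(t, CVConfig(repeats=10, k=2, seed=7))
        # a single permutation at n=52 leaves noticeable spread around 0.5
        assert 0.35 <= cv.mean_auc <= 0.65

    def test_deterministic_given_seed(self, gaussian_table):
        cfg = CVConfig(repeats=2, k=2, seed=9)
        a = run_repeated_cv(gaussian_table, cfg)
        b = run_repeated_cv(gaussian_table, cfg)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_inside_fold_selection_avoids_bias(self):
        """Selecting on the full table before CV must inflate null-data CV
        AUC relative to honest inside-fold selection."""
        from rectomics.selection import SelectionResult, select_features
        t = make_gaussian_table(n_per_class=26, n_features=150, seed=8)
        cfg = CVConfig(repeats=5, k=4, seed=8)
        honest = run_repeated_cv(t, cfg)
        leaked = select_features(t, k=4).selected
        biased_sel = lambda tr: SelectionResult(
            selected=list(leaked), relevance=dict.fromkeys(leaked, 0.0),
            redundancy=dict.fromkeys(leaked, 0.0), survivors=list(leaked))
        biased = run_repeated_cv(t, cfg, selector=biased_sel)
        assert biased.mean_auc > honest.mean_auc + 0.05
        assert 0.35 <= honest.mean_auc <= 0.65


class TestFrequencyRanking:
    def test_always_selected_feature_tops_with_full_frequency(self):
        t = make_gaussian_table(n_per_class=26, n_features=10,
                                effect={0: 5.0}, seed=10)
        cv = run_repeated_cv(t, CVConfig(repeats=5, k=1, seed=10))
        rank = rank_features_by_frequency(cv)
        assert rank.iloc[0]["feature"] == "f00"
        assert rank.iloc[0]["frequency"] == 15  # 3 folds x 5 repeats

    def test_frequencies_bounded_by_folds_times_repeats_times_k(self):
        t = make_gaussian_table(n_per_class=26, n_features=10,
                                effect={0: 2.0, 1: 2.0}, seed=11)
        cfg = CVConfig(repeats=4, k=3, seed=11)
        cv = run_repeated_cv(t, cfg)
        rank = rank_features_by_frequency(cv)
        assert rank["frequency"].max() <= 12
        assert rank["frequency"].sum() <= cfg.repeats * cfg.folds * cfg.k


class TestFinalModelAndEvaluation:
    @staticmethod
    def _disc_val(seed=12, d=3.0):
        disc = make_gaussian_table(n_per_class=26, n_features=6,
                                   effect={0: d, 1: d}, seed=seed)
        val = make_gaussian_table(n_per_class=13, n_features=6,
                                  effect={0: d, 1: d}, seed=seed + 100)
        val.meta["cohort"] = "validation"
        val.meta["institution"] = ["inst2"] * 16 + ["inst3"] * 10
        val.meta["sex"] = (["M", "F"] * 13)
        return disc, val

    def test_threshold_in_unit_interval_and_youden_optimal(self):
        disc, _ = self._disc_val()
        bundle = fit_final_model(disc, ["f00", "f01"])
        thr = optimize_threshold(bundle, disc)
        assert 0 < thr < 1
        s = bundle.scores(disc)
        ypos = (disc.labels == "ypT0-2").to_numpy()
        js = []
        for t0 in np.linspace(0.01, 0.99, 99):
            pred = s >= t0
            js.append((pred & ypos).mean() / ypos.mean()
                      - (pred & ~ypos).mean() / (~ypos).mean())
        pred = s >= thr
        j_at = (pred & ypos).mean() / ypos.mean() \
            - (pred & ~ypos).mean() / (~ypos).mean()
        assert j_at >= max(js) - 1e-9

    def test_holdout_metrics_consistent_counts(self):
        disc, val = self._disc_val()
        bundle = fit_final_model(disc, ["f00", "f01"])
        optimize_threshold(bundle, disc)
        out = evaluate(bundle, val, by=("institution", "sex"))
        o = out["overall"]
        assert o["tp"] + o["fn"] + o["tn"] + o["fp"] == 26
        assert o["auc"] > 0.9
        assert set(out["by_institution"]) == {"inst2", "inst3"}

    def test_single_class_stratum_reports_missing_auc(self):
        disc, val = self._disc_val()
        val.meta["institution"] = ["solo" if g == "ypT0-2" else "other"
                                   for g in val.meta["ypT_group"]]
        bundle = fit_final_model(disc, ["f00"])
        optimize_threshold(bundle, disc)
        out = evaluate(bundle, val, by=("institution",))
        assert out["by_institution"]["solo"]["auc"] is None

    def test_auc_invariant_under_monotone_score_transform(self):
        rng = np.random.default_rng(13)
        y = rng.random(40) > 0.5
        s = rng.random(40)
        assert roc_auc_score(y, s) == pytest.approx(
            roc_auc_score(y, np.exp(5 * s)))

    def test_perfect_scores_give_unit_metrics(self):
        disc, val = self._disc_val(d=30.0)
        bundle = fit_final_model(disc, ["f00", "f01"])
        optimize_threshold(bundle, disc)
        o = evaluate(bundle, val)["overall"]
        assert o["auc"] == 1.0 and o["mcc"] == pytest.approx(1.0)
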
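"""Feature selection, AUC, confusion metrics and the LOSO disease index."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rsomvasc import (
    ValidationError,
    auc,
    confusion_metrics,
    counts_from_rates,
    generate_cohort,
    loso_index,
    select_top_k,
)

FAST_RF = {"n_estimators": 50}


class TestSelectTopK:
    @staticmethod
    def _toy():
        rng = np.random.default_rng(0)
        y = np.r_[np.zeros(8, int), np.ones(8, int)]
        X = pd.DataFrame({
            "strong": y * 3.0 + rng.normal(0, 0.1, 16),
            "weak": y * 0.5 + rng.normal(0, 1.0, 16),
            "noise": rng.normal(size=16),
            "constant": np.ones(16),
        })
        return X, y

    def test_dominant_feature_selected_first(self):
        X, y = self._toy()
        assert select_top_k(X, y, 1) == ["strong"]

    def test_k_equals_p_is_identity(self):
        X, y = self._toy()
        assert set(select_top_k(X, y, 4)) == set(X.columns)

    def test_constant_feature_ranked_last(self):
        X, y = self._toy()
        assert select_top_k(X, y, 4)[-1] == "constant"

    def test_ranking_matches_closed_form_f(self):
        X, y = self._toy()
        Xn = X[["strong", "weak", "noise"]]
        F = {}
        for col in Xn:
            v = Xn[col].to_numpy()
            groups = [v[y == g] for g in (0, 1)]
            grand = v.mean()
            ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
            ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
            F[col] = (ssb / 1) / (ssw / (len(v) - 2))
        expected = sorted(F, key=F.get, reverse=True)
        assert select_top_k(Xn, y, 3) == expected

    def test_invalid_k_rejected(self):
        X, y = self._toy()
        with pytest.raises(ValidationError):
            select_top_k(X, y, 0)
        with pytest.raises(ValidationError):
            select_top_k(X, y, 5)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_matches_exhaustive_pair_count(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n1, n0 = rng.integers(2, 5, 2)
            idx = np.round(rng.random(n1 + n0), 1)  # ties likely
            y = np.r_[np.ones(n1, int), np.zeros(n0, int)]
            pos, neg = idx[:n1], idx[n1:]
            brute = np.mean([
                1.0 if p > q else (0.5 if p == q else 0.0)
                for p, q in itertools.product(pos, neg)
            ])
            assert auc(idx, y) == pytest.approx(brute)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        idx = rng.random(10)
        y = rng.integers(0, 2, 10)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        a = auc(idx, y)
        assert auc(np.exp(3 * idx), y) == pytest.approx(a)
        assert auc(np.log(idx + 1e-9), y) == pytest.approx(a)

    def test_label_swap_complements(self):
        rng = np.random.default_rng(2)
        idx = rng.random(12)
        y = np.r_[np.ones(5, int), np.zeros(7, int)]
        assert auc(idx, y) == pytest.approx(1.0 - auc(idx, 1 - y))

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            auc([0.1, 0.2], [1, 1])


class TestConfusionMetrics:
    def test_worked_example_hyperemia_minute_one(self):
        m = confusion_metrics(12, 1, 11, 2)
        assert round(m["accuracy"], 2) == 0.88
        assert round(m["ppv"], 2) == 0.86
        assert round(m["npv"], 2) == 0.92

    def test_perfect_classification(self):
        m = confusion_metrics(13, 0, 13, 0)
        assert all(m[k] == 1.0 for k in m)

    def test_occlusion_minute_two_accuracy(self):
        # counts reconstructed from printed sensitivity/specificity at n=13+13
        tp, fn, tn, fp = counts_from_rates(0.46, 0.77, 13, 13)
        assert round(confusion_metrics(tp, fn, tn, fp)["accuracy"], 2) == 0.62

    def test_undefined_ppv_flagged(self):
        m = confusion_metrics(0, 5, 5, 0)
        assert np.isnan(m["ppv"])

    def test_label_swap_exchanges_metric_pairs(self):
        m = confusion_metrics(12, 1, 11, 2)
        swapped = confusion_metrics(11, 2, 12, 1)
        assert m["sensitivity"] == swapped["specificity"]
        assert m["ppv"] == pytest.approx(swapped["npv"])

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            confusion_metrics(-1, 1, 1, 1)
        with pytest.raises(ValidationError):
            confusion_metrics(0, 0, 5, 5)


class TestLosoIndex:
    def test_perfect_synthetic_effect_gives_unit_auc(self, strong_cohort):
        res = loso_index(strong_cohort, "hyp1", k=9, rf_params=FAST_RF, seed=0)
        assert res.classifiable
        assert res.auc >= 0.95
        assert len(res.index) == 26

    def test_null_cohort_auc_in_chance_band(self, null_cohort):
        res = loso_index(null_cohort, "hyp1", k=9, rf_params=FAST_RF, seed=0)
        assert 0.25 <= res.auc <= 0.75

    def test_importances_normalised(self, strong_cohort):
        res = loso_index(strong_cohort, "hyp1", k=9, rf_params=FAST_RF, seed=0)
        assert res.importances is not None
        assert res.importances.sum() == pytest.approx(1.0)
        assert (res.importances >= 0).all()
        assert set(res.importances.index) <= set(res.selected)

    def test_auto_k_scans_and_reports(self):
        cohort = generate_cohort(4, "strong", seed=0)
        res = loso_index(cohort, "hyp1", k="auto",
                         rf_params={"n_estimators": 25}, seed=0)
        assert 1 <= res.k <= 18

    def test_all_missing_timepoint_not_classifiable(self, null_cohort):
        cohort = generate_cohort(4, "null", seed=3)
        cohort.features.loc[(slice(None), "occl1"), :] = np.nan
        # baseline untouched; delta at occl1 all-missing
        res = loso_index(cohort, "occl1", k=5, rf_params=FAST_RF, seed=0)
        assert not res.classifiable

    def test_too_few_subjects_rejected(self):
        cohort = generate_cohort(2, "null", seed=0)
        with pytest.raises(ValidationError):
            loso_index(cohort, "hyp1", k=3, rf_params=FAST_RF, seed=0)

    def test_deterministic_under_seed(self, null_cohort):
        a = loso_index(null_cohort, "hyp1", k=5, rf_params=FAST_RF, seed=3)
        b = loso_index(null_cohort, "hyp1", k=5, rf_params=FAST_RF, seed=3)
        np.testing.assert_array_equal(a.index.to_numpy(), b.index.to_numpy())

    def test_label_permutation_auc_near_chance(self):
        """Permuting labels of a real-effect cohort yields chance-level mean
        AUC — a leakage guard on the fold structure."""
        cohort = generate_cohort(4, "strong", seed=1)
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(60):
            perm = cohort.covariates.copy()
            perm["group"] = rng.permutation(perm["group"].to_numpy())
            shuffled = type(cohort)(features=cohort.features, covariates=perm)
            res = loso_index(shuffled, "hyp1", k=3,
                             rf_params={"n_estimators": 25}, seed=0)
            aucs.append(res.auc)
        assert 0.40 <= float(np.mean(aucs)) <= 0.60
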
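"""Association screen, BY FDR, and per-feature CV classifiers."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from pdmci.screen import (
    FeatureScreen,
    adjusted_association,
    by_fdr,
    single_feature_classifier,
)


def simulate_binary(n_case=60, n_ctrl=60, shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    y = np.concatenate([np.ones(n_case), np.zeros(n_ctrl)])
    x = rng.normal(size=n_case + n_ctrl)
    x[: n_case] += shift
    age = rng.normal(70, 5, n_case + n_ctrl)
    gender = rng.integers(0, 2, n_case + n_ctrl).astype(float)
    return y, x, age, gender


class TestAdjustedAssociation:
    def test_direction_matches_shift_sign(self):
        y, x, age, gender = simulate_binary(shift=-1.5, seed=1)
        res = adjusted_association(y, x, age, gender)
        assert res.effect_direction == "-"
        assert res.p_value < 1e-4
        y, x, age, gender = simulate_binary(shift=+1.5, seed=2)
        assert adjusted_association(y, x, age, gender).effect_direction == "+"

    def test_separation_flagged(self):
        y, _, age, gender = simulate_binary(seed=3)
        res = adjusted_association(y, y.copy(), age, gender)
        assert res.separation

    def test_missing_rows_dropped(self):
        y, x, age, gender = simulate_binary(shift=-1.0, seed=4)
        x2 = x.copy()
        x2[:5] = np.nan
        res = adjusted_association(y, x2, age, gender)
        assert np.isfinite(res.p_value)

    def test_too_few_per_class_rejected(self):
        with pytest.raises(ValueError, match="2 participants"):
            adjusted_association([1, 0, 0, 0], [1.0, 2, 3, 4],
                                 [70, 71, 72, 73], [0, 1, 0, 1])

    def test_null_type_one_error_calibrated(self):
        """Rejection rate at alpha=0.05 under the null sits inside its own
        99% binomial band (500 independent null features, n=200/200)."""
        rng = np.random.default_rng(5)
        n = 400
        y = np.concatenate([np.ones(200), np.zeros(200)])
        age = rng.normal(70, 5, n)
        gender = rng.integers(0, 2, n).astype(float)
        m = 500
        rejections = 0
        for _ in range(m):
            x = rng.normal(size=n)
            if adjusted_association(y, x, age, gender).p_value < 0.05:
                rejections += 1
        rate = rejections / m
        half_width = 2.6 * np.sqrt(0.05 * 0.95 / m)
        assert 0.05 - half_width <= rate <= 0.05 + half_width


class TestByFdr:
    def test_equal_after_monotonization(self):
        adj = by_fdr([0.01, 0.02, 0.03, 0.04])
        m_c = 4 * sum(1 / k for k in range(1, 5))
        assert np.allclose(adj, 0.01 * m_c)
        assert adj[0] == pytest.approx(0.0833, abs=5e-4)

    def test_single_p_unchanged(self):
        assert by_fdr([0.3])[0] == pytest.approx(0.3)

    def test_capped_at_one(self):
        assert np.all(by_fdr([1.0, 1.0, 1.0]) == 1.0)

    def test_empty_vector(self):
        assert by_fdr([]).size == 0

    def test_matches_statsmodels_reference(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            m = int(rng.integers(1, 400))
            p = rng.random(m)
            ref = multipletests(p, method="fdr_by")[1]
            assert np.max(np.abs(by_fdr(p) - ref)) < 1e-12

    def test_order_invariance_and_dominates_bh(self):
        rng = np.random.default_rng(9)
        p = rng.random(80)
        perm = rng.permutation(80)
        assert np.allclose(by_fdr(p)[perm], by_fdr(p[perm]))
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.all(by_fdr(p) >= bh - 1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            by_fdr([0.5, 1.2])


class TestSingleFeatureClassifier:
    def test_binormal_effect_recovers_closed_form_auroc(self):
        """Effect d=2 between classes implies population AUROC Phi(d/sqrt(2))."""
        y, x, age, gender = simulate_binary(100, 100, shift=2.0, seed=10)
        auc, _ = single_feature_classifier(y, x, age, gender, seed=0)
        assert auc == pytest.approx(norm.cdf(2 / np.sqrt(2)), abs=0.05)

    def test_pure_noise_is_chance_level(self):
        y, x, age, gender = simulate_binary(80, 80, shift=0.0, seed=11)
        auc, _ = single_feature_classifier(y, x, age, gender, seed=0)
        assert 0.4 <= auc <= 0.6

    def test_auroc_rises_with_age_effect(self):
        """Baseline (age+gender only) model tracks an injected age effect."""
        rng = np.random.default_rng(12)
        n = 160
        aucs = []
        for age_shift in (0.0, 4.0, 10.0):
            y = np.concatenate([np.ones(n // 2), np.zeros(n // 2)])
            age = rng.normal(70, 4, n)
            age[: n // 2] += age_shift
            gender = rng.integers(0, 2, n).astype(float)
            auc, _ = single_feature_classifier(y, None, age, gender, seed=0)
            aucs.append(auc)
        assert 0.4 <= aucs[0] <= 0.6
        assert aucs[0] < aucs[1] < aucs[2]

    def test_few_cases_reduces_folds_with_warning(self):
        y, x, age, gender = simulate_binary(4, 40, shift=1.0, seed=13)
        with pytest.warns(UserWarning, match="reducing CV folds"):
            single_feature_classifier(y, x, age, gender, seed=0, repeats=2)

    def test_deterministic_given_seed(self):
        y, x, age, gender = simulate_binary(30, 30, shift=1.0, seed=14)
        a1, s1 = single_feature_classifier(y, x, age, gender, seed=5, repeats=3)
        a2, s2 = single_feature_classifier(y, x, age, gender, seed=5, repeats=3)
        assert a1 == a2
        assert np.array_equal(s1, s2)


class TestFeatureScreen:
    @pytest.fixture(scope="class")
    def screen_result(self):
        rng = np.random.default_rng(20)
        n = 80
        y = np.concatenate([np.ones(20), np.zeros(60)])
        targets = pd.DataFrame(rng.normal(size=(n, 12)),
                               columns=[f"f{i}" for i in range(12)])
        targets["f0"] -= 1.4 * y  # one real signal
        age = rng.normal(70, 5, n)
        gender = rng.integers(0, 2, n).astype(float)
        model = FeatureScreen(targets, y, age, gender, family="features")
        return model.fit(compute_classifiers=True, seed=0, repeats=3)

    def test_sorted_by_p(self, screen_result):
        p = screen_result.frame["p_value"].to_numpy()
        assert np.all(np.diff(p) >= 0)
        assert screen_result.frame["p_value"].iloc[0] == p.min()

    def test_signal_feature_ranks_first(self, screen_result):
        assert screen_result.frame["target"].iloc[0] == "f0"
        assert screen_result.frame["effect_direction"].iloc[0] == "-"

    def test_fdr_dominates_p(self, screen_result):
        frame = screen_result.frame
        assert np.all(frame["fdr"] >= frame["p_value"] - 1e-15)
        assert np.all(frame["fdr"] <= 1.0)

    def test_threshold_metrics_respect_specificity_floor(self, screen_result):
        assert (screen_result.frame["specificity"] >= 0.85).all()

    def test_summary_mentions_family(self, screen_result):
        assert "features" in screen_result.summary()
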
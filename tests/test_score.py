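"""Score algebra, weight derivation, ROC cutoffs and the robustness harness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from maaspenn.score import (
    RFConfig,
    ScoreWeights,
    derive_weights,
    fit_rf,
    maaspenn_score,
    published_cutoffs,
    published_weights,
    robustness_runs,
    roc_select_cutoff,
    score_outcome_correlation,
    threshold_table,
)


def brute_force_auc(scores, labels):
    """Oracle: exhaustive pairwise concordance count (ties worth 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


class TestPublishedConstants:
    def test_weights_are_the_kernel_slice_pixel_triplet(self):
        w = published_weights()
        assert w.weights == {"kernel": 0.48, "slice_thickness": 0.33,
                             "pixel_spacing": 0.19}
        assert w.provenance == "published"

    def test_cutoff_table_consistency(self):
        t = published_cutoffs()
        assert len(t) == 11
        assert (t["false_alarm"] == (1.0 - t["specificity"]).round(10)).all()
        row70 = t[t["pct_threshold"] == 70].iloc[0]
        assert row70["score_cutoff"] == 0.94

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ScoreWeights({"kernel": 0.5, "slice_thickness": 0.4}, "fitted")


class TestDeriveWeights:
    def test_published_style_importances_normalize_exactly(self):
        imp = {"kernel": 48.0, "slice_thickness": 33.0, "pixel_spacing": 19.0,
               "vendor": 0.0, "model": 0.0, "tube_current": 0.0,
               "exposure": 0.0, "exposure_time": 0.0}
        w = derive_weights(imp, k=3)
        assert w.weights == pytest.approx(
            {"kernel": 0.48, "slice_thickness": 0.33, "pixel_spacing": 0.19}
        )
        assert w.provenance == "fitted"

    def test_equal_importances_give_equal_thirds(self):
        w = derive_weights(
            {"kernel": 5.0, "slice_thickness": 5.0, "pixel_spacing": 5.0}, k=3
        )
        assert all(v == pytest.approx(1 / 3) for v in w.weights.values())

    def test_zero_importance_in_top_k_gets_zero_weight(self):
        w = derive_weights({"kernel": 3.0, "slice_thickness": 1.0,
                            "pixel_spacing": 0.0, "vendor": 0.0}, k=3)
        assert w.weights["pixel_spacing"] == 0.0

    def test_invariant_under_uniform_scaling(self):
        imp = {"kernel": 10.0, "slice_thickness": 7.0, "pixel_spacing": 2.0}
        w1 = derive_weights(imp, k=3)
        w2 = derive_weights({k: 100 * v for k, v in imp.items()}, k=3)
        for p in w1.weights:
            assert w1.weights[p] == pytest.approx(w2.weights[p])

    def test_k_larger_than_parameter_count_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            derive_weights({"kernel": 1.0}, k=3)


class TestScoreAlgebra:
    def test_fully_matched_pair_scores_one(self):
        enc = {"kernel": 1.0, "slice_thickness": 1.0, "pixel_spacing": 1.0}
        assert maaspenn_score(enc) == 1.0

    @pytest.mark.parametrize(
        "enc, expected",
        [
            ({"kernel": 0.5, "slice_thickness": 1.0, "pixel_spacing": 1.0}, 0.76),
            ({"kernel": 1.0, "slice_thickness": 0.5, "pixel_spacing": 1.0}, 0.835),
        ],
    )
    def test_hand_computed_scores(self, enc, expected):
        assert maaspenn_score(enc) == pytest.approx(expected, abs=1e-12)

    def test_missing_retained_component_rejected(self):
        with pytest.raises(ValueError, match="pixel_spacing"):
            maaspenn_score({"kernel": 1.0, "slice_thickness": 1.0})

    def test_frame_variant_matches_scalar(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.uniform(size=(20, 3)),
            columns=["kernel", "slice_thickness", "pixel_spacing"],
        )
        series = maaspenn_score(df)
        for i in range(20):
            assert series.iloc[i] == pytest.approx(maaspenn_score(df.iloc[i].to_dict()))

    @given(
        k=st.floats(0, 1), s=st.floats(0, 1), p=st.floats(0, 1),
        bump=st.floats(0, 1),
    )
    def test_range_and_monotonicity(self, k, s, p, bump):
        base = maaspenn_score({"kernel": k, "slice_thickness": s, "pixel_spacing": p})
        assert 0.0 <= base <= 1.0 + 1e-12
        k2 = min(1.0, k + bump)
        bumped = maaspenn_score({"kernel": k2, "slice_thickness": s, "pixel_spacing": p})
        assert bumped >= base - 1e-12
        if k == s == p == 1.0:
            assert base == 1.0


class TestSpearman:
    def test_monotone_relation_gives_one(self):
        s = np.linspace(0.3, 1.0, 20)
        assert score_outcome_correlation(s, s ** 3 * 100) == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        s = np.linspace(0.3, 1.0, 20)
        assert score_outcome_correlation(s, 100 - s * 50) == pytest.approx(-1.0)

    def test_constant_input_is_nan(self):
        assert np.isnan(score_outcome_correlation(np.ones(10), np.arange(10.0)))


class TestROC:
    def test_perfect_separation(self):
        scores = np.concatenate([np.linspace(0.3, 0.5, 50), np.linspace(0.7, 1.0, 50)])
        labels = np.repeat([0, 1], 50)
        rule = roc_select_cutoff(scores, labels)
        assert rule.auc == 1.0
        assert rule.sensitivity == 1.0
        assert rule.specificity == 1.0
        assert rule.false_alarm == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            roc_select_cutoff(np.arange(5.0), np.ones(5))

    def test_independent_labels_auc_near_half(self):
        rng = np.random.default_rng(12)
        scores = rng.uniform(size=5000)
        labels = rng.integers(0, 2, size=5000)
        rule = roc_select_cutoff(scores, labels)
        assert rule.auc == pytest.approx(0.5, abs=0.03)

    @pytest.mark.parametrize("seed", range(10))
    def test_rank_auc_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.choice(np.linspace(0, 1, 25), size=80)  # with ties
        labels = rng.integers(0, 2, size=80)
        if labels.min() == labels.max():
            return
        rule = roc_select_cutoff(scores, labels)
        assert rule.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_threshold_table_marks_degenerate_thresholds(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(0.5, 1.0, 100)
        pct = rng.uniform(40, 60, 100)  # all labels identical at 10% and 90%
        t = threshold_table(scores, pct, thresholds=(10, 50, 90))
        assert np.isnan(t.loc[t["pct_threshold"] == 10, "auc"]).all()
        assert np.isnan(t.loc[t["pct_threshold"] == 90, "auc"]).all()
        assert np.isfinite(t.loc[t["pct_threshold"] == 50, "auc"]).all()


def _toy_regression(n=200, seed=0, informative=True):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.uniform(size=(n, 8)),
        columns=["vendor", "model", "tube_current", "exposure", "exposure_time",
                 "slice_thickness", "pixel_spacing", "kernel"],
    )
    if informative:
        y = 60 * X["kernel"] + 30 * X["slice_thickness"] + rng.normal(0, 2, n)
    else:
        y = rng.uniform(0, 100, n)
    return X, np.clip(y, 0, 100)


class TestRandomForest:
    def test_deterministic_given_seed(self):
        X, y = _toy_regression()
        cfg = RFConfig(n_trees=100, seed=5)
        f1 = fit_rf(X, y, cfg)
        f2 = fit_rf(X, y, cfg)
        pd.testing.assert_series_equal(f1.importances, f2.importances)
        assert f1.variance_explained_pct == f2.variance_explained_pct

    def test_uninformative_outcome_explains_nothing(self):
        X, y = _toy_regression(informative=False, seed=1)
        fit = fit_rf(X, y, RFConfig(n_trees=100, seed=1))
        assert fit.variance_explained_pct < 10.0

    def test_constant_outcome_rejected(self):
        X, _ = _toy_regression()
        with pytest.raises(ValueError, match="constant"):
            fit_rf(X, np.full(len(X), 50.0))

    def test_length_mismatch_rejected(self):
        X, y = _toy_regression()
        with pytest.raises(ValueError, match="encodings vs"):
            fit_rf(X, y[:-1])

    def test_impurity_importance_mode(self):
        X, y = _toy_regression()
        fit = fit_rf(X, y, RFConfig(n_trees=100, seed=2, importance_method="impurity"))
        assert fit.importances.idxmax() == "kernel"


class TestRobustnessHarness:
    def test_same_master_seed_reproduces_runs(self):
        X, y = _toy_regression(n=120, seed=4)
        kwargs = dict(n_runs=5, thresholds=(30, 50), seed=99)
        r1 = robustness_runs(X, y, **kwargs)
        r2 = robustness_runs(X, y, **kwargs)
        pd.testing.assert_frame_equal(r1, r2)

    def test_degenerate_thresholds_flagged_na(self):
        X, y = _toy_regression(n=120, seed=5)
        runs = robustness_runs(X, y, n_runs=3, thresholds=(99,), seed=0)
        assert runs["auc"].isna().all()

    def test_noise_free_outcome_gives_degenerate_auc(self):
        rng = np.random.default_rng(6)
        X = _toy_regression(n=150, seed=6)[0]
        y = np.clip(100 * (0.48 * X["kernel"] + 0.33 * X["slice_thickness"]
                           + 0.19 * X["pixel_spacing"]), 0, 100)
        runs = robustness_runs(X, y.to_numpy(), n_runs=5, thresholds=(50,), seed=1)
        assert (runs["auc"].dropna() == 1.0).all()
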
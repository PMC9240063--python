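"""Classifier protocols, evaluation metrics and group tests."""

from __future__ import annotations

import itertools
import warnings
from math import comb

import numpy as np
import pandas as pd
import pytest

from netbio.response_model import (
    ModelSpec,
    PredictionResult,
    across_study_predict,
    anova_f_scores,
    anova_select_k,
    binarize_recist,
    compare_groups,
    compute_metrics,
    feature_importance,
    fit_classifier,
    loocv,
    monte_carlo_cv,
    predict,
)


def auc_pair_counting_oracle(y, scores):
    """Exhaustive concordant-pair counting with half credit for ties."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def separable_toy(n=20, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = pd.DataFrame(
        {
            "f1": y * 4.0 + rng.normal(0, 0.1, n),
            "f2": rng.normal(0, 1, n),
        },
        index=[f"s{i}" for i in range(n)],
    )
    return X, y


def test_binarize_recist_mapping():
    assert binarize_recist(["CR", "PR", "SD", "PD", "R", "NR"]).tolist() == [1, 1, 0, 0, 1, 0]
    with pytest.raises(ValueError):
        binarize_recist(["MR"])


class TestFitClassifier:
    def test_separable_toy_perfect_training_accuracy(self):
        X, y = separable_toy()
        model = fit_classifier(X, y, ModelSpec(rng_seed=0))
        pred = predict(model, X)
        assert (pred.labels.to_numpy() == y).all()
        assert model.chosen_C in ModelSpec().C_grid

    def test_single_class_rejected(self):
        X, _ = separable_toy()
        with pytest.raises(ValueError):
            fit_classifier(X, np.ones(len(X), dtype=int))

    def test_duplicated_feature_column_splits_weight_symmetrically(self):
        # L2 shares the weight equally across exact duplicates; the ranking
        # of samples (hence predicted labels) is unchanged, while the exact
        # probabilities may shift because duplication halves the effective
        # penalty along that direction.
        X, y = separable_toy()
        X2 = X.copy()
        X2["f1_copy"] = X2["f1"]
        m1 = fit_classifier(X, y, ModelSpec(rng_seed=0))
        m2 = fit_classifier(X2, y, ModelSpec(rng_seed=0))
        coefs = dict(zip(m2.feature_names, m2.coefficients))
        assert coefs["f1"] == pytest.approx(coefs["f1_copy"], rel=1e-4)
        p1 = predict(m1, X).labels.to_numpy()
        p2 = predict(m2, X2).labels.to_numpy()
        assert (p1 == p2).all()

    def test_balanced_weights_protect_minority_class(self):
        rng = np.random.default_rng(3)
        n_maj, n_min = 45, 5
        y = np.array([0] * n_maj + [1] * n_min)
        X = pd.DataFrame({"f": np.concatenate([rng.normal(0, 0.3, n_maj), rng.normal(4, 0.3, n_min)])})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_classifier(X, y, ModelSpec(rng_seed=0))
        pred = predict(model, X)
        minority_recall = (pred.labels.to_numpy()[y == 1] == 1).mean()
        assert minority_recall == 1.0

    def test_deterministic_given_seed(self):
        X, y = separable_toy(seed=5)
        m1 = fit_classifier(X, y, ModelSpec(rng_seed=11))
        m2 = fit_classifier(X, y, ModelSpec(rng_seed=11))
        assert m1.coefficients.tolist() == m2.coefficients.tolist()
        assert m1.chosen_C == m2.chosen_C


class TestLoocv:
    def test_tiny_cohort_matches_manual_fold_by_fold_fits(self):
        X = pd.DataFrame(
            {"f": [0.0, 0.1, 1.0, 0.9]}, index=["a", "b", "c", "d"]
        )
        y = np.array([0, 0, 1, 1])
        spec = ModelSpec(rng_seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred, _ = loocv(X, y, spec)
            for i in range(4):
                rest = [j for j in range(4) if j != i]
                model = fit_classifier(X.iloc[rest], y[rest], spec)
                manual = model.estimator.predict_proba(
                    X.iloc[[i]].to_numpy(dtype=float)
                )[0, 1]
                assert pred.probabilities.iloc[i] == pytest.approx(manual, abs=1e-12)

    def test_separable_cohort_perfect_accuracy(self):
        X, y = separable_toy(n=24)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, report = loocv(X, y, ModelSpec(rng_seed=0))
        assert report.accuracy == 1.0
        assert report.auc_roc == 1.0
        assert report.fisher_p < 0.01

    def test_pure_noise_features_near_chance(self):
        rng = np.random.default_rng(17)
        n = 40
        y = np.array([0, 1] * (n // 2))
        X = pd.DataFrame(rng.standard_normal((n, 5)), columns=[f"f{i}" for i in range(5)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, report = loocv(X, y, ModelSpec(rng_seed=0))
        assert 0.3 <= report.accuracy <= 0.7
        assert 0.3 <= report.auc_roc <= 0.7


class TestMonteCarloCv:
    def test_split_sizes(self):
        X, y = separable_toy(n=10)
        _, splits = monte_carlo_cv(
            X, y, ModelSpec(rng_seed=0), n_iter=3, return_splits=True
        )
        for tr, te in splits:
            assert len(tr) == 8 and len(te) == 2

    def test_same_seed_reproduces_metrics(self):
        X, y = separable_toy(n=20, seed=2)
        r1 = monte_carlo_cv(X, y, ModelSpec(rng_seed=4), n_iter=5)
        r2 = monte_carlo_cv(X, y, ModelSpec(rng_seed=4), n_iter=5)
        assert [m.auc_roc for m in r1] == [m.auc_roc for m in r2]
        assert [m.accuracy for m in r1] == [m.accuracy for m in r2]

    def test_planted_features_beat_random_pathway_features(self, benchmark, benchmark_single):
        from netbio.workflow import _score_cohort

        cohort = benchmark_single["cohort"]
        y = benchmark_single["y"]
        planted_feats = benchmark_single["features"]
        background = sorted(
            set(benchmark["collection"].sets) - set(benchmark["planted"])
        )[:5]
        random_feats = _score_cohort(
            cohort.expression, benchmark["collection"].subset(background), 0.25
        )
        spec = ModelSpec(rng_seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            auc_planted = np.mean(
                [r.auc_roc for r in monte_carlo_cv(planted_feats, y, spec, n_iter=20)]
            )
            auc_random = np.mean(
                [r.auc_roc for r in monte_carlo_cv(random_feats, y, spec, n_iter=20)]
            )
        # random-pathway features retain weak signal because ssGSEA ranks are
        # compositional (planted shifts displace every other gene's rank), so
        # the meaningful contract is a large separation, not pure chance.
        assert auc_planted >= 0.85
        assert auc_random <= auc_planted - 0.2

    def test_two_feature_sets_share_identical_splits(self):
        X, y = separable_toy(n=20, seed=2)
        X_other = X + 100.0  # different features, same labels
        _, s1 = monte_carlo_cv(X, y, ModelSpec(rng_seed=4), n_iter=5, return_splits=True)
        _, s2 = monte_carlo_cv(
            X_other, y, ModelSpec(rng_seed=4), n_iter=5, return_splits=True
        )
        for (tr1, te1), (tr2, te2) in zip(s1, s2):
            assert tr1.tolist() == tr2.tolist()
            assert te1.tolist() == te2.tolist()


class TestAcrossStudy:
    def test_self_prediction_equals_in_sample(self):
        X, y = separable_toy(n=20)
        spec = ModelSpec(rng_seed=0)
        pred = across_study_predict(X, y, X, spec)
        model = fit_classifier(X, y, spec)
        in_sample = predict(model, X)
        assert pred.probabilities.to_numpy() == pytest.approx(
            in_sample.probabilities.to_numpy()
        )

    def test_disjoint_feature_names_rejected(self):
        X, y = separable_toy()
        X_other = X.rename(columns={"f1": "g1", "f2": "g2"})
        with pytest.raises(ValueError, match="shared features"):
            across_study_predict(X, y, X_other)

    def test_planted_signal_transfers(self, benchmark):
        from netbio.workflow import _score_cohort

        a, b = benchmark["cohort_a"], benchmark["cohort_b"]
        coll = benchmark["collection"].subset(benchmark["selected"])
        fa = _score_cohort(a.expression, coll, 0.25)
        fb = _score_cohort(b.expression, coll, 0.25)
        pred = across_study_predict(
            fa, a.clinical["response"].to_numpy(), fb, ModelSpec(rng_seed=0)
        )
        rep = compute_metrics(
            b.clinical["response"].to_numpy(), pred.probabilities.to_numpy()
        )
        assert rep.auc_roc >= 0.8


class TestAnovaSelection:
    def test_identical_class_means_give_zero_f(self):
        X = pd.DataFrame({"flat": [1.0, 2.0, 1.0, 2.0]})
        y = np.array([0, 0, 1, 1])
        assert anova_f_scores(X, y)["flat"] == pytest.approx(0.0)

    def test_worked_f_example(self):
        # groups (1,2) vs (3,4): SSB=4 on 1 df, SSW=1 on 2 df -> F=8
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0]})
        y = np.array([0, 0, 1, 1])
        assert anova_f_scores(X, y)["f"] == pytest.approx(8.0)

    def test_top_k_ranks_by_f_then_name(self):
        X = pd.DataFrame(
            {
                "b_strong": [0, 0.1, 5, 5.1],
                "a_strong": [0, 0.1, 5, 5.1],
                "weak": [0.0, 1.0, 0.5, 0.6],
            }
        )
        y = np.array([0, 0, 1, 1])
        assert anova_select_k(X, y, 2) == ["a_strong", "b_strong"]
        with pytest.raises(ValueError):
            anova_select_k(X, y, 4)

    def test_planted_features_enriched_in_top_k(self, benchmark):
        from netbio.workflow import _score_cohort

        a = benchmark["cohort_a"]
        fa = _score_cohort(a.expression, benchmark["collection"], 0.25)
        top = anova_select_k(fa, a.clinical["response"].to_numpy(), 10)
        signal = set(benchmark["planted"]) | set(
            a.ground_truth["confounded_pathways"]
        )
        assert len(set(top) & signal) >= 8


class TestComputeMetrics:
    def test_perfect_separation(self):
        rep = compute_metrics([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert rep.auc_roc == 1.0
        assert rep.accuracy == 1.0

    def test_three_of_four_concordant_pairs(self):
        rep = compute_metrics([1, 0, 1, 0], [0.9, 0.8, 0.3, 0.2])
        assert rep.auc_roc == pytest.approx(0.75)

    def test_fisher_p_for_diagonal_confusion(self):
        # confusion ((3,0),(0,3)): two-sided p = 2 / C(6,3) = 0.1
        rep = compute_metrics([1, 1, 1, 0, 0, 0], [0.9, 0.9, 0.9, 0.1, 0.1, 0.1])
        assert rep.confusion.tolist() == [[3, 0], [0, 3]]
        assert rep.fisher_p == pytest.approx(2 / comb(6, 3))

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 31))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        scores = np.round(rng.random(n), 1)  # rounding forces ties
        rep = compute_metrics(y, scores)
        assert rep.auc_roc == pytest.approx(auc_pair_counting_oracle(y, scores))

    def test_confusion_sums_to_n(self):
        rep = compute_metrics([1, 0, 1, 0, 1], [0.6, 0.6, 0.4, 0.2, 0.9])
        assert rep.confusion.sum() == 5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([1, 1, 1], [0.5, 0.6, 0.7])


class TestFeatureImportance:
    model = type(
        "M",
        (),
        {
            "feature_names": ["p2", "n3", "p1"],
            "coefficients": np.array([2.0, -3.0, 1.0]),
        },
    )()

    def test_positive_sign_ranking(self):
        assert feature_importance(self.model, top_n=2, sign="positive") == [
            ("p2", 2.0),
            ("p1", 1.0),
        ]

    def test_negative_sign(self):
        assert feature_importance(self.model, top_n=5, sign="negative") == [("n3", -3.0)]

    def test_all_zero_warns(self):
        zero = type(
            "M", (), {"feature_names": ["a"], "coefficients": np.array([0.0])}
        )()
        with pytest.warns(UserWarning):
            assert feature_importance(zero, sign="both") == []


class TestCompareGroups:
    def test_identical_groups(self):
        t, p_t = compare_groups([1, 2, 3], [1, 2, 3], test="t_test")
        assert t == pytest.approx(0.0)
        _, p_mw = compare_groups([1, 2, 3], [1, 2, 3], test="mann_whitney")
        assert p_mw == pytest.approx(1.0)

    def test_mann_whitney_exact_enumeration(self):
        # (1,2,3) vs (4,5,6): complete separation; exact two-sided p by
        # enumerating all C(6,3) rank assignments
        u_obs = 0
        count = 0
        for combo in itertools.combinations(range(6), 3):
            ranks_a = np.array(combo) + 1
            u = ranks_a.sum() - 3 * 4 / 2
            if min(u, 9 - u) <= min(u_obs, 9 - u_obs):
                count += 1
        expected = count / comb(6, 3)
        stat, p = compare_groups([1, 2, 3], [4, 5, 6], test="mann_whitney")
        assert min(stat, 9 - stat) == 0
        assert p == pytest.approx(expected)
        assert p == pytest.approx(0.1)

    def test_t_statistic_matches_hand_formula(self):
        a, b = np.array([0, 0, 0, 1.0]), np.array([1, 1, 1, 0.0])
        stat, _ = compare_groups(a, b, test="t_test")
        sp2 = (a.var(ddof=1) * 3 + b.var(ddof=1) * 3) / 6  # pooled variance
        expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 4))
        assert stat == pytest.approx(expected)

    def test_zero_variance_both_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1, 1], [2, 2], test="t_test")


def test_prediction_result_threshold():
    pred = PredictionResult(pd.Series([0.49, 0.5, 0.51], index=list("abc")))
    assert pred.labels.tolist() == [0, 1, 1]
    with pytest.raises(ValueError):
        PredictionResult(pd.Series([1.2]))
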
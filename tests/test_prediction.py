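"""Bootstrap LASSO->SVM prediction engine: AUROC, iterations, ensembles,
importance scoring, permutation significance and PLS-DA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_auroc
from traumapanel import (
    augment_covariates,
    auroc,
    bootstrap_ensemble,
    importance_scores,
    model_significance,
    plsda_scores,
    run_iteration,
)
from traumapanel.prediction import IterationResult


class TestAuroc:
    @pytest.mark.parametrize("labels,scores,expected", [
        ([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9], 1.0),
        ([0, 1, 0, 1], [0.9, 0.8, 0.1, 0.2], 0.5),
        ([0, 1], [0.5, 0.5], 0.5),  # tie counts one half
    ])
    def test_hand_cases(self, labels, scores, expected):
        assert auroc(labels, scores) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1, 1, 1], [0.1, 0.2, 0.3])

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_matches_pair_counting_and_reversal(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 20)
        labels = np.concatenate([[0, 1], rng.integers(0, 2, n)])
        scores = rng.choice(np.linspace(0, 1, 7), size=len(labels))
        a = auroc(labels, scores)
        assert a == pytest.approx(brute_force_auroc(labels, scores))
        assert auroc(labels, -scores) == pytest.approx(1 - a)


def separable_data(seed=0, n=112, p=10, informative=2, delta=3.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = np.array([0] * (n // 3) + [1] * (n - n // 3))
    X[y == 1, :informative] += delta
    return X, y


class TestRunIteration:
    def test_separated_classes_high_oob_auroc(self):
        X, y = separable_data(seed=1)
        hits = 0
        for s in range(10):
            res = run_iteration(X, y, rng=np.random.default_rng(s))
            assert res is not None
            if res.oob_auroc >= 0.9:
                hits += 1
        assert hits >= 9

    def test_oob_excludes_in_bag(self):
        X, y = separable_data(seed=2)
        res = run_iteration(X, y, rng=np.random.default_rng(0))
        assert not set(res.oob) & set(res.in_bag)
        assert len(res.in_bag) == 112

    def test_weights_nonzero_only_on_selected(self):
        X, y = separable_data(seed=3)
        res = run_iteration(X, y, rng=np.random.default_rng(1))
        assert np.all(res.weights[~res.selected] == 0)
        assert res.weights[res.selected].any()

    def test_single_class_pool_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError):
            run_iteration(X, np.ones(10, dtype=int))


class TestImportance:
    def _iteration(self, weights, idx=0):
        w = np.asarray(weights, dtype=float)
        return IterationResult(idx, np.array([0]), np.array([1]),
                               w != 0, w, 0.5)

    def test_quadratic_mean_and_scaling(self):
        # feature 0: weights 3 and 4 -> rms sqrt(12.5); feature 1 never selected
        its = [self._iteration([3.0, 0.0]), self._iteration([4.0, 0.0], 1)]
        raw_rms = np.sqrt((3**2 + 4**2) / 2)
        assert raw_rms == pytest.approx(np.sqrt(12.5))
        scores = importance_scores(its, feature_names=["a", "b"])
        assert scores["a"] == 100.0
        assert scores["b"] == 0.0

    @pytest.mark.parametrize("c", [0.01, 1.0, 50.0])
    def test_scale_invariant_maximum(self, c):
        its = [self._iteration([c, c / 2]), self._iteration([c, c / 2], 1)]
        scores = importance_scores(its, feature_names=["a", "b"])
        assert scores["a"] == 100.0
        assert scores["b"] == pytest.approx(50.0)

    def test_all_zero_weights_warn(self):
        with pytest.warns(UserWarning):
            scores = importance_scores([self._iteration([0.0, 0.0])])
        assert (scores == 0).all()


class TestEnsemble:
    def test_seed_determinism_and_summary_ordering(self):
        X, y = separable_data(seed=4, p=8)
        s1 = bootstrap_ensemble(X, y, B=5, seed=9)
        s2 = bootstrap_ensemble(X, y, B=5, seed=9)
        assert np.array_equal(s1.aurocs, s2.aurocs)
        assert s1.ci_low <= s1.median <= s1.ci_high
        assert s1.importance.max() == 100.0

    def test_single_iteration_degenerate_ci(self):
        X, y = separable_data(seed=5, p=8)
        s = bootstrap_ensemble(X, y, B=1, seed=0)
        assert s.median == s.aurocs[0] == s.ci_low == s.ci_high

    def test_oob_fraction_near_theoretical(self):
        # P(zero draws) for n=112, draw 112 with replacement ~ e^-1 = 0.368
        X, y = separable_data(seed=6, p=5)
        sizes = []
        for seed in range(30):
            res = run_iteration(X, y, rng=np.random.default_rng(seed))
            sizes.append(len(res.oob))
        frac = np.mean(sizes) / len(y)
        assert abs(frac - np.exp(-1)) < 0.1 * np.exp(-1) + 0.02

    def test_invalid_b_rejected(self):
        X, y = separable_data(seed=7, p=5)
        with pytest.raises(ValueError):
            bootstrap_ensemble(X, y, B=0)


class TestSignificance:
    def _summary(self, aurocs):
        from traumapanel.prediction import ModelSummary

        a = np.asarray(aurocs, dtype=float)
        return ModelSummary(a, float(np.median(a)), float(a.min()),
                            float(a.max()), pd.Series(dtype=float))

    def test_identical_distributions_null(self):
        s = self._summary(np.linspace(0.4, 0.6, 100))
        assert model_significance(s, s) >= 0.5

    def test_uniform_shift_highly_significant(self):
        base = np.linspace(0.4, 0.6, 100)
        p = model_significance(self._summary(base + 0.1), self._summary(base))
        assert p < 1e-6

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            model_significance(self._summary([0.5, 0.6, 0.7]),
                               self._summary([0.5, 0.6]))

    def test_tiny_b_warns_but_returns(self):
        with pytest.warns(UserWarning, match="underpowered"):
            p = model_significance(self._summary([0.7, 0.8]),
                                   self._summary([0.5, 0.6]))
        assert 0 <= p <= 1

    def test_two_sample_mode(self):
        base = np.linspace(0.4, 0.6, 50)
        p = model_significance(self._summary(base + 0.2), self._summary(base),
                               mode="two_sample")
        assert p < 1e-6


class TestAugmentCovariates:
    def _inputs(self, n=6, p=115):
        X = pd.DataFrame(np.zeros((n, p)), index=[f"s{i}" for i in range(n)],
                         columns=[f"f{i}" for i in range(p)])
        pats = pd.DataFrame({
            "iss": np.arange(n), "age": 40.0 + np.arange(n),
            "sex": ["M", "F"] * (n // 2),
        }, index=X.index)
        return X, pats

    def test_appends_three_columns(self):
        X, pats = self._inputs()
        out = augment_covariates(X, pats)
        assert out.shape[1] == 118
        assert out["sex"].tolist() == [0.0, 1.0] * 3  # M=0, F=1

    def test_double_augment_rejected(self):
        X, pats = self._inputs()
        out = augment_covariates(X, pats)
        with pytest.raises(ValueError, match="already present"):
            augment_covariates(out, pats)

    def test_missing_covariate_names_patient(self):
        X, pats = self._inputs()
        pats.loc["s3", "age"] = np.nan
        with pytest.raises(ValueError, match="s3"):
            augment_covariates(X, pats)


class TestPLSDA:
    def test_separated_classes_split_on_first_component(self):
        X, y = separable_data(seed=8, p=6, informative=3, delta=5.0)
        scores, explained = plsda_scores(X, y)
        lo = scores[y == 0, 0]
        hi = scores[y == 1, 0]
        if lo.mean() > hi.mean():
            lo, hi = hi, lo
        assert lo.max() < hi.min()  # zero overlap
        assert scores.shape == (len(y), 2)
        assert np.all(explained >= 0) and explained.sum() <= 1.0 + 1e-9

    def test_constant_feature_dropped_with_warning(self):
        X, y = separable_data(seed=9, p=5)
        X[:, 2] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            scores, _ = plsda_scores(X, y)
        assert scores.shape[0] == len(y)

    def test_excess_components_rejected(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        y = np.array([0, 1] * 5)
        with pytest.raises(ValueError):
            plsda_scores(X, y, n_components=5)
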
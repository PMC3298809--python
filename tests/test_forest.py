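"""Forest engine: OOB bookkeeping, permutation importance, linear baseline, accuracy."""

import numpy as np
import pandas as pd
import pytest

from metabodelta import (
    ForestParams,
    accuracy,
    fit_forest,
    fit_linear,
    oob_permutation_importance,
)


def _oracle_tree_predict(tree, X):
    """Independent per-row traversal of a fitted sklearn tree.

    Walks children_left/children_right/feature/threshold arrays directly
    instead of calling the tree's own predict path.
    """
    t = tree.tree_
    X32 = np.asarray(X, dtype=np.float32)
    out = np.empty(len(X32))
    for i, row in enumerate(X32):
        node = 0
        while t.children_left[node] != -1:
            if row[t.feature[node]] <= t.threshold[node]:
                node = t.children_left[node]
            else:
                node = t.children_right[node]
        out[i] = t.value[node, 0, 0]
    return out


def _oracle_importance(results, X, y, perm_seed):
    """Brute-force recomputation of the OOB permutation importance.

    Re-traverses every tree on true and permuted copies for EVERY feature
    (no skipping of unused features) and recomputes means, SDs and the
    normalisation from first principles, sharing only the documented
    permutation-seed derivation."""
    n_trees = results.n_trees
    p = X.shape[1]
    d = np.zeros((n_trees, p))
    for t_idx, tree in enumerate(results.trees_):
        oob = results.oob_sets_[t_idx]
        Xo = X[oob]
        yo = y[oob]
        mse0 = np.mean((yo - _oracle_tree_predict(tree, Xo)) ** 2)
        for j in range(p):
            rng = np.random.default_rng([perm_seed, t_idx, j])
            perm = rng.permutation(len(oob))
            Xp = Xo.copy()
            Xp[:, j] = Xo[perm, j]
            d[t_idx, j] = np.mean((yo - _oracle_tree_predict(tree, Xp)) ** 2) - mse0
    raw = d.mean(axis=0)
    se = d.std(axis=0, ddof=1) / np.sqrt(n_trees)
    return raw, np.where(se > 0, raw / np.where(se > 0, se, 1.0), raw)


class TestForestFit:
    def test_single_tree_no_bootstrap_memorises(self, rng):
        X = rng.standard_normal((30, 4))
        y = rng.standard_normal(30)
        fit = fit_forest(X, y, ForestParams(n_trees=1, min_node=1, bootstrap=False, seed=3))
        np.testing.assert_allclose(fit.predict(X), y, atol=1e-6)

    def test_same_seed_identical_predictions(self, rng):
        X = rng.standard_normal((40, 5))
        y = X[:, 0] + rng.standard_normal(40)
        probe = rng.standard_normal((10, 5))
        p1 = fit_forest(X, y, ForestParams(n_trees=25, seed=11)).predict(probe)
        p2 = fit_forest(X, y, ForestParams(n_trees=25, seed=11)).predict(probe)
        np.testing.assert_array_equal(p1, p2)

    def test_oob_is_complement_of_inbag_support(self, rng):
        X = rng.standard_normal((25, 3))
        y = rng.standard_normal(25)
        fit = fit_forest(X, y, ForestParams(n_trees=10, seed=0))
        for t in range(fit.n_trees):
            support = np.flatnonzero(fit.inbag_[t] > 0)
            oob = fit.oob_sets_[t]
            assert fit.inbag_[t].sum() == 25  # bootstrap of size n
            np.testing.assert_array_equal(np.sort(np.concatenate([support, oob])), np.arange(25))

    def test_oob_recovers_monotone_signal(self, rng):
        x = np.sort(rng.standard_normal(100))
        y = 2.0 * x + 1.0
        fit = fit_forest(x[:, None], y, ForestParams(n_trees=100, seed=5))
        assert accuracy(y, fit.oob_prediction_) > 0.9

    def test_resubstitution_at_least_oob(self, rng):
        X = rng.standard_normal((80, 10))
        y = X[:, 0] - X[:, 1] + 0.5 * rng.standard_normal(80)
        fit = fit_forest(X, y, ForestParams(n_trees=100, seed=2))
        assert fit.resubstitution_accuracy >= fit.oob_accuracy

    def test_mtry_exceeding_p_rejected(self, rng):
        X = rng.standard_normal((20, 3))
        with pytest.raises(ValueError, match="mtry"):
            fit_forest(X, rng.standard_normal(20), ForestParams(n_trees=2, mtry=4))

    def test_summary_mentions_dimensions(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 3)), columns=["a", "b", "c"])
        fit = fit_forest(X, rng.standard_normal(30), ForestParams(n_trees=10, seed=0))
        text = fit.summary()
        assert "n samples" in text and "30" in text


class TestPermutationImportance:
    def test_matches_bruteforce_oracle_exactly(self, rng):
        X = rng.standard_normal((20, 3))
        y = X[:, 0] + 0.3 * rng.standard_normal(20)
        fit = fit_forest(X, y, ForestParams(n_trees=5, min_node=2, seed=9))
        imp = oob_permutation_importance(fit, perm_seed=123)
        raw_o, norm_o = _oracle_importance(fit, X.astype(np.float32), y, perm_seed=123)
        got = imp.sort_index()
        np.testing.assert_allclose(got["raw_importance"].to_numpy(), raw_o, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(got["importance"].to_numpy(), norm_o, rtol=1e-10, atol=1e-12)

    def test_oracle_match_larger_forest(self, rng):
        X = rng.standard_normal((20, 3))
        y = X[:, 0] - 0.5 * X[:, 2] + 0.2 * rng.standard_normal(20)
        fit = fit_forest(X, y, ForestParams(n_trees=10, seed=21))
        imp = oob_permutation_importance(fit, perm_seed=77).sort_index()
        raw_o, norm_o = _oracle_importance(fit, X.astype(np.float32), y, perm_seed=77)
        np.testing.assert_allclose(imp["raw_importance"].to_numpy(), raw_o, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(imp["importance"].to_numpy(), norm_o, rtol=1e-10, atol=1e-12)

    def test_unused_feature_exactly_zero(self, rng):
        X = np.column_stack([rng.standard_normal(30), np.full(30, 2.5)])
        y = X[:, 0]
        fit = fit_forest(X, y, ForestParams(n_trees=20, seed=4))
        imp = oob_permutation_importance(fit).sort_index()
        assert imp["raw_importance"].iloc[1] == 0.0

    def test_informative_feature_ranks_first(self):
        wins = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            X = rng.standard_normal((80, 2))
            y = X[:, 0] + 0.3 * rng.standard_normal(80)
            fit = fit_forest(X, y, ForestParams(n_trees=50, seed=s))
            imp = fit.importance(perm_seed=s)
            wins += int(imp.index[0] == 0)
        assert wins >= 19  # >= 95 % of 20 seeds

    def test_noise_importance_concentrates_at_zero(self):
        vals = []
        for s in range(50):
            rng = np.random.default_rng(1000 + s)
            X = rng.standard_normal((50, 5))
            y = rng.standard_normal(50)
            fit = fit_forest(X, y, ForestParams(n_trees=30, seed=s))
            vals.append(fit.importance(perm_seed=s)["importance"].mean())
        assert abs(np.mean(vals)) < 0.5

    def test_duplicate_feature_shares_credit(self, rng):
        x = rng.standard_normal(60)
        noise = rng.standard_normal(60)
        y = x + 0.3 * noise
        single = fit_forest(x[:, None], y, ForestParams(n_trees=40, seed=6))
        raw_single = oob_permutation_importance(single).loc[0, "raw_importance"]
        dup = fit_forest(np.column_stack([x, x]), y, ForestParams(n_trees=40, seed=6))
        raw_pair = oob_permutation_importance(dup)["raw_importance"].sum()
        assert raw_pair <= 2.0 * raw_single + 0.1

    def test_mismatched_training_data_rejected(self, rng):
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        fit = fit_forest(X, y, ForestParams(n_trees=5, seed=0))
        with pytest.raises(ValueError, match="match"):
            oob_permutation_importance(fit, X + 1.0, y)


class TestLinearBaseline:
    def test_exact_noise_free_fit(self):
        x = np.linspace(-2, 2, 20)
        fit = fit_linear(x[:, None], 3.0 * x + 1.0)
        assert fit.params.iloc[0] == pytest.approx(3.0)
        assert fit.intercept == pytest.approx(1.0)

    def test_orthogonal_response_zero_coefficient(self):
        x = np.array([-1.0, 1.0, -1.0, 1.0])
        y = np.array([-1.0, -1.0, 1.0, 1.0])  # orthogonal to x, zero-mean
        fit = fit_linear(x[:, None], y)
        assert fit.params.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_rank_deficiency_warns_and_matches_pinv(self, rng):
        x = rng.standard_normal(15)
        X = np.column_stack([x, x])  # duplicated predictor
        y = 2 * x + rng.standard_normal(15)
        with pytest.warns(UserWarning, match="rank-deficient"):
            fit = fit_linear(X, y)
        design = np.column_stack([np.ones(15), X])
        expected = design @ np.linalg.pinv(design) @ y
        np.testing.assert_allclose(fit.fittedvalues, expected, atol=1e-8)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_linear(np.array([[1.0]]), np.array([1.0]))


class TestAccuracy:
    def test_identity_and_sign(self, rng):
        y = rng.standard_normal(10)
        assert accuracy(y, y) == pytest.approx(1.0)
        assert accuracy(y, -y) == pytest.approx(-1.0)

    def test_affine_invariance(self, rng):
        y = rng.standard_normal(10)
        assert accuracy(y, 2.5 * y + 3.0) == pytest.approx(1.0)

    def test_constant_vector_sentinel(self):
        with pytest.warns(UserWarning, match="constant"):
            assert accuracy([1.0, 2.0, 3.0], [5.0, 5.0, 5.0]) == 0.0

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="at least 3"):
            accuracy([1.0, 2.0], [1.0, 2.0])
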
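"""Random forest, GRRF selection, ranked FST and proximity imputation."""

import numpy as np
import pandas as pd
import pytest

from lcpanel.selection import (fit_random_forest, grrf_select,
                               rank_fst_select, rf_impute)


def noise_matrix(rng, n=60, p=20):
    return rng.integers(0, 3, (n, p)).astype(np.int8)


class TestRandomForest:
    def test_perfect_feature_tops_importance(self):
        """A feature identical to the label wins the importance ranking in
        nearly every seeded run."""
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = noise_matrix(rng)
            y = (X[:, 7] > 0).astype(int)
            if len(np.unique(y)) < 2:
                continue
            forest = fit_random_forest(X, y, n_trees=60, rng=seed)
            wins += int(np.argmax(forest.importance) == 7)
        assert wins >= 95

    def test_oob_error_at_chance_under_permuted_labels(self, rng):
        X = noise_matrix(rng, n=100, p=30)
        y = np.repeat([0, 1], 50)
        forest = fit_random_forest(X, rng.permutation(y), n_trees=300, rng=4)
        assert abs(forest.oob_error - 0.5) < 0.1

    def test_duplicated_rows_predict_identically(self, rng):
        X = noise_matrix(rng, n=50, p=10)
        y = (X[:, 0] + X[:, 1] > 2).astype(int)
        forest = fit_random_forest(X, y, n_trees=50, rng=0)
        X_dup = np.vstack([X, X[:5]])
        pred = forest.predict(X_dup)
        np.testing.assert_array_equal(pred[50:], pred[:5])

    def test_agrees_with_reference_implementation(self, rng):
        """On an easy signal our forest and scikit-learn's reach the same
        predictions and the same top feature."""
        sklearn_ensemble = pytest.importorskip("sklearn.ensemble")
        X = noise_matrix(rng, n=80, p=15)
        y = (X[:, 3] >= 1).astype(int)
        ours = fit_random_forest(X, y, n_trees=200, rng=1)
        ref = sklearn_ensemble.RandomForestClassifier(
            n_estimators=200, random_state=1
        ).fit(X, y)
        X_new = noise_matrix(np.random.default_rng(9), n=40, p=15)
        agree = (ours.predict(X_new) == ref.predict(X_new)).mean()
        assert agree >= 0.95
        assert np.argmax(ref.feature_importances_) == np.argmax(ours.importance)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_random_forest(noise_matrix(rng), np.zeros(60), n_trees=5)

    def test_seeded_determinism(self, rng):
        X = noise_matrix(rng)
        y = (X[:, 2] > 0).astype(int)
        f1 = fit_random_forest(X, y, n_trees=40, rng=11)
        f2 = fit_random_forest(X, y, n_trees=40, rng=11)
        np.testing.assert_array_equal(f1.importance, f2.importance)
        np.testing.assert_array_equal(f1.feature, f2.feature)


class TestGrrf:
    def test_gamma_zero_matches_plain_forest_selection(self, rng):
        """With gamma=0 every penalty is 1, so a GRRF run with the same
        seed selects exactly the plain forest's positive-importance set."""
        X = noise_matrix(rng, n=70, p=25)
        y = (X[:, 5] > 0).astype(int)
        prelim = fit_random_forest(X, y, n_trees=100, rng=3)
        table = grrf_select(X, y, [f"L{j}" for j in range(25)], n_runs=1,
                            n_trees=100, gamma=0.0, rng=42, preliminary=prelim)
        plain = fit_random_forest(X, y, n_trees=100,
                                  rng=np.random.default_rng(42))
        expected = {f"L{j}" for j in np.flatnonzero(plain.importance > 0)}
        got = set(table.loc[table["selected"], "locus"])
        assert got == expected

    def test_perfect_separator_always_selected_rank_one(self, rng):
        X = noise_matrix(rng, n=80, p=30)
        y = X[:, 12] % 2
        table = grrf_select(X, y, list(range(30)), n_runs=10, n_trees=100,
                            gamma=0.3, rng=5)
        row = table[table["locus"] == 12].iloc[0]
        assert row["n_runs_positive"] == 10
        assert row["rank"] == 1

    def test_full_regularization_shrinks_selection(self, rng):
        """gamma=1 with an all-zero guide zeroes every unused feature's
        gain, so the regularized forest selects no more than plain RF."""
        X = noise_matrix(rng, n=60, p=20)
        y = (X[:, 1] > 0).astype(int)
        for seed in range(5):
            prelim = fit_random_forest(X, y, n_trees=50, rng=seed)
            prelim.importance[:] = 0.0
            table = grrf_select(X, y, list(range(20)), n_runs=1, n_trees=50,
                                gamma=1.0, rng=seed, preliminary=prelim)
            plain = fit_random_forest(X, y, n_trees=50,
                                      rng=np.random.default_rng(seed))
            assert table["selected"].sum() <= (plain.importance > 0).sum()

    def test_noise_importance_centered_at_zero(self, rng):
        X = noise_matrix(rng, n=80, p=40)
        y = np.repeat([0, 1], 40)
        forest = fit_random_forest(X, rng.permutation(y), n_trees=400, rng=8)
        imp = forest.importance
        se = imp.std(ddof=1) / np.sqrt(len(imp))
        assert abs(imp.mean()) < 2 * se + 1e-12

    def test_gamma_domain_error(self, rng):
        X = noise_matrix(rng)
        y = (X[:, 0] > 0).astype(int)
        with pytest.raises(ValueError):
            grrf_select(X, y, list(range(20)), gamma=1.5, n_trees=5)


class TestRankFst:
    def test_ranking_and_truncation(self):
        comp = pd.DataFrame(
            {"chrom": ["LG01"] * 3, "pos": [100, 200, 300],
             "a": [0.9, 0.1, 0.5], "b": [1.0, 1.0, 1.0]}
        )
        top2 = rank_fst_select(comp, n_select=2)
        assert list(top2["pos"]) == [100, 300]

    def test_ties_broken_by_position(self):
        comp = pd.DataFrame(
            {"chrom": ["LG02", "LG01", "LG01"], "pos": [50, 900, 10],
             "a": [0.2, 0.2, 0.2], "b": [1.0, 1.0, 1.0]}
        )
        ranked = rank_fst_select(comp)
        assert list(zip(ranked["chrom"], ranked["pos"])) == [
            ("LG01", 10), ("LG01", 900), ("LG02", 50)
        ]

    def test_overlong_request_warns_and_truncates(self):
        comp = pd.DataFrame(
            {"chrom": ["LG01"], "pos": [1], "a": [0.1], "b": [1.0]}
        )
        with pytest.warns(UserWarning):
            out = rank_fst_select(comp, n_select=5)
        assert len(out) == 1


class TestRfImpute:
    def test_complete_matrix_unchanged(self, rng):
        X = noise_matrix(rng, n=40, p=8)
        y = (X[:, 0] > 0).astype(int)
        out = rf_impute(X, y, n_iter=2, n_trees=20, rng=0)
        np.testing.assert_array_equal(out, X)

    def test_class_consensus_fills_single_gap(self):
        """A missing entry in a locus perfectly aligned with the classes is
        imputed to that class's consensus genotype."""
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 20)
        X = rng.integers(0, 3, (40, 6)).astype(np.int8)
        X[:, 2] = np.where(y == 0, 0, 2)  # class-determined locus
        X_missing = X.copy()
        X_missing[3, 2] = -1  # individual 3 is class 0
        out = rf_impute(X_missing, y, n_iter=3, n_trees=100, rng=2)
        assert out[3, 2] == 0
        obs = X_missing >= 0
        np.testing.assert_array_equal(out[obs], X_missing[obs])

    def test_beats_mode_imputation_under_mcar(self, rng):
        y = np.repeat([0, 1], 30)
        p_a = np.where(y == 0, 0.15, 0.85)
        X = rng.binomial(2, p_a[:, None], size=(60, 30)).astype(np.int8)
        mask = rng.random(X.shape) < 0.1
        X_missing = np.where(mask, -1, X).astype(np.int8)
        out = rf_impute(X_missing, y, n_iter=4, n_trees=150, rng=3)
        acc = (out[mask] == X[mask]).mean()
        mode = np.array([np.bincount(X_missing[X_missing[:, j] >= 0, j],
                                     minlength=3).argmax()
                         for j in range(30)])
        mode_acc = (np.broadcast_to(mode, X.shape)[mask] == X[mask]).mean()
        assert acc > mode_acc

    def test_all_missing_column_rejected(self, rng):
        X = noise_matrix(rng, n=30, p=4)
        y = (X[:, 0] > 0).astype(int)
        X[:, 2] = -1
        with pytest.raises(ValueError, match="column 2"):
            rf_impute(X, y, n_iter=1, n_trees=10, rng=0)
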
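import itertools

import numpy as np
import pandas as pd
import pytest
import sklearn.metrics

from oracles import oracle_f1
from vrtask.classify import (
    ConfusionCounts,
    HyperGrid,
    accuracy,
    best_per_trial,
    design_matrix,
    f1_score,
    fit_and_score,
    permutation_null_best_f1,
    run_all,
    stratified_folds,
)


def make_table(n_per_class=20, n_features=6, separation=0.0, seed=0, label_col=True):
    """Two Gaussian clusters along the first feature."""
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0, 1, (n_per_class, n_features))
    X1 = rng.normal(0, 1, (n_per_class, n_features))
    X1[:, 0] += separation
    df = pd.DataFrame(
        np.vstack([X0, X1]), columns=[f"f{j}" for j in range(n_features)]
    )
    df["label"] = ["e33"] * n_per_class + ["e34"] * n_per_class
    return df


class TestMetrics:
    def test_printed_formula_example(self):
        assert f1_score(ConfusionCounts(tp=3, fp=1, fn=2, tn=10)) == pytest.approx(
            3 / 4.5
        )
        assert f1_score(ConfusionCounts(tp=5, fp=0, fn=0, tn=1)) == 1.0
        assert f1_score(ConfusionCounts(tp=0, fp=3, fn=2, tn=1)) == 0.0

    def test_degenerate_no_positives_warns(self):
        with pytest.warns(UserWarning):
            assert f1_score(ConfusionCounts(tp=0, fp=0, fn=0, tn=5)) == 0.0

    def test_accuracy_examples(self):
        assert accuracy(ConfusionCounts(tp=21, tn=32, fp=0, fn=0)) == 1.0
        assert accuracy(ConfusionCounts(tp=0, tn=0, fp=32, fn=21)) == 0.0
        assert accuracy(ConfusionCounts(tp=10, tn=20, fp=12, fn=11)) == pytest.approx(
            30 / 53
        )

    def test_exhaustive_agreement_small_n(self):
        """All label/prediction assignments for n <= 6 agree with the
        precision/recall brute force and with sklearn."""
        for n in range(1, 7):
            for y_true in itertools.product([0, 1], repeat=n):
                for y_pred in itertools.product([0, 1], repeat=n):
                    yt, yp = np.array(y_true), np.array(y_pred)
                    c = ConfusionCounts(
                        tp=int(((yt == 1) & (yp == 1)).sum()),
                        fp=int(((yt == 0) & (yp == 1)).sum()),
                        fn=int(((yt == 1) & (yp == 0)).sum()),
                        tn=int(((yt == 0) & (yp == 0)).sum()),
                    )
                    if c.tp + 0.5 * (c.fp + c.fn) == 0:
                        continue
                    ours = f1_score(c)
                    assert ours == pytest.approx(oracle_f1(c.tp, c.fp, c.fn))
                    assert ours == pytest.approx(
                        sklearn.metrics.f1_score(yt, yp, zero_division=0)
                    )
                    assert accuracy(c) == pytest.approx(
                        sklearn.metrics.accuracy_score(yt, yp)
                    )


class TestStratifiedFolds:
    def test_study_split_fold_sizes(self):
        labels = ["e33"] * 32 + ["e34"] * 21
        folds = stratified_folds(labels, k=5, seed=0)
        sizes = sorted(len(f) for f in folds)
        assert sizes == [10, 10, 11, 11, 11]
        for fold in folds:
            n33 = sum(labels[i] == "e33" for i in fold)
            n34 = len(fold) - n33
            assert n33 in (6, 7) and n34 in (4, 5)

    def test_partition_property(self):
        labels = ["e33"] * 32 + ["e34"] * 21
        folds = stratified_folds(labels, k=5, seed=3)
        flat = np.concatenate(folds)
        assert sorted(flat.tolist()) == list(range(53))

    def test_deterministic_and_seed_sensitive(self):
        labels = ["a"] * 20 + ["b"] * 15
        f1 = stratified_folds(labels, seed=5)
        f2 = stratified_folds(labels, seed=5)
        f3 = stratified_folds(labels, seed=6)
        assert all(np.array_equal(a, b) for a, b in zip(f1, f2))
        assert any(not np.array_equal(a, b) for a, b in zip(f1, f3))

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds(["a"] * 10 + ["b"] * 3, k=5)


class TestDesignMatrix:
    def test_encoding(self):
        df = pd.DataFrame(
            {
                "end_error": [1.0, 2.0],
                "sex": ["male", "female"],
                "occupation": [0, 2],
                "label": ["e33", "e34"],
            }
        )
        X, y, names = design_matrix(df)
        assert y.tolist() == [0, 1]
        assert "sex_male" in names and "occupation_2" in names
        assert X[0, names.index("sex_male")] == 1.0

    def test_missing_labels_and_nonfinite_rejected(self):
        df = make_table()
        with pytest.raises(ValueError):
            design_matrix(df.drop(columns="label"))
        bad = df.copy()
        bad.loc[0, "f0"] = np.nan
        with pytest.raises(ValueError):
            design_matrix(bad)


class TestFitAndScore:
    @pytest.mark.parametrize("algorithm", ["RF", "SVM", "MLP"])
    def test_separable_clusters_reach_perfect_f1(self, algorithm):
        table = make_table(separation=10.0, seed=1)
        res = fit_and_score(
            table, algorithm, grid=HyperGrid(), seed=0,
            compute_importance=False,
        )
        assert res.mean_f1 == 1.0
        assert res.mean_accuracy == 1.0

    def test_deterministic_given_seed(self):
        table = make_table(separation=1.0, seed=2)
        a = fit_and_score(table, "RF", seed=4)
        b = fit_and_score(table, "RF", seed=4)
        assert a.fold_f1 == b.fold_f1
        assert a.importance == b.importance

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            fit_and_score(make_table(), "XGB")

    def test_no_leakage_of_heldout_rows(self):
        """Poisoning the held-out rows of one fold must not move that
        fold's training-side standardisation statistics."""
        table = make_table(separation=1.0, seed=3)
        res = fit_and_score(
            table, "SVM", grid=HyperGrid.reduced(), seed=0,
            compute_importance=False, capture_internals=True,
        )
        folds = stratified_folds(table["label"].to_numpy(), k=5, seed=0)
        poisoned = table.copy()
        cols = [c for c in table.columns if c != "label"]
        poisoned.loc[poisoned.index[folds[0]], cols] = 1e6
        res_p = fit_and_score(
            poisoned, "SVM", grid=HyperGrid.reduced(), seed=0,
            compute_importance=False, capture_internals=True,
        )
        np.testing.assert_allclose(
            res.fold_details[0]["scaler_mean"], res_p.fold_details[0]["scaler_mean"]
        )
        assert not np.allclose(
            res.fold_details[1]["scaler_mean"], res_p.fold_details[1]["scaler_mean"]
        )

    def test_chosen_params_come_from_grid(self):
        table = make_table(separation=2.0, seed=5)
        grid = HyperGrid.reduced()
        res = fit_and_score(table, "SVM", grid=grid, seed=1, compute_importance=False)
        for params in res.chosen_params:
            assert params["C"] in grid.svm_C and params["kernel"] in grid.svm_kernels


class TestImportance:
    @pytest.mark.parametrize("algorithm", ["RF", "SVM", "MLP"])
    def test_single_signal_feature_dominates(self, algorithm):
        table = make_table(n_per_class=30, separation=6.0, seed=7)
        res = fit_and_score(table, algorithm, grid=HyperGrid.reduced(), seed=0)
        imp = res.importance
        assert imp["f0"] == max(imp.values())
        assert all(imp["f0"] > v for k, v in imp.items() if k != "f0")
        assert sum(imp.values()) == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_importance_is_diffuse(self):
        shares = []
        for seed in range(3):
            table = make_table(n_per_class=25, separation=0.0, seed=seed)
            res = fit_and_score(table, "RF", grid=HyperGrid.reduced(), seed=seed)
            shares.append(max(res.importance.values()))
        uniform = 1.0 / 6
        assert np.mean(shares) < 3 * uniform


class TestRunAll:
    def test_summary_shape_and_best_flags(self):
        tables = {
            t: make_table(n_per_class=12, separation=1.0, seed=t) for t in range(1, 4)
        }
        summary, results = run_all(
            tables,
            feature_sets=("all", "no_end_error"),
            grid=HyperGrid.reduced(),
            nested=False,
            compute_importance=False,
            seed=0,
        )
        assert len(summary) == 3 * 2 * 3  # trials x feature sets x algorithms
        for (fs, tid), sub in summary.groupby(["feature_set", "trial_id"]):
            assert sub["best_f1"].sum() == 1
            assert sub["best_accuracy"].sum() == 1
        best = best_per_trial(summary, "all")
        assert len(best) == 3
        assert set(best["best_f1_algorithm"]).issubset({"RF", "SVM", "MLP"})

    def test_feature_set_filter_drops_columns(self):
        df = make_table(n_per_class=10, separation=5.0, seed=0)
        df = df.rename(columns={"f0": "end_error"})
        summary, results = run_all(
            {1: df},
            feature_sets=("all", "no_end_error"),
            grid=HyperGrid.reduced(),
            nested=False,
            compute_importance=True,
            seed=0,
        )
        imp_all = results[(1, "all", "RF")].importance
        imp_no = results[(1, "no_end_error", "RF")].importance
        assert "end_error" in imp_all and "end_error" not in imp_no
        # The only informative column removed: F1 must not improve.
        s = summary.set_index(["feature_set", "algorithm"])
        assert (
            s.loc[("no_end_error", "RF"), "mean_f1"]
            <= s.loc[("all", "RF"), "mean_f1"]
        )


def test_permutation_null_centers_near_chance():
    """Best-of-algorithms F1 under permuted labels on a noise table spans a
    band around chance that contains the observed noise-table score."""
    table = make_table(n_per_class=12, separation=0.0, seed=9)
    null = permutation_null_best_f1(
        table, n_permutations=30, algorithms=("SVM",), seed=0
    )
    lo, hi = np.percentile(null, [2.5, 97.5])
    obs = fit_and_score(
        table, "SVM", grid=HyperGrid.reduced(), nested=False,
        compute_importance=False, seed=123,
    ).mean_f1
    assert lo - 1e-9 <= obs <= hi + 1e-9
    assert 0.2 < np.median(null) < 0.85
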
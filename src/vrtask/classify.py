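"""Per-trial classification of genetic-risk group labels.

Each of the nine task trials yields its own feature table (one row per
participant); trials involve different rotation sequences and are never
pooled.  Three standard algorithms are compared — random forest (RF),
support vector machine (SVM, linear and RBF kernels over a fixed C grid)
and multi-layer perceptron (MLP, over a fixed alpha grid) — under
stratified five-fold cross-validation.  The positive class is the risk
group (e34).

Performance is summarised by the F1 score computed directly from confusion
counts, ``TP / (TP + 0.5 (FP + FN))``, and by accuracy.  Hyperparameters
are selected by an inner grid search on the training portion of each outer
fold (nested mode, the default, which keeps selection leakage out of the
reported score); a non-nested "naive" mode that picks the grid point with
the best outer-CV mean is provided for comparison and for cheap permutation
nulls.  Feature importances come from impurity for RF and from held-out
permutation importance for SVM/MLP, averaged over folds, clipped at zero
and normalised to sum to one.

Chance level is calibrated empirically by label permutation rather than
assumed from a closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "POSITIVE_CLASS",
    "ConfusionCounts",
    "HyperGrid",
    "CVResult",
    "f1_score",
    "accuracy",
    "stratified_folds",
    "design_matrix",
    "fit_and_score",
    "run_all",
    "best_per_trial",
    "permutation_null_best_f1",
    "FEATURE_SETS",
]

POSITIVE_CLASS = "e34"
ALGORITHMS = ("RF", "SVM", "MLP")

# Named column filters: which table columns enter the design matrix.
FEATURE_SETS: dict[str, Callable[[str], bool]] = {
    "all": lambda c: True,
    "no_end_error": lambda c: c != "end_error",
    "no_demographics": lambda c: c not in ("age", "sex", "occupation"),
}


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with e34 as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def f1_score(c: ConfusionCounts) -> float:
    """F1 = TP / (TP + 0.5 (FP + FN)); 0 (with a warning) if no positives
    appear anywhere."""
    denom = c.tp + 0.5 * (c.fp + c.fn)
    if denom == 0:
        warnings.warn("F1 undefined: no positive instances; returning 0.0")
        return 0.0
    return c.tp / denom


def accuracy(c: ConfusionCounts) -> float:
    """Fraction of correctly classified participants."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    return (c.tp + c.tn) / c.total


@dataclass(frozen=True)
class HyperGrid:
    """Hyperparameter grids of the three algorithms.

    The SVM C grid, the SVM kernels and the MLP alpha grid are the task's
    fixed defaults; RF runs with standard defaults and no grid.  The
    ``reduced()`` constructor trades grid resolution and model size for
    speed in large simulation studies.
    """

    svm_C: tuple = (0.5, 1, 3, 5, 10, 20)
    svm_kernels: tuple = ("linear", "rbf")
    mlp_alpha: tuple = (0.0001, 0.0005, 0.001, 0.002)
    rf_n_estimators: int = 100
    mlp_hidden: tuple = (100,)
    mlp_max_iter: int = 400

    @classmethod
    def reduced(cls) -> "HyperGrid":
        return cls(
            svm_C=(1, 10),
            svm_kernels=("linear", "rbf"),
            mlp_alpha=(0.0001, 0.001),
            rf_n_estimators=60,
            mlp_hidden=(25,),
            mlp_max_iter=150,
        )

    def param_grid(self, algorithm: str) -> list[dict]:
        if algorithm == "RF":
            return [{}]
        if algorithm == "SVM":
            return [
                {"C": C, "kernel": k} for k in self.svm_kernels for C in self.svm_C
            ]
        if algorithm == "MLP":
            return [{"alpha": a} for a in self.mlp_alpha]
        raise ValueError(f"unknown algorithm {algorithm!r}")


@dataclass
class CVResult:
    """Cross-validation outcome for one (trial, algorithm, feature-set) cell."""

    trial_id: int
    algorithm: str
    feature_set: str
    fold_confusions: list
    fold_f1: list
    fold_accuracy: list
    mean_f1: float
    mean_accuracy: float
    chosen_params: list
    importance: dict = field(default_factory=dict)
    fold_details: list = field(default_factory=list)


def stratified_folds(
    labels: Sequence[str], k: int = 5, seed: int = 0
) -> list[np.ndarray]:
    """Partition indices into k stratified, shuffled, balanced folds.

    Per-fold class counts differ from exact proportionality by at most one
    participant; within each class the members are shuffled by ``seed``.
    Classes are dealt largest-first and each class's surplus members go to
    the currently smallest folds, so total fold sizes are as even as
    possible (e.g. 32/21 labels at k=5 give sizes 11, 11, 11, 10, 10).
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs at least k={k} members")
    folds: list[list[int]] = [[] for _ in range(k)]
    # Larger classes first so surplus placement can balance fold totals.
    for cls in classes[np.argsort(-counts, kind="stable")]:
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(idx.size)]
        q, r = divmod(idx.size, k)
        sizes = np.full(k, q)
        if r:
            totals = np.array([len(f) for f in folds])
            # Smallest folds (earliest index on ties) receive the extras.
            extras = np.lexsort((np.arange(k), totals))[:r]
            sizes[extras] += 1
        start = 0
        for f, size in zip(folds, sizes):
            f.extend(idx[start : start + size].tolist())
            start += size
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def design_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Encode a feature table into (X, y, column names).

    ``sex`` becomes a 0/1 male indicator, ``occupation`` is one-hot
    encoded, and every other non-label column is used as-is.  y is 1 for
    the positive (risk) class.
    """
    if "label" not in table.columns:
        raise ValueError("table must have a 'label' column")
    if table["label"].isna().any():
        raise ValueError("missing labels")
    cols: dict[str, np.ndarray] = {}
    for c in table.columns:
        if c == "label":
            continue
        if c == "sex":
            cols["sex_male"] = (table[c] == "male").to_numpy(float)
        elif c == "occupation":
            occ = table[c].astype(int)
            for level in range(int(occ.max()) + 1):
                cols[f"occupation_{level}"] = (occ == level).to_numpy(float)
        else:
            cols[c] = table[c].to_numpy(float)
    X = np.column_stack(list(cols.values())) if cols else np.empty((len(table), 0))
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    y = (table["label"] == POSITIVE_CLASS).to_numpy(int)
    return X, y, list(cols.keys())


def _make_model(algorithm: str, params: dict, grid: HyperGrid, seed: int):
    if algorithm == "RF":
        return RandomForestClassifier(
            n_estimators=grid.rf_n_estimators, random_state=seed
        )
    if algorithm == "SVM":
        return SVC(C=params["C"], kernel=params["kernel"], random_state=seed)
    if algorithm == "MLP":
        return MLPClassifier(
            alpha=params["alpha"],
            hidden_layer_sizes=grid.mlp_hidden,
            max_iter=grid.mlp_max_iter,
            random_state=seed,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


def _safe_f1(c: ConfusionCounts) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return f1_score(c)


def _fit_predict(model, X_tr, y_tr, X_te) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter on tiny n
        model.fit(X_tr, y_tr)
        return model.predict(X_te)


def _inner_select(
    algorithm: str,
    grid: HyperGrid,
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    seed: int,
    inner_k: int = 3,
) -> dict:
    """Pick the grid point with the best mean F1 over an inner stratified CV
    of the training portion only."""
    settings = grid.param_grid(algorithm)
    if len(settings) == 1:
        return settings[0]
    inner = stratified_folds(y_tr.astype(str), k=inner_k, seed=seed)
    best_params, best_score = settings[0], -1.0
    for params in settings:
        scores = []
        for test_idx in inner:
            mask = np.zeros(y_tr.size, dtype=bool)
            mask[test_idx] = True
            model = _make_model(algorithm, params, grid, seed)
            pred = _fit_predict(model, X_tr[~mask], y_tr[~mask], X_tr[mask])
            scores.append(_safe_f1(_confusion(y_tr[mask], pred)))
        score = float(np.mean(scores))
        if score > best_score:
            best_params, best_score = params, score
    return best_params


def _permutation_importance(
    model, X_te: np.ndarray, y_te: np.ndarray, rng: np.random.Generator, n_repeats: int = 10
) -> np.ndarray:
    """Held-out permutation importance under the F1 score."""
    base = _safe_f1(_confusion(y_te, model.predict(X_te)))
    n_features = X_te.shape[1]
    imp = np.zeros(n_features)
    for j in range(n_features):
        drops = []
        for _ in range(n_repeats):
            Xp = X_te.copy()
            Xp[:, j] = Xp[rng.permutation(X_te.shape[0]), j]
            drops.append(base - _safe_f1(_confusion(y_te, model.predict(Xp))))
        imp[j] = np.mean(drops)
    return imp


def fit_and_score(
    table: pd.DataFrame,
    algorithm: str,
    grid: HyperGrid | None = None,
    k: int = 5,
    seed: int = 0,
    *,
    trial_id: int = 0,
    feature_set: str = "all",
    nested: bool = True,
    compute_importance: bool = True,
    capture_internals: bool = False,
) -> CVResult:
    """Stratified k-fold cross-validation of one algorithm on one trial table.

    Standardisation statistics and hyperparameter selection use training
    folds only.  In nested mode (default) each outer fold runs its own
    inner 3-fold grid search; in naive mode one grid point is chosen by its
    outer-CV mean F1 and that setting's fold scores are reported.
    """
    grid = grid or HyperGrid()
    if algorithm not in ALGORITHMS:
        raise ValueError(f"algorithm must be one of {ALGORITHMS}")
    X, y, colnames = design_matrix(table)
    labels = table["label"].to_numpy()
    folds = stratified_folds(labels, k=k, seed=seed)
    fold_seeds = np.random.SeedSequence(seed).generate_state(2 * k) % (2**31)

    def run_fold(
        fold_i: int,
        test_idx: np.ndarray,
        params: dict | None,
        with_importance: bool = compute_importance,
    ):
        mask = np.zeros(y.size, dtype=bool)
        mask[test_idx] = True
        scaler = StandardScaler().fit(X[~mask])
        X_tr, X_te = scaler.transform(X[~mask]), scaler.transform(X[mask])
        y_tr, y_te = y[~mask], y[mask]
        mseed = int(fold_seeds[fold_i])
        if params is None:
            params = _inner_select(algorithm, grid, X_tr, y_tr, mseed)
        model = _make_model(algorithm, params, grid, mseed)
        pred = _fit_predict(model, X_tr, y_tr, X_te)
        conf = _confusion(y_te, pred)
        detail = {"scaler_mean": scaler.mean_.copy()} if capture_internals else None
        imp = None
        if with_importance:
            if algorithm == "RF":
                imp = model.feature_importances_.copy()
            else:
                rng = np.random.default_rng(int(fold_seeds[k + fold_i]))
                imp = _permutation_importance(model, X_te, y_te, rng)
        return conf, params, imp, detail

    if nested:
        outcomes = [run_fold(i, idx, None) for i, idx in enumerate(folds)]
    else:
        # Naive mode: one grid point, chosen by its outer-CV mean F1.
        # Importances are only computed for the winning setting, via one
        # extra refit pass when they are requested.
        best_params, best_outs, best_score = None, None, -1.0
        for params in grid.param_grid(algorithm):
            outs = [
                run_fold(i, idx, params, with_importance=False)
                for i, idx in enumerate(folds)
            ]
            score = float(np.mean([_safe_f1(o[0]) for o in outs]))
            if score > best_score:
                best_params, best_outs, best_score = params, outs, score
        if compute_importance:
            outcomes = [run_fold(i, idx, best_params) for i, idx in enumerate(folds)]
        else:
            outcomes = best_outs

    confusions = [o[0] for o in outcomes]
    fold_f1 = [_safe_f1(c) for c in confusions]
    fold_acc = [accuracy(c) for c in confusions]
    importance: dict[str, float] = {}
    if compute_importance:
        imps = np.stack([o[2] for o in outcomes]).mean(axis=0)
        imps = np.clip(imps, 0.0, None)
        if imps.sum() == 0:
            warnings.warn("degenerate all-zero importances; using uniform")
            imps = np.ones_like(imps)
        imps = imps / imps.sum()
        importance = dict(zip(colnames, imps.tolist()))
    return CVResult(
        trial_id=trial_id,
        algorithm=algorithm,
        feature_set=feature_set,
        fold_confusions=confusions,
        fold_f1=fold_f1,
        fold_accuracy=fold_acc,
        mean_f1=float(np.mean(fold_f1)),
        mean_accuracy=float(np.mean(fold_acc)),
        chosen_params=[o[1] for o in outcomes],
        importance=importance,
        fold_details=[o[3] for o in outcomes if o[3] is not None],
    )


def _filter_table(table: pd.DataFrame, feature_set: str) -> pd.DataFrame:
    try:
        keep = FEATURE_SETS[feature_set]
    except KeyError:
        raise ValueError(f"unknown feature set {feature_set!r}") from None
    cols = [c for c in table.columns if c == "label" or keep(c)]
    return table[cols]


def run_all(
    tables: dict[int, pd.DataFrame],
    feature_sets: Sequence[str] = ("all", "no_end_error"),
    algorithms: Sequence[str] = ALGORITHMS,
    seed: int = 0,
    grid: HyperGrid | None = None,
    nested: bool = True,
    compute_importance: bool = True,
    k: int = 5,
) -> tuple[pd.DataFrame, dict]:
    """Cross-validate every trial x feature-set x algorithm cell.

    Returns a tidy summary frame (one row per cell, with per-trial best
    flags for F1 and accuracy) and the dict of full CVResults keyed by
    (trial_id, feature_set, algorithm).
    """
    grid = grid or HyperGrid()
    rows = []
    results: dict[tuple, CVResult] = {}
    for feature_set in feature_sets:
        for trial_id in sorted(tables):
            table = _filter_table(tables[trial_id], feature_set)
            for algorithm in algorithms:
                res = fit_and_score(
                    table,
                    algorithm,
                    grid=grid,
                    k=k,
                    seed=seed,
                    trial_id=trial_id,
                    feature_set=feature_set,
                    nested=nested,
                    compute_importance=compute_importance,
                )
                results[(trial_id, feature_set, algorithm)] = res
                rows.append(
                    {
                        "trial_id": trial_id,
                        "feature_set": feature_set,
                        "algorithm": algorithm,
                        "mean_f1": res.mean_f1,
                        "mean_accuracy": res.mean_accuracy,
                    }
                )
    summary = pd.DataFrame(rows)
    summary["best_f1"] = False
    summary["best_accuracy"] = False
    for (fs, tid), sub in summary.groupby(["feature_set", "trial_id"]):
        summary.loc[sub["mean_f1"].idxmax(), "best_f1"] = True
        summary.loc[sub["mean_accuracy"].idxmax(), "best_accuracy"] = True
    return summary, results


def best_per_trial(summary: pd.DataFrame, feature_set: str = "all") -> pd.DataFrame:
    """Best algorithm per trial for F1 and accuracy (the report's shape)."""
    sub = summary[summary["feature_set"] == feature_set]
    rows = []
    for trial_id, g in sub.groupby("trial_id"):
        f1_row = g.loc[g["mean_f1"].idxmax()]
        acc_row = g.loc[g["mean_accuracy"].idxmax()]
        rows.append(
            {
                "trial_id": trial_id,
                "best_f1": f1_row["mean_f1"],
                "best_f1_algorithm": f1_row["algorithm"],
                "best_accuracy": acc_row["mean_accuracy"],
                "best_accuracy_algorithm": acc_row["algorithm"],
            }
        )
    return pd.DataFrame(rows)


def permutation_null_best_f1(
    table: pd.DataFrame,
    n_permutations: int = 200,
    algorithms: Sequence[str] = ALGORITHMS,
    grid: HyperGrid | None = None,
    k: int = 5,
    seed: int = 0,
    nested: bool = False,
) -> np.ndarray:
    """Empirical chance distribution of the best-of-algorithms mean F1.

    Labels are permuted ``n_permutations`` times; for each permutation the
    full per-trial analysis (all algorithms, same CV machinery) is re-run
    and the best mean F1 recorded.  The 2.5th-97.5th percentile range of
    the result is the central 95% permutation band.
    """
    grid = grid or HyperGrid.reduced()
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = table.copy()
        perm["label"] = rng.permutation(perm["label"].to_numpy())
        scores = [
            fit_and_score(
                perm,
                alg,
                grid=grid,
                k=k,
                seed=int(rng.integers(2**31)),
                nested=nested,
                compute_importance=False,
            ).mean_f1
            for alg in algorithms
        ]
        null[b] = max(scores)
    return null
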
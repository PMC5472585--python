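"""Classifier training and evaluation under four-fold cross-validation.

The audit question is not "which model wins" but "does the error keep falling
as we add features or data, or has it hit a floor". Everything here therefore
revolves around misclassification-rate curves under a fixed four-fold
stratified cross-validation protocol:

* :func:`error_vs_num_features` — error as a function of the number of
  features kept, with features ranked by point-biserial correlation with the
  label INSIDE each training fold (no test-fold leakage);
* :func:`error_vs_dataset_size` — error as a function of the number of
  reactions, on nested stratified subsamples so the curve is comparable
  across sizes;
* :func:`gini_importance_stability` — mean-decrease-in-impurity feature
  importances across repeated runs, with Spearman rank agreement;
* :func:`lasso_logistic_check` — an L1-logistic cross-check of the
  tree-ensemble accuracies;
* :func:`rf_regression_rmse` — the regression-instead-of-classification
  check (pooled 4-fold RMSE on the target's natural scale);
* :func:`pca_projection` — standardized PCA scores per class for overlap
  inspection.

All randomness is controlled by explicit seeds; rows are processed in
row-id-sorted order so results are invariant to row permutation of the input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import (
    ExtraTreesClassifier,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "FeatureMatrix",
    "ModelSpec",
    "CVResult",
    "Curve",
    "correlation_rank",
    "cv_train_eval",
    "error_vs_num_features",
    "error_vs_dataset_size",
    "gini_importance_stability",
    "lasso_logistic_check",
    "rf_regression_rmse",
    "pca_projection",
    "stratified_nested_subsamples",
]

FAMILIES = ("descriptor", "fingerprint", "cld", "condition")


@dataclass
class FeatureMatrix:
    """Named feature columns x reaction rows, with feature-family provenance."""

    values: np.ndarray
    columns: list[str]
    families: list[str]
    row_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, p = self.values.shape
        if len(self.columns) != p or len(self.families) != p or len(self.row_ids) != n:
            raise ValueError("columns/families/row_ids must align with values")
        if len(set(self.columns)) != p:
            raise ValueError("column names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @classmethod
    def from_array(
        cls,
        X: np.ndarray,
        columns: Sequence[str] | None = None,
        families: Sequence[str] | str = "descriptor",
        row_ids: Sequence[str] | None = None,
    ) -> "FeatureMatrix":
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        cols = list(columns) if columns is not None else [f"f{j}" for j in range(p)]
        fams = [families] * p if isinstance(families, str) else list(families)
        ids = list(row_ids) if row_ids is not None else [f"r{i:08d}" for i in range(n)]
        return cls(X, cols, fams, ids)

    @property
    def shape(self):
        return self.values.shape

    def select_columns(self, names: Sequence[str]) -> "FeatureMatrix":
        pos = {c: j for j, c in enumerate(self.columns)}
        idx = [pos[n] for n in names]
        return FeatureMatrix(
            self.values[:, idx],
            [self.columns[j] for j in idx],
            [self.families[j] for j in idx],
            list(self.row_ids),
        )

    def take_rows(self, idx: Sequence[int]) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(
            self.values[idx],
            list(self.columns),
            list(self.families),
            [self.row_ids[i] for i in idx],
        )

    def sorted_by_row_id(self) -> tuple["FeatureMatrix", np.ndarray]:
        order = np.asarray(sorted(range(len(self.row_ids)), key=lambda i: self.row_ids[i]))
        return self.take_rows(order), order


@dataclass(frozen=True)
class ModelSpec:
    """Classifier/regressor configuration.

    Defaults: random forest with 500 trees, sqrt(p) features per split,
    unlimited depth. ``kind='ert'`` swaps in extremely randomized trees
    (random split thresholds); ``kind='lasso_logistic'`` an L1-penalized
    logistic regression with the penalty chosen by internal cross-validation;
    ``kind='rf_regressor'`` the regression forest. ``select_k`` activates
    per-training-fold correlation-based feature selection.
    """

    kind: str = "rf"
    n_estimators: int = 500
    max_features: str | int | float = "sqrt"
    max_depth: int | None = None
    select_k: int | None = None
    selection_scope: str = "fold"  # 'fold' (leakage-safe) or 'global'
    lasso_cs: int = 5
    lasso_inner_folds: int = 3

    def build(self, seed: int):
        if self.kind == "rf":
            return RandomForestClassifier(
                n_estimators=self.n_estimators,
                max_features=self.max_features,
                max_depth=self.max_depth,
                random_state=seed,
                n_jobs=1,
            )
        if self.kind == "ert":
            return ExtraTreesClassifier(
                n_estimators=self.n_estimators,
                max_features=self.max_features,
                max_depth=self.max_depth,
                random_state=seed,
                n_jobs=1,
            )
        if self.kind == "lasso_logistic":
            return make_pipeline(
                StandardScaler(),
                LogisticRegressionCV(
                    penalty="l1",
                    solver="liblinear",
                    Cs=self.lasso_cs,
                    cv=self.lasso_inner_folds,
                    random_state=seed,
                    max_iter=2000,
                ),
            )
        if self.kind == "rf_regressor":
            return RandomForestRegressor(
                n_estimators=self.n_estimators,
                max_features=self.max_features,
                max_depth=self.max_depth,
                random_state=seed,
                n_jobs=1,
            )
        raise ValueError(f"unknown model kind {self.kind!r}")


@dataclass
class CVResult:
    """Per-fold misclassification rates under k-fold cross-validation."""

    fold_errors: list[float]
    mean_error: float
    std_error: float
    test_fold_ids: list[list[str]]
    seed: int
    #: per-fold feature names used for training (None when no selection active)
    selected_features: list[list[str]] | None = None

    def __post_init__(self):
        if not np.isclose(self.mean_error, float(np.mean(self.fold_errors))):
            raise ValueError("mean_error must be the average of fold_errors")


@dataclass
class Curve:
    """A cross-validation error curve: x vs mean error with std bars."""

    x: list[float]
    y: list[float]
    yerr: list[float]

    def __post_init__(self):
        if not (len(self.x) == len(self.y) == len(self.yerr)):
            raise ValueError("x, y, yerr must have equal length")


def _as_matrix(X) -> FeatureMatrix:
    if isinstance(X, FeatureMatrix):
        return X
    return FeatureMatrix.from_array(np.asarray(X))


def correlation_rank(X, y) -> list[tuple[str, float]]:
    """Features ordered by decreasing |point-biserial correlation| with y.

    Point-biserial correlation is the Pearson correlation between a feature
    column and the 0/1 label. Constant columns get correlation 0 and rank
    last; ties are broken by column name.
    """
    fm = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    V = fm.values
    yc = y - y.mean()
    xc = V - V.mean(axis=0)
    sx = xc.std(axis=0)
    sy = yc.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).mean(axis=0) / (sx * sy)
    r = np.where(sx == 0, 0.0, r)
    order = sorted(range(len(fm.columns)), key=lambda j: (-abs(r[j]), fm.columns[j]))
    return [(fm.columns[j], float(r[j])) for j in order]


def _check_classes(y: np.ndarray, folds: int):
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < folds:
        raise ValueError(
            f"need >= {folds} rows per class, got class counts {dict(zip(classes, counts))}"
        )


def cv_train_eval(
    X,
    y,
    model_spec: ModelSpec = ModelSpec(),
    folds: int = 4,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validated misclassification rate.

    The dataset is split into ``folds`` stratified parts; the model is
    trained on all but one and scored on the held-out part, and the fold
    errors are averaged. When ``model_spec.select_k`` is set, the
    correlation-based feature ranking is recomputed inside each training fold
    (``selection_scope='fold'``) so no test-fold information enters the
    selection; ``selection_scope='global'`` ranks once on the full data
    instead (leaky, provided for protocol-sensitivity checks only).

    Rows are internally sorted by row id before fold assignment, so the
    result depends only on (row contents, ids, seed), not on input order.
    """
    fm = _as_matrix(X)
    y = np.asarray(y)
    order = np.asarray(sorted(range(len(fm.row_ids)), key=lambda i: fm.row_ids[i]))
    fm, y = fm.take_rows(order), y[order]
    _check_classes(y, folds)

    global_top = None
    if model_spec.select_k is not None and model_spec.selection_scope == "global":
        global_top = [n for n, _ in correlation_rank(fm, y)[: model_spec.select_k]]

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_errors, test_ids, selected = [], [], []
    for tr, te in skf.split(fm.values, y):
        Xtr, Xte = fm.take_rows(tr), fm.take_rows(te)
        if model_spec.select_k is not None:
            if global_top is not None:
                keep = global_top
            else:
                keep = [n for n, _ in correlation_rank(Xtr, y[tr])[: model_spec.select_k]]
            selected.append(list(keep))
            Xtr, Xte = Xtr.select_columns(keep), Xte.select_columns(keep)
        model = model_spec.build(seed)
        model.fit(Xtr.values, y[tr])
        pred = model.predict(Xte.values)
        fold_errors.append(float(np.mean(pred != y[te])))
        test_ids.append(list(Xte.row_ids))
    return CVResult(
        fold_errors=fold_errors,
        mean_error=float(np.mean(fold_errors)),
        std_error=float(np.std(fold_errors)),
        test_fold_ids=test_ids,
        seed=seed,
        selected_features=selected or None,
    )


def error_vs_num_features(
    X, y, k_grid: Sequence[int], model_spec: ModelSpec = ModelSpec(), seed: int = 0,
    folds: int = 4,
) -> Curve:
    """Cross-validated error as a function of the number of features kept."""
    fm = _as_matrix(X)
    if len(k_grid) == 0:
        raise ValueError("k_grid must be non-empty")
    if max(k_grid) > fm.shape[1]:
        raise ValueError("k_grid exceeds the number of columns")
    ys, errs = [], []
    for k in k_grid:
        res = cv_train_eval(fm, y, replace(model_spec, select_k=int(k)), folds, seed)
        ys.append(res.mean_error)
        errs.append(res.std_error)
    return Curve(list(map(float, k_grid)), ys, errs)


def stratified_nested_subsamples(
    y, size_grid: Sequence[int], seed: int
) -> dict[int, np.ndarray]:
    """Nested, stratified, seeded row subsets: smaller samples are subsets of
    larger ones, and each preserves the class proportions of y."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes = np.unique(y)
    perms = {c: rng.permutation(np.flatnonzero(y == c)) for c in classes}
    props = {c: len(perms[c]) / len(y) for c in classes}
    out = {}
    for n in sorted(size_grid):
        take = {c: int(round(n * props[c])) for c in classes}
        # fix rounding drift deterministically on the largest class
        drift = n - sum(take.values())
        take[max(classes, key=lambda c: props[c])] += drift
        idx = np.concatenate([perms[c][: take[c]] for c in classes])
        out[int(n)] = np.sort(idx)
    return out


def error_vs_dataset_size(
    X, y, size_grid: Sequence[int], model_spec: ModelSpec = ModelSpec(),
    seed: int = 0, folds: int = 4,
) -> Curve:
    """Cross-validated error as a function of dataset size.

    Subsamples are stratified, seeded and nested so the curve reflects sample
    size, not resampling noise. Sizes leaving fewer than ``folds`` rows in
    some class are skipped with a warning.
    """
    fm = _as_matrix(X)
    y = np.asarray(y)
    if max(size_grid) > fm.shape[0]:
        raise ValueError("size_grid exceeds the number of rows")
    subsets = stratified_nested_subsamples(y, size_grid, seed)
    xs, ys, errs = [], [], []
    for n in sorted(size_grid):
        idx = subsets[int(n)]
        _, counts = np.unique(y[idx], return_counts=True)
        if len(counts) < 2 or counts.min() < max(folds, 4):
            warnings.warn(f"size {n}: too few rows per class, skipped")
            continue
        res = cv_train_eval(fm.take_rows(idx), y[idx], model_spec, folds, seed)
        xs.append(float(n))
        ys.append(res.mean_error)
        errs.append(res.std_error)
    return Curve(xs, ys, errs)


@dataclass
class ImportanceStability:
    """Gini (mean-decrease-in-impurity) importances across repeated runs."""

    feature_names: list[str]
    importances: np.ndarray  # (n_runs, p)
    mean: np.ndarray
    std: np.ndarray
    rank_agreement: float  # mean pairwise Spearman correlation across runs
    seeds: list[int]

    def top_feature(self, run: int | None = None) -> str:
        imp = self.mean if run is None else self.importances[run]
        return self.feature_names[int(np.argmax(imp))]


def gini_importance_stability(
    X, y, model_spec: ModelSpec = ModelSpec(), n_runs: int = 5,
    seeds: Sequence[int] | None = None,
) -> ImportanceStability:
    """Fit the ensemble repeatedly and report importance stability.

    Each run fits on the full data with a different seed; Gini importances
    (mean decrease in impurity) are collected and the mean pairwise Spearman
    rank correlation across runs summarizes their stability.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    fm = _as_matrix(X)
    y = np.asarray(y)
    seeds = list(seeds) if seeds is not None else list(range(n_runs))
    if len(seeds) != n_runs:
        raise ValueError("need one seed per run")
    runs = []
    for s in seeds:
        model = model_spec.build(int(s))
        model.fit(fm.values, y)
        runs.append(np.asarray(model.feature_importances_))
    imp = np.vstack(runs)
    rhos = [
        stats.spearmanr(imp[a], imp[b]).statistic
        for a in range(n_runs)
        for b in range(a + 1, n_runs)
    ]
    return ImportanceStability(
        feature_names=list(fm.columns),
        importances=imp,
        mean=imp.mean(axis=0),
        std=imp.std(axis=0),
        rank_agreement=float(np.mean(rhos)),
        seeds=[int(s) for s in seeds],
    )


def lasso_logistic_check(
    X, y, subsample_n: int | None = None, seed: int = 0, folds: int = 4,
    model_spec: ModelSpec | None = None,
) -> float:
    """Four-fold CV accuracy of L1-penalized logistic regression.

    The penalty strength is chosen by internal cross-validation on the
    training folds only. ``subsample_n`` evaluates on a stratified seeded
    subsample, mirroring the practice of checking a cheaper linear model on a
    subset of a large corpus.
    """
    fm = _as_matrix(X)
    y = np.asarray(y)
    if subsample_n is not None:
        if subsample_n > fm.shape[0]:
            raise ValueError("subsample_n exceeds the number of rows")
        idx = stratified_nested_subsamples(y, [subsample_n], seed)[int(subsample_n)]
        fm, y = fm.take_rows(idx), y[idx]
    spec = model_spec or ModelSpec(kind="lasso_logistic")
    res = cv_train_eval(fm, y, spec, folds, seed)
    return 1.0 - res.mean_error


def rf_regression_rmse(
    X, y_continuous, seed: int = 0, folds: int = 4,
    model_spec: ModelSpec | None = None,
) -> float:
    """Pooled 4-fold CV root-mean-square error of random-forest regression,
    on the target's natural scale."""
    fm = _as_matrix(X)
    yc = np.asarray(y_continuous, dtype=float)
    if np.all(yc == yc[0]):
        warnings.warn("constant regression target; RMSE is 0")
        return 0.0
    order = np.asarray(sorted(range(len(fm.row_ids)), key=lambda i: fm.row_ids[i]))
    fm, yc = fm.take_rows(order), yc[order]
    spec = model_spec or ModelSpec(kind="rf_regressor")
    rng = np.random.default_rng(seed)
    # within each rank-stratum, shuffle fold assignment
    fold_of = np.empty(len(yc), dtype=int)
    ranks = np.argsort(np.argsort(yc, kind="stable"), kind="stable")
    for start in range(0, len(yc), folds):
        members = np.flatnonzero((ranks >= start) & (ranks < start + folds))
        fold_of[members] = rng.permutation(folds)[: len(members)]
    sq_errors = np.empty(len(yc))
    for f in range(folds):
        te = np.flatnonzero(fold_of == f)
        tr = np.flatnonzero(fold_of != f)
        model = spec.build(seed)
        model.fit(fm.values[tr], yc[tr])
        pred = model.predict(fm.values[te])
        sq_errors[te] = (pred - yc[te]) ** 2
    return float(np.sqrt(sq_errors.mean()))


@dataclass
class PCAProjection:
    """Standardized PCA scores with class labels, for overlap inspection."""

    scores: np.ndarray  # (n, n_components)
    labels: np.ndarray
    explained_variance_ratio: np.ndarray
    components: np.ndarray

    def centroid_separation(self, component: int = 0) -> float:
        """|centroid difference| / pooled std along one component."""
        s = self.scores[:, component]
        a, b = s[self.labels == 0], s[self.labels == 1]
        pooled = np.sqrt((a.var() + b.var()) / 2)
        if pooled == 0:
            return 0.0
        return float(abs(a.mean() - b.mean()) / pooled)


def pca_projection(X, y, n_components: int = 2) -> PCAProjection:
    """Standardized PCA of the feature matrix with class labels attached.

    Component signs follow the convention that the largest-magnitude loading
    of each component is positive, so projections are reproducible across
    runs and platforms.
    """
    fm = _as_matrix(X)
    y = np.asarray(y)
    if fm.shape[1] < n_components:
        raise ValueError("need at least n_components columns")
    Z = StandardScaler().fit_transform(fm.values)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z)
    comps = pca.components_.copy()
    for i in range(n_components):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
            scores[:, i] = -scores[:, i]
    return PCAProjection(
        scores=scores,
        labels=y,
        explained_variance_ratio=pca.explained_variance_ratio_,
        components=comps,
    )
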
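"""Nearest-neighbor bracketing of the Bayes classification error.

The Bayes error R* is the misclassification probability of the optimal
classifier given a feature representation — the irreducible error. It cannot
be computed from data directly, but the asymptotic nearest-neighbor theory of
Cover and Hart brackets it from both sides using only the leave-one-out
nearest-neighbor error rate R_NN. For a binary problem,

    (1 - sqrt(1 - 2 R_NN)) / 2  <=  R*  <=  R_NN,

and for c classes the lower bound generalizes to
((c-1)/c) * (1 - sqrt(1 - c R_NN / (c-1))).

If a cross-validated classifier's error sits close to the upper bound while
the lower bound is far above zero, the remaining error is intrinsic to the
representation rather than to the classifier — the central diagnostic of a
predictability audit.

R_NN is computed exactly (chunked brute-force Euclidean distances on
per-feature standardized columns) with fully deterministic tie-breaking:
distance ties go to the lower row index, vote ties to class 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Sequence

import numpy as np

from .classify import stratified_nested_subsamples

__all__ = [
    "BayesBoundEstimate",
    "BoundCurve",
    "nn_error",
    "cover_hart_bounds",
    "bound_estimate",
    "bound_curve",
]


@dataclass(frozen=True)
class BayesBoundEstimate:
    """A (lower, upper) bracket on the Bayes error R*.

    ``r_nn`` is the leave-one-out k-NN error the bracket derives from;
    metadata (n, k, metric, standardization) makes the estimate reproducible.
    """

    r_nn: float
    lower: float
    upper: float
    n: int
    k: int
    metric: str = "euclidean"
    standardized: bool = True
    estimator: str = "cover-hart-1nn"

    def __post_init__(self):
        if not 0.0 <= self.lower <= self.upper:
            raise ValueError("bounds must satisfy 0 <= lower <= upper")

    def contains(self, r_star: float, slack: float = 0.0) -> bool:
        return self.lower - slack <= r_star <= self.upper + slack

    def to_dict(self) -> dict:
        return {
            "r_nn": self.r_nn,
            "lower": self.lower,
            "upper": self.upper,
            "n": self.n,
            "k": self.k,
            "metric": self.metric,
            "standardized": self.standardized,
            "estimator": self.estimator,
        }


@dataclass
class BoundCurve:
    """Lower/upper Bayes-error bounds as a function of dataset size."""

    sizes: list[int]
    lower: list[float]
    upper: list[float]
    estimates: list[BayesBoundEstimate]

    def __post_init__(self):
        if not (len(self.sizes) == len(self.lower) == len(self.upper)):
            raise ValueError("sizes, lower, upper must align")
        for lo, up in zip(self.lower, self.upper):
            if lo > up:
                raise ValueError("lower must not exceed upper")


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


def nn_error(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 1,
    *,
    standardize: bool = True,
    chunk_size: int = 2048,
) -> float:
    """Leave-one-out k-nearest-neighbor misclassification rate.

    Euclidean metric on per-feature standardized columns. Exact and fully
    deterministic: among equidistant neighbors the lower row index wins, and
    a tied k-vote goes to class 0. Complexity is O(n^2 d) via chunked
    matrix products, which is the regime this audit targets (n up to ~10^5).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("X and y must align")
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} rows")
    Z = _standardize(X) if standardize else X
    sq = np.einsum("ij,ij->i", Z, Z)
    errors = 0
    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        # squared distances from chunk rows to all rows
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * (Z[start:stop] @ Z.T)
        np.maximum(d2, 0.0, out=d2)
        rows = np.arange(start, stop)
        d2[np.arange(stop - start), rows] = np.inf  # exclude self
        if k == 1:
            # np.argmin returns the first (lowest-index) minimizer: the
            # required distance tie-break for free
            nn = np.argmin(d2, axis=1)
            errors += int(np.sum(y[nn] != y[rows]))
        else:
            part = np.argpartition(d2, k, axis=1)[:, : k + 1]
            for r in range(stop - start):
                cand = part[r]
                order = sorted(cand, key=lambda j: (d2[r, j], j))[:k]
                votes = int(np.sum(y[order] == 1))
                pred = 1 if votes > k - votes else 0  # tie -> class 0
                errors += int(pred != y[rows[r]])
    return errors / n


def cover_hart_bounds(r_nn: float, n_classes: int = 2) -> tuple[float, float]:
    """Asymptotic NN bracket on the Bayes error from the NN error rate.

    Binary: lower = (1 - sqrt(1 - 2 r_nn)) / 2, upper = r_nn. For c classes
    the lower bound is ((c-1)/c) * (1 - sqrt(1 - c r_nn / (c-1))); the upper
    bound remains r_nn (the NN risk itself).
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    cap = (n_classes - 1) / n_classes
    if not 0.0 <= r_nn <= cap + 1e-12:
        raise ValueError(f"r_nn must lie in [0, {cap}] for {n_classes} classes")
    r_nn = min(r_nn, cap)
    c = n_classes
    lower = cap * (1.0 - sqrt(max(0.0, 1.0 - c * r_nn / (c - 1))))
    return (lower, r_nn)


def bound_estimate(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 1,
    seed: int = 0,
    *,
    standardize: bool = True,
) -> BayesBoundEstimate:
    """Estimate the Bayes-error bracket for a labeled feature matrix.

    Composes the leave-one-out NN error with the Cover-Hart bounds. The
    computation is deterministic; ``seed`` is recorded for provenance and
    used only by subsampling callers.
    """
    y = np.asarray(y)
    r = nn_error(X, y, k=k, standardize=standardize)
    n_classes = len(np.unique(y))
    lower, upper = cover_hart_bounds(r, n_classes=n_classes)
    return BayesBoundEstimate(
        r_nn=r,
        lower=lower,
        upper=upper,
        n=len(y),
        k=k,
        standardized=standardize,
        estimator=f"cover-hart-{k}nn",
    )


def bound_curve(
    X: np.ndarray,
    y: np.ndarray,
    size_grid: Sequence[int],
    k: int = 1,
    seed: int = 0,
) -> BoundCurve:
    """Bayes-error bounds on nested stratified subsamples of growing size."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if max(size_grid) > len(y):
        raise ValueError("size_grid exceeds the number of rows")
    subsets = stratified_nested_subsamples(y, size_grid, seed)
    sizes, lowers, uppers, ests = [], [], [], []
    for n in sorted(size_grid):
        idx = subsets[int(n)]
        est = bound_estimate(X[idx], y[idx], k=k, seed=seed)
        sizes.append(int(n))
        lowers.append(est.lower)
        uppers.append(est.upper)
        ests.append(est)
    return BoundCurve(sizes, lowers, uppers, ests)
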
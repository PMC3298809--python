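"""Random-forest regression with out-of-bag permutation importance.

The forest is built from scikit-learn regression trees, but the bootstrap
bookkeeping is explicit: each tree records the multiset of in-bag sample
indices, and its out-of-bag (OOB) set is exactly the complement of that
multiset's support. This bookkeeping is what makes the importance measure
well defined: for feature j and tree t,

    d_tj = MSE_t(OOB, X with column j permuted within the OOB subset)
         − MSE_t(OOB, X),

the raw importance of j is the mean of d_tj over trees, and the normalised
importance divides that mean by its standard error over trees
(SD(d_tj)/sqrt(n_trees)) — the z-score convention of the classical
randomForest implementation. A feature that no tree splits on has raw
importance exactly zero, since permuting it cannot change any prediction.

The permutation used for (tree t, feature j) is drawn from
``numpy.random.default_rng([perm_seed, t, j])`` over the tree's OOB
positions in ascending sample order. That derivation is part of the
contract, so an independent re-computation sharing the seed reproduces the
importance exactly.

The module also carries the linear least-squares baseline and the shared
accuracy metric (Pearson correlation between observed and predicted
Δglucose). Model objects follow the endog/exog construction convention with
``fit()`` returning a results object.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "ForestParams",
    "ForestModel",
    "ForestResults",
    "LinearModel",
    "LinearResults",
    "fit_forest",
    "fit_linear",
    "oob_permutation_importance",
    "accuracy",
]


@dataclasses.dataclass(frozen=True)
class ForestParams:
    """Forest hyperparameters (regression conventions of the classical algorithm).

    ``mtry`` is the number of candidate features per split, defaulting to
    ⌈p/3⌉; ``min_node`` bounds the terminal-node size (mapped to the tree
    learner's minimum-samples-per-leaf); ``bootstrap=False`` grows every
    tree on the full sample (no OOB set — useful only for diagnostics).
    """

    n_trees: int = 500
    mtry: int | None = None
    min_node: int = 5
    seed: int = 0
    bootstrap: bool = True

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError(f"n_trees must be >= 1, got {self.n_trees}")
        if self.min_node < 1:
            raise ValueError(f"min_node must be >= 1, got {self.min_node}")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError(f"mtry must be >= 1, got {self.mtry}")

    def resolve_mtry(self, p: int) -> int:
        if self.mtry is not None:
            if self.mtry > p:
                raise ValueError(f"mtry ({self.mtry}) exceeds number of features ({p})")
            return self.mtry
        return max(1, math.ceil(p / 3))


def _as_matrix(X) -> tuple[np.ndarray, list]:
    if isinstance(X, pd.DataFrame):
        return np.ascontiguousarray(X.to_numpy(dtype=np.float32)), list(X.columns)
    arr = np.ascontiguousarray(np.asarray(X, dtype=np.float32))
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, list(range(arr.shape[1]))


class ForestModel:
    """Random-forest regression model over (endog y, exog X).

    ``feature_ids`` default to the DataFrame columns (or integer positions).
    ``fit()`` grows ``params.n_trees`` trees, each on an independent
    bootstrap resample of size n with ``mtry`` candidate features per split,
    and returns :class:`ForestResults`. Fixed seed ⇒ identical forest.
    """

    def __init__(self, endog, exog, feature_ids=None, params: ForestParams | None = None):
        self.X, inferred_ids = _as_matrix(exog)
        self.y = np.asarray(pd.Series(endog) if not isinstance(endog, np.ndarray) else endog, dtype=float).ravel()
        if len(self.y) != self.X.shape[0]:
            raise ValueError("endog and exog have different numbers of samples")
        self.feature_ids = list(feature_ids) if feature_ids is not None else inferred_ids
        if len(self.feature_ids) != self.X.shape[1]:
            raise ValueError("feature_ids length does not match number of columns")
        self.params = params if params is not None else ForestParams()

    def fit(self) -> "ForestResults":
        n, p = self.X.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        params = self.params
        mtry = params.resolve_mtry(p)
        seeds = np.random.SeedSequence(params.seed).generate_state(2 * params.n_trees, dtype=np.uint32)
        trees: list[DecisionTreeRegressor] = []
        inbag = np.zeros((params.n_trees, n), dtype=np.uint16)
        for t in range(params.n_trees):
            if params.bootstrap:
                rng = np.random.default_rng(int(seeds[2 * t]))
                idx = rng.integers(0, n, size=n)
            else:
                idx = np.arange(n)
            np.add.at(inbag[t], idx, 1)
            tree = DecisionTreeRegressor(
                max_features=mtry,
                min_samples_leaf=params.min_node,
                random_state=int(seeds[2 * t + 1] >> 1),
            )
            tree.fit(self.X[idx], self.y[idx])
            trees.append(tree)
        return ForestResults(self, trees, inbag)


class ForestResults:
    """Fitted forest: trees, in-bag multisets, OOB predictions and importance."""

    def __init__(self, model: ForestModel, trees, inbag: np.ndarray):
        self.model = model
        self.trees_ = trees
        self.inbag_ = inbag
        #: per tree, OOB sample indices in ascending order
        self.oob_sets_ = [np.flatnonzero(inbag[t] == 0) for t in range(len(trees))]
        self.feature_ids = model.feature_ids
        self._oob_pred: np.ndarray | None = None

    @property
    def n_trees(self) -> int:
        return len(self.trees_)

    def predict(self, X) -> np.ndarray:
        """Forest prediction: mean of the per-tree predictions."""
        arr, _ = _as_matrix(X)
        if arr.shape[1] != len(self.feature_ids):
            raise ValueError(
                f"expected {len(self.feature_ids)} features, got {arr.shape[1]}"
            )
        out = np.zeros(arr.shape[0])
        for tree in self.trees_:
            out += tree.tree_.predict(arr).ravel()
        return out / self.n_trees

    @property
    def fittedvalues(self) -> np.ndarray:
        """Resubstitution (all-sample) predictions on the training matrix."""
        return self.predict(self.model.X)

    @property
    def oob_prediction_(self) -> np.ndarray:
        """Per-sample mean prediction over trees for which the sample is OOB.

        Samples that are in-bag for every tree get NaN (with a warning);
        with hundreds of trees this does not occur in practice.
        """
        if self._oob_pred is None:
            n = len(self.model.y)
            total = np.zeros(n)
            count = np.zeros(n)
            for t, tree in enumerate(self.trees_):
                oob = self.oob_sets_[t]
                if len(oob) == 0:
                    continue
                total[oob] += tree.tree_.predict(self.model.X[oob]).ravel()
                count[oob] += 1
            never = count == 0
            if never.any():
                warnings.warn(
                    f"{int(never.sum())} sample(s) are in-bag for every tree; "
                    "their OOB prediction is NaN",
                    stacklevel=2,
                )
            with np.errstate(invalid="ignore"):
                self._oob_pred = np.where(never, np.nan, total / np.maximum(count, 1))
                self._oob_pred[never] = np.nan
        return self._oob_pred

    @property
    def resubstitution_accuracy(self) -> float:
        return accuracy(self.model.y, self.fittedvalues)

    @property
    def oob_accuracy(self) -> float:
        pred = self.oob_prediction_
        ok = ~np.isnan(pred)
        return accuracy(self.model.y[ok], pred[ok])

    def importance(self, perm_seed: int = 0) -> pd.DataFrame:
        """OOB permutation importance; see :func:`oob_permutation_importance`."""
        return oob_permutation_importance(self, perm_seed=perm_seed)

    def summary(self, perm_seed: int | None = None, top: int = 10) -> str:
        """Plain-text fit summary; with ``perm_seed`` includes top importances."""
        n, p = self.model.X.shape
        params = self.model.params
        lines = [
            "Random forest regression (OOB-tracked)",
            "=" * 42,
            f"n samples            {n:>10d}",
            f"n features           {p:>10d}",
            f"n trees              {self.n_trees:>10d}",
            f"mtry                 {params.resolve_mtry(p):>10d}",
            f"min node size        {params.min_node:>10d}",
            f"resubstitution acc   {self.resubstitution_accuracy:>10.3f}",
            f"OOB acc              {self.oob_accuracy:>10.3f}",
        ]
        if perm_seed is not None:
            imp = self.importance(perm_seed=perm_seed)
            lines.append("-" * 42)
            lines.append("top OOB permutation importances (normalised)")
            for fid, row in imp.head(top).iterrows():
                lines.append(f"  {str(fid):<20s} {row['importance']:>8.2f}")
        return "\n".join(lines)


def fit_forest(X, y, params: ForestParams | None = None, feature_ids=None) -> ForestResults:
    """Convenience wrapper: construct and fit a :class:`ForestModel`."""
    n = len(np.asarray(y).ravel())
    if n < 5:
        raise ValueError(f"need at least 5 samples to grow a forest, got {n}")
    return ForestModel(y, X, feature_ids=feature_ids, params=params).fit()


def oob_permutation_importance(
    results: ForestResults,
    X=None,
    y=None,
    perm_seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance from the OOB error increase, per tree.

    For every tree the OOB mean squared error is computed with the true
    predictor column and with that column permuted within the OOB subset;
    the per-tree differences d_tj are averaged over all trees (trees that do
    not use feature j contribute exactly 0) and normalised by their standard
    error over trees. Returns a DataFrame indexed by feature id, sorted by
    normalised importance descending (ties by feature id), with columns
    ``raw_importance``, ``importance``, ``rank`` (1..p) and ``zero_sd``
    (features whose per-tree differences have no spread are flagged and
    their normalised value falls back to the raw mean).

    ``X`` and ``y``, if given, must equal the training data (a consistency
    guard); the importance is defined on the training OOB sets.
    """
    model = results.model
    if X is not None:
        arr, ids = _as_matrix(X)
        if ids != list(results.feature_ids) and ids != list(range(len(results.feature_ids))):
            missing = [f for f in results.feature_ids if f not in ids]
            raise ValueError(f"feature(s) {missing or ids} do not match the fitted model")
        if arr.shape != model.X.shape or not np.array_equal(arr, model.X):
            raise ValueError("X does not match the matrix the forest was trained on")
    if y is not None:
        yv = np.asarray(pd.Series(y), dtype=float).ravel()
        if not np.array_equal(yv, model.y):
            raise ValueError("y does not match the response the forest was trained on")

    n_trees = results.n_trees
    p = model.X.shape[1]
    d = np.zeros((n_trees, p))
    any_oob = np.zeros(model.X.shape[0], dtype=bool)
    for t, tree in enumerate(results.trees_):
        oob = results.oob_sets_[t]
        if len(oob) == 0:
            continue
        any_oob[oob] = True
        Xo = np.ascontiguousarray(model.X[oob])
        yo = model.y[oob]
        mse0 = float(np.mean((yo - tree.tree_.predict(Xo).ravel()) ** 2))
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        Xp = Xo.copy()
        for j in used:
            rng = np.random.default_rng([perm_seed, t, int(j)])
            perm = rng.permutation(len(oob))
            saved = Xp[:, j].copy()
            Xp[:, j] = Xo[perm, j]
            mse_perm = float(np.mean((yo - tree.tree_.predict(Xp).ravel()) ** 2))
            Xp[:, j] = saved
            d[t, j] = mse_perm - mse0
    if not any_oob.all():
        warnings.warn(
            "some samples are never out-of-bag; importance estimates may be noisy",
            stacklevel=2,
        )

    raw = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1) if n_trees > 1 else np.zeros(p)
    se = sd / math.sqrt(n_trees)
    zero_sd = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        imp = np.where(zero_sd, raw, raw / np.where(zero_sd, 1.0, se))
    table = pd.DataFrame(
        {
            "raw_importance": raw,
            "importance": imp,
            "zero_sd": zero_sd,
        },
        index=pd.Index(results.feature_ids, name="feature_id"),
    )
    order = sorted(table.index, key=lambda f: (-table.at[f, "importance"], str(f)))
    table = table.loc[order]
    table["rank"] = np.arange(1, p + 1)
    return table


class LinearModel:
    """Ordinary least-squares baseline over (endog y, exog X) with intercept."""

    def __init__(self, endog, exog, feature_ids=None):
        X = exog.to_numpy(dtype=float) if isinstance(exog, pd.DataFrame) else np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        self.X = X
        self.y = np.asarray(pd.Series(endog) if not isinstance(endog, np.ndarray) else endog, dtype=float).ravel()
        if len(self.y) != X.shape[0]:
            raise ValueError("endog and exog have different numbers of samples")
        if feature_ids is not None:
            self.feature_ids = list(feature_ids)
        elif isinstance(exog, pd.DataFrame):
            self.feature_ids = list(exog.columns)
        else:
            self.feature_ids = list(range(X.shape[1]))

    def fit(self) -> "LinearResults":
        n, p = self.X.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples for least squares, got {n}")
        design = np.column_stack([np.ones(n), self.X])
        coef, _, rank, _ = np.linalg.lstsq(design, self.y, rcond=None)
        if rank < min(design.shape):
            warnings.warn(
                f"rank-deficient design (rank {rank} < {min(design.shape)}); "
                "minimum-norm solution returned",
                stacklevel=2,
            )
        return LinearResults(self, coef, rank)


class LinearResults:
    """Least-squares fit: intercept + coefficients, minimum-norm under rank deficiency."""

    def __init__(self, model: LinearModel, coef: np.ndarray, rank: int):
        self.model = model
        self.intercept = float(coef[0])
        self.params = pd.Series(coef[1:], index=model.feature_ids, name="coef")
        self.rank = int(rank)

    def predict(self, X) -> np.ndarray:
        arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        return self.intercept + arr @ self.params.to_numpy()

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.X)

    @property
    def resubstitution_accuracy(self) -> float:
        return accuracy(self.model.y, self.fittedvalues)

    def summary(self) -> str:
        lines = [
            "Linear least-squares baseline",
            "=" * 42,
            f"n samples   {len(self.model.y):>10d}",
            f"n features  {self.model.X.shape[1]:>10d}",
            f"rank        {self.rank:>10d}",
            f"intercept   {self.intercept:>10.4f}",
            f"resub acc   {self.resubstitution_accuracy:>10.3f}",
        ]
        return "\n".join(lines)


def fit_linear(X, y, feature_ids=None) -> LinearResults:
    """Convenience wrapper: construct and fit a :class:`LinearModel`."""
    return LinearModel(y, X, feature_ids=feature_ids).fit()


def accuracy(y_true, y_pred) -> float:
    """Pearson product-moment correlation between observed and predicted response.

    Affine-invariant in either argument (positive slope). Fewer than three
    pairs is an error; a constant vector makes the correlation undefined and
    is reported as 0.0 with a warning (the degenerate-fold sentinel).
    """
    yt = np.asarray(y_true, dtype=float).ravel()
    yp = np.asarray(y_pred, dtype=float).ravel()
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred have different lengths")
    if yt.size < 3:
        raise ValueError(f"need at least 3 pairs for the accuracy metric, got {yt.size}")
    if np.std(yt) == 0 or np.std(yp) == 0:
        warnings.warn("constant vector in accuracy(); returning sentinel 0.0", stacklevel=2)
        return 0.0
    return float(np.corrcoef(yt, yp)[0, 1])
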
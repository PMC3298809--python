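"""Iterative importance-halving feature selection.

Starting from all p features, a forest is fitted, OOB permutation
importances are computed, and the half of the features with the smallest
importance is discarded; sizes follow the ceiling schedule
p, ⌈p/2⌉, ⌈p/4⌉, …, 1 (the ceiling convention makes 286 pass through
143 → 72 → 36 → 18 → 9, so a nine-feature panel sits exactly at the fifth
bisection). The selection trace records, for every size, the retained set
and the median cross-validated accuracy of a forest restricted to that
size; the stable minimum is the smallest size whose median accuracy stays
within a tolerance δ of the best size's.

Two evaluation modes exist. The default, ``nested``, re-runs the entire
halving path inside every training fold, so held-out folds never influence
which features are kept (leakage-safe). ``full_data`` re-uses the halving
path computed once on all samples and only refits the forest per fold; it
exists to demonstrate the selection bias this shortcut induces and is
clearly labelled in outputs.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterator

import numpy as np
import pandas as pd

from .forest import ForestParams, ForestResults, fit_forest, oob_permutation_importance

__all__ = [
    "StabilityRule",
    "SelectionTrace",
    "halving_schedule",
    "halve",
    "halving_path",
    "run_selection_trace",
    "select_stable_minimum",
    "plot_selection_trace",
]


@dataclasses.dataclass(frozen=True)
class StabilityRule:
    """Plateau tolerance: a size is 'stable' if its median CV accuracy is
    within ``delta`` accuracy units of the best median over the trace."""

    delta: float = 0.02

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")


def halving_schedule(p: int) -> list[int]:
    """Sizes [p, ⌈p/2⌉, ⌈p/4⌉, …, 1] (strictly decreasing)."""
    if p < 1:
        raise ValueError(f"p must be >= 1, got {p}")
    sizes = [int(p)]
    while sizes[-1] > 1:
        sizes.append(math.ceil(sizes[-1] / 2))
    return sizes


def halve(feature_ids, importance: pd.DataFrame | pd.Series) -> list:
    """Retain the ⌈k/2⌉ features with the largest importance.

    Ties are broken by feature id ascending, making the halving
    deterministic. ``importance`` must cover exactly the given features.
    """
    ids = list(feature_ids)
    imp = importance["importance"] if isinstance(importance, pd.DataFrame) else importance
    if set(imp.index) != set(ids):
        raise ValueError("importance does not cover exactly the given feature set")
    keep = math.ceil(len(ids) / 2)
    order = sorted(ids, key=lambda f: (-float(imp.loc[f]), str(f)))
    return order[:keep]


def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence([int(x) & 0x7FFFFFFF for x in parts]).generate_state(1)[0] >> 1)


def halving_path(
    X: pd.DataFrame,
    y,
    params: ForestParams,
    perm_seed: int = 0,
    stop_size: int = 1,
) -> Iterator[tuple[int, list, ForestResults]]:
    """Yield (size, retained feature ids, fitted forest) along the halving path.

    The first element is the full feature set; each subsequent set keeps the
    better-important half of the previous one. Forest and permutation seeds
    are derived per size from ``params.seed``/``perm_seed`` so the path is
    deterministic.
    """
    ids = list(X.columns)
    yv = np.asarray(pd.Series(y), dtype=float).ravel()
    for size in halving_schedule(len(ids)):
        Xs = X[ids]
        fit = fit_forest(
            Xs, yv, dataclasses.replace(params, seed=_derive_seed(params.seed, size))
        )
        yield size, ids, fit
        if size <= stop_size or size == 1:
            return
        imp = oob_permutation_importance(fit, perm_seed=_derive_seed(perm_seed, size))
        ids = halve(ids, imp)


@dataclasses.dataclass
class SelectionTrace:
    """Halving trace: per size the retained set and CV accuracy profile.

    ``retained`` maps size → feature ids from the all-sample halving path
    (nested: each set is a subset of every larger one). ``accuracies`` has
    one row per CV repetition and one column per size; ``median_accuracy``
    is its per-size median. ``mode`` records whether the per-size accuracy
    re-ran the halving inside each training fold (``nested``) or reused the
    all-sample sets (``full_data``, leakage-prone).
    """

    sizes: list[int]
    retained: dict[int, list]
    accuracies: pd.DataFrame
    mode: str

    @property
    def median_accuracy(self) -> pd.Series:
        return self.accuracies.median(axis=0)

    def __len__(self) -> int:
        return len(self.sizes)


def run_selection_trace(
    X: pd.DataFrame,
    y,
    params: ForestParams | None = None,
    cv=None,
    mode: str = "nested",
    perm_seed: int = 0,
) -> SelectionTrace:
    """Halving path with cross-validated accuracy at every size.

    In ``nested`` mode each training fold runs its own halving path from p
    down to 1 and the fold's forests predict the held-out fold at every
    size; out-of-fold predictions are pooled per repetition and size, and
    the Pearson accuracy per (repetition, size) is recorded. In
    ``full_data`` mode the retained sets come from the single all-sample
    path and folds only refit.
    """
    from .evaluation import CVSpec, make_folds  # deferred: evaluation imports selection

    if params is None:
        params = ForestParams(n_trees=200)
    if cv is None:
        cv = CVSpec()
    if mode not in ("nested", "full_data"):
        raise ValueError(f"unknown mode {mode!r}")
    yv = np.asarray(pd.Series(y), dtype=float).ravel()
    n = len(yv)
    sizes = halving_schedule(X.shape[1])

    retained: dict[int, list] = {
        size: ids for size, ids, _ in halving_path(X, yv, params, perm_seed=perm_seed)
    }

    acc = np.full((cv.repeats, len(sizes)), np.nan)
    for rep in range(cv.repeats):
        folds = make_folds(n, cv.folds, np.random.default_rng([cv.seed, rep]))
        preds = {size: np.full(n, np.nan) for size in sizes}
        for k, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            fold_params = dataclasses.replace(params, seed=_derive_seed(params.seed, rep, k))
            if mode == "nested":
                path = halving_path(
                    X.iloc[train_idx], yv[train_idx], fold_params,
                    perm_seed=_derive_seed(perm_seed, rep, k),
                )
                for size, ids, fit in path:
                    preds[size][test_idx] = fit.predict(X.iloc[test_idx][ids])
            else:
                for size in sizes:
                    ids = retained[size]
                    fit = fit_forest(
                        X.iloc[train_idx][ids], yv[train_idx],
                        dataclasses.replace(fold_params, seed=_derive_seed(fold_params.seed, size)),
                    )
                    preds[size][test_idx] = fit.predict(X.iloc[test_idx][ids])
        for s_i, size in enumerate(sizes):
            acc[rep, s_i] = cv.pool_accuracy(yv, preds[size], folds)

    accuracies = pd.DataFrame(acc, columns=pd.Index(sizes, name="size"))
    accuracies.index.name = "repeat"
    return SelectionTrace(sizes=sizes, retained=retained, accuracies=accuracies, mode=mode)


def select_stable_minimum(
    trace: SelectionTrace, rule: StabilityRule | None = None
) -> tuple[int, list]:
    """Smallest size whose median CV accuracy is within δ of the trace's best.

    Returns (size, retained feature ids at that size).
    """
    if rule is None:
        rule = StabilityRule()
    if not trace.sizes:
        raise ValueError("empty selection trace")
    med = trace.median_accuracy
    cutoff = float(med.max()) - rule.delta
    stable = [size for size in trace.sizes if med.loc[size] >= cutoff]
    size = min(stable)
    return size, trace.retained[size]


def plot_selection_trace(trace: SelectionTrace, path=None, ax=None):
    """Median CV accuracy against panel size (log2 x-axis, descending)."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 4))
    else:
        fig = ax.figure
    med = trace.median_accuracy
    ax.plot(trace.sizes, med.loc[trace.sizes], marker="o")
    lo = trace.accuracies.quantile(0.25)
    hi = trace.accuracies.quantile(0.75)
    ax.fill_between(trace.sizes, lo.loc[trace.sizes], hi.loc[trace.sizes], alpha=0.2)
    ax.set_xscale("log", base=2)
    ax.invert_xaxis()
    ax.set_xlabel("number of metabolites")
    ax.set_ylabel("median CV accuracy (Pearson r)")
    ax.set_title(f"Importance-halving selection ({trace.mode})")
    if path is not None:
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax
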
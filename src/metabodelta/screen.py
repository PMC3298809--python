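"""Univariate Spearman screening and collinearity diagnostics.

Each metabolite is screened against Δglucose with Spearman's rank
correlation (mid-ranks for ties) at a fixed significance level, without
multiple-testing correction — the screen is a reproduction of a simple
α = 0.05 filter, not a discovery procedure (a Benjamini–Hochberg flag is
available). The per-feature % variance explained is 100·rho². Collinearity
among the selected metabolites is diagnosed with the condition number of
their Spearman correlation matrix; metabolites sharing pathways correlate
strongly, and a condition number far above 1000 signals that a linear model
on these predictors is numerically unstable, motivating tree ensembles.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import FeatureMatrix

__all__ = [
    "ScreenResult",
    "spearman_screen",
    "select_significant",
    "correlation_matrix",
    "condition_number",
    "plot_correlation_heatmap",
]

_EXACT_MAX_N = 10


@dataclasses.dataclass
class ScreenResult:
    """Per-feature Spearman screen against Δglucose.

    ``table`` has one row per feature (sorted by |rho| descending, ties by
    feature id), with columns rho, p_value, var_explained_pct (= 100·rho²),
    significant (p < alpha) and degenerate (constant column; reported as
    rho = 0, p = 1, never significant).
    """

    table: pd.DataFrame
    alpha: float
    method: str

    def __len__(self) -> int:
        return len(self.table)


def _spearman_vector(values: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Spearman rho of each column of ``values`` against ``y``.

    Returns (rho, degenerate). rho is the Pearson correlation of mid-ranks;
    degenerate marks constant columns (or all columns, if y is constant),
    for which rho is set to 0.
    """
    R = pd.DataFrame(values).rank().to_numpy()
    ry = pd.Series(y).rank().to_numpy()
    Rc = R - R.mean(axis=0)
    ryc = ry - ry.mean()
    ss_x = (Rc**2).sum(axis=0)
    ss_y = float((ryc**2).sum())
    degenerate = (ss_x <= 0) | (ss_y <= 0)
    den = np.sqrt(np.where(degenerate, 1.0, ss_x * ss_y))
    rho = np.where(degenerate, 0.0, Rc.T @ ryc / den)
    return np.clip(rho, -1.0, 1.0), degenerate


def _t_approx_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from t = rho·sqrt((n−2)/(1−rho²)) on n−2 df; |rho|=1 → 0."""
    rho = np.asarray(rho, dtype=float)
    p = np.zeros_like(rho)
    interior = np.abs(rho) < 1.0 - 1e-12
    t = rho[interior] * np.sqrt((n - 2) / (1.0 - rho[interior] ** 2))
    p[interior] = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return p


def _exact_p(values: np.ndarray, y: np.ndarray, rho_obs: np.ndarray) -> np.ndarray:
    """Exact permutation p-values: P(|rho_perm| >= |rho_obs|) over all n! permutations."""
    n = len(y)
    if n > _EXACT_MAX_N:
        raise ValueError(f"exact permutation p-values limited to n <= {_EXACT_MAX_N}, got n={n}")
    R = pd.DataFrame(values).rank().to_numpy()
    ry = pd.Series(y).rank().to_numpy()
    Rc = R - R.mean(axis=0)
    ss_x = (Rc**2).sum(axis=0)
    ryc = ry - ry.mean()
    ss_y = float((ryc**2).sum())
    den = np.sqrt(np.where(ss_x > 0, ss_x * ss_y, 1.0))
    count = np.zeros(values.shape[1], dtype=np.int64)
    total = 0
    batch: list[np.ndarray] = []
    thresh = np.abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        batch.append(ryc[list(perm)])
        if len(batch) == 20000:
            rho_b = np.abs(Rc.T @ np.asarray(batch).T) / den[:, None]
            count += (rho_b >= thresh[:, None]).sum(axis=1)
            total += len(batch)
            batch = []
    if batch:
        rho_b = np.abs(Rc.T @ np.asarray(batch).T) / den[:, None]
        count += (rho_b >= thresh[:, None]).sum(axis=1)
        total += len(batch)
    return count / total


def spearman_screen(
    matrix: FeatureMatrix,
    y: pd.Series | np.ndarray,
    alpha: float = 0.05,
    method: str = "t",
    bh_correct: bool = False,
) -> ScreenResult:
    """Screen every feature against the response by Spearman rank correlation.

    ``method="t"`` uses the tie-corrected t-approximation (the standard
    choice at this sample size); ``method="exact"`` enumerates all
    permutations and is limited to n ≤ 10. With ``bh_correct`` the
    significance flag is applied to Benjamini–Hochberg adjusted p-values
    (off by default: the reproduced filter is a plain α threshold).
    """
    values = matrix.values.to_numpy(dtype=float)
    yv = np.asarray(pd.Series(y).reindex(matrix.values.index) if isinstance(y, pd.Series) else y, dtype=float)
    n = values.shape[0]
    if n < 4:
        raise ValueError(f"need at least 4 samples for the screen, got {n}")
    if len(yv) != n:
        raise ValueError("response is not aligned with the feature matrix")
    if np.isnan(values).any():
        raise ValueError("screen requires a matrix without missing entries; impute first")

    rho, degenerate = _spearman_vector(values, yv)
    if method == "t":
        p = _t_approx_p(rho, n)
    elif method == "exact":
        p = _exact_p(values, yv, rho)
    else:
        raise ValueError(f"unknown p-value method {method!r}")
    p = np.where(degenerate, 1.0, p)

    p_for_flag = p
    if bh_correct:
        p_for_flag = _benjamini_hochberg(p)
    table = pd.DataFrame(
        {
            "rho": rho,
            "p_value": p,
            "var_explained_pct": 100.0 * rho**2,
            "significant": (p_for_flag < alpha) & ~degenerate,
            "degenerate": degenerate,
        },
        index=matrix.values.columns.rename("feature_id"),
    )
    if matrix.feature_names is not None:
        table.insert(0, "name", matrix.feature_names)
    order = sorted(table.index, key=lambda f: (-abs(table.at[f, "rho"]), str(f)))
    return ScreenResult(table=table.loc[order], alpha=alpha, method=method)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        k = m - rank_from_end
        running = min(running, p[idx] * m / k)
        adj[idx] = running
    return adj


def select_significant(screen: ScreenResult) -> list:
    """Feature ids with p < α, ordered by |rho| descending (ties by id)."""
    t = screen.table
    return list(t.index[t["significant"]])


def correlation_matrix(
    matrix: FeatureMatrix,
    y: pd.Series | np.ndarray,
    subset: list,
    response_label: str = "delta_glucose",
) -> pd.DataFrame:
    """Pairwise Spearman correlation over {Δglucose} ∪ subset.

    Symmetric with unit diagonal. Degenerate (constant) columns get zero
    correlation with everything and are listed in ``attrs['degenerate']``.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    sub = matrix.subset(subset)
    yv = np.asarray(pd.Series(y).reindex(matrix.values.index) if isinstance(y, pd.Series) else y, dtype=float)
    data = np.column_stack([yv, sub.values.to_numpy(dtype=float)])
    labels = [response_label] + subset
    R = pd.DataFrame(data).rank().to_numpy()
    sd = R.std(axis=0)
    degenerate = [labels[i] for i in np.flatnonzero(sd == 0)]
    Rc = R - R.mean(axis=0)
    denom = np.where(sd > 0, np.sqrt((Rc**2).sum(axis=0)), 1.0)
    Rn = Rc / denom
    corr = Rn.T @ Rn
    corr[sd == 0, :] = 0.0
    corr[:, sd == 0] = 0.0
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    out = pd.DataFrame(np.clip(corr, -1.0, 1.0), index=labels, columns=labels)
    out.attrs["degenerate"] = degenerate
    return out


def condition_number(corr: pd.DataFrame | np.ndarray) -> float:
    """κ = σ_max / σ_min of the correlation matrix; ∞ for a singular matrix.

    κ ≥ 1 always; values far above 1000 indicate severe multicollinearity.
    """
    arr = np.asarray(corr, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"correlation matrix must be square, got shape {arr.shape}")
    if not np.allclose(arr, arr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    s = np.linalg.svd(arr, compute_uv=False)
    if s[-1] <= s[0] * 1e-12:
        return math.inf
    return float(s[0] / s[-1])


def plot_correlation_heatmap(corr: pd.DataFrame, path=None, ax=None):
    """Heatmap of a correlation matrix: blue positive, red negative."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(max(4, 0.22 * len(corr)), max(4, 0.22 * len(corr))))
    else:
        fig = ax.figure
    im = ax.imshow(corr.to_numpy(), cmap="RdBu", vmin=-1, vmax=1)
    ax.set_xticks(range(len(corr)), corr.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(corr)), corr.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    ax.set_title("Spearman correlation")
    if path is not None:
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax
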
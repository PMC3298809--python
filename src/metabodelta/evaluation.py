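"""Leakage-safe repeated k-fold cross-validation and model comparison.

The evaluation protocol mirrors the study design: tenfold cross-validation
in which *every* data-dependent modelling step — the Spearman significance
filter, the importance-halving selection and the model fit itself — is
re-run on the training folds only, repeated (100 times at the faithful
scale) with fresh random fold assignments, reporting the median accuracy
over repetitions. Accuracy per repetition is by default the Pearson
correlation between the observed response and the pooled out-of-fold
predictions (per-fold correlations on ~17 samples are too unstable to
average; a per-fold-mean option exists).

Five pipelines are compared under a shared fold structure, mirroring the
study's model-comparison table:

* Spearman filter → linear model
* Spearman filter → random forest
* importance halving → random forest
* importance halving + established risk markers → random forest
* established risk markers only → random forest

where the established risk markers are gender (encoded 0/1), waist
circumference, BMI, age and baseline fasting glucose.
"""

from __future__ import annotations

import dataclasses
import json
import platform
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .forest import ForestParams, accuracy, fit_forest, fit_linear
from .preprocess import ClinicalTable, FeatureMatrix, compute_delta_glucose, impute_lod, log_normalize
from .screen import (
    condition_number,
    correlation_matrix,
    plot_correlation_heatmap,
    select_significant,
    spearman_screen,
)
from .selection import (
    StabilityRule,
    _derive_seed,
    halving_path,
    plot_selection_trace,
    run_selection_trace,
    select_stable_minimum,
)

__all__ = [
    "CVSpec",
    "EvaluationResult",
    "PIPELINES",
    "encode_clinical",
    "make_folds",
    "cross_validate",
    "compare_models",
    "run_full_analysis",
]

#: The five comparison pipelines, in table order.
PIPELINES = (
    "spearman_linear",
    "spearman_forest",
    "halving_forest",
    "halving_clinical_forest",
    "clinical_forest",
)

_PIPELINE_LABELS = {
    "spearman_linear": ("Spearman correlation", "linear model"),
    "spearman_forest": ("Spearman correlation", "random forest"),
    "halving_forest": ("RF importance", "random forest"),
    "halving_clinical_forest": ("RF importance + established markers", "random forest"),
    "clinical_forest": ("established markers", "random forest"),
}


@dataclasses.dataclass(frozen=True)
class CVSpec:
    """Cross-validation protocol: folds, repetitions, seed and pooling rule."""

    folds: int = 10
    repeats: int = 5
    seed: int = 0
    pooling: str = "pooled"  # or "per_fold_mean"

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError(f"folds must be >= 2, got {self.folds}")
        if self.repeats < 1:
            raise ValueError(f"repeats must be >= 1, got {self.repeats}")
        if self.pooling not in ("pooled", "per_fold_mean"):
            raise ValueError(f"unknown pooling {self.pooling!r}")

    def pool_accuracy(self, y: np.ndarray, preds: np.ndarray, folds) -> float:
        """Accuracy of one repetition from its out-of-fold predictions."""
        if self.pooling == "pooled":
            return accuracy(y, preds)
        per_fold = []
        for test_idx in folds:
            if len(test_idx) < 3:
                continue
            per_fold.append(accuracy(y[test_idx], preds[test_idx]))
        return float(np.mean(per_fold)) if per_fold else 0.0


def make_folds(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Uniform random partition of range(n) into near-equal folds (no stratification)."""
    if folds > n:
        raise ValueError(f"folds ({folds}) exceeds number of samples ({n})")
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, folds)]


def encode_clinical(clinical: ClinicalTable) -> pd.DataFrame:
    """Established risk markers as numeric predictors (gender female=1)."""
    d = clinical.data
    return pd.DataFrame(
        {
            "gender": (d["gender"].astype(str) == "female").astype(float),
            "waist_cm": d["waist_cm"].astype(float),
            "bmi": d["bmi"].astype(float),
            "age_years": d["age_years"].astype(float),
            "glucose_baseline": d["glucose_baseline"].astype(float),
        },
        index=d.index,
    )


@dataclasses.dataclass
class EvaluationResult:
    """One pipeline's evaluation: resubstitution, OOB and repeated-CV accuracy.

    ``cv_accuracies`` holds one accuracy per repetition;
    ``median_cv_accuracy`` is their median. ``selected_features`` maps
    (repeat, fold) to the feature ids chosen inside that training fold when
    the pipeline performs selection.
    """

    pipeline: str
    all_sample_accuracy: float
    oob_accuracy: float | None
    cv_accuracies: list[float]
    selected_features: dict
    all_sample_selection: list

    @property
    def median_cv_accuracy(self) -> float:
        return float(np.median(self.cv_accuracies))


def _fit_pipeline(
    spec: str,
    X: pd.DataFrame,
    clin: pd.DataFrame | None,
    y: np.ndarray,
    train_idx: np.ndarray,
    params: ForestParams,
    alpha: float,
    n_select: int,
    perm_seed: int,
    preselected: list | None = None,
):
    """Fit one pipeline on the training rows only.

    Returns (predict(test_rows) callable over global row indices, selected
    metabolite ids). ``preselected`` short-circuits the selection step — the
    deliberately leaky mode where selection saw all samples.
    """
    Xtr = X.iloc[train_idx]
    ytr = y[train_idx]

    def with_clinical(frame: pd.DataFrame, rows: np.ndarray) -> pd.DataFrame:
        return pd.concat([frame, clin.iloc[rows]], axis=1)

    if spec in ("spearman_linear", "spearman_forest"):
        if preselected is not None:
            sel = list(preselected)
        else:
            fm = FeatureMatrix(Xtr, stage="log_normalized")
            sel = select_significant(spearman_screen(fm, ytr, alpha=alpha))
        if not sel:
            mean = float(np.mean(ytr))
            return (lambda rows: np.full(len(rows), mean)), []
        if spec == "spearman_linear":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # collinear selections may be rank-deficient
                fit = fit_linear(Xtr[sel], ytr)
        else:
            fit = fit_forest(Xtr[sel], ytr, params)
        return (lambda rows: fit.predict(X.iloc[rows][sel])), sel

    if spec in ("halving_forest", "halving_clinical_forest"):
        if preselected is not None:
            sel = list(preselected)
        else:
            sel = None
            for size, ids, _fit in halving_path(Xtr, ytr, params, perm_seed=perm_seed, stop_size=n_select):
                sel = ids
        if spec == "halving_forest":
            fit = fit_forest(Xtr[sel], ytr, params)
            return (lambda rows: fit.predict(X.iloc[rows][sel])), sel
        fit = fit_forest(with_clinical(Xtr[sel], train_idx), ytr, params)
        return (lambda rows: fit.predict(with_clinical(X.iloc[rows][sel], rows))), sel

    if spec == "clinical_forest":
        fit = fit_forest(clin.iloc[train_idx], ytr, params)
        return (lambda rows: fit.predict(clin.iloc[rows])), []

    raise ValueError(f"unknown pipeline spec {spec!r}; expected one of {PIPELINES}")


def cross_validate(
    spec: str,
    X: pd.DataFrame | FeatureMatrix,
    y,
    cv: CVSpec | None = None,
    clinical: ClinicalTable | pd.DataFrame | None = None,
    params: ForestParams | None = None,
    alpha: float = 0.05,
    n_select: int = 9,
    leaky: bool = False,
) -> EvaluationResult:
    """Repeated k-fold evaluation of one pipeline.

    All selection steps run inside each training fold (unless ``leaky=True``,
    which performs the selection once on all samples first — the biased
    shortcut kept for demonstration). Also fits the pipeline once on all
    samples for the resubstitution ("all samples") accuracy, with the
    forest's OOB accuracy alongside where applicable.
    """
    if isinstance(X, FeatureMatrix):
        X = X.values
    if cv is None:
        cv = CVSpec()
    if params is None:
        params = ForestParams(n_trees=200)
    yv = np.asarray(pd.Series(y), dtype=float).ravel()
    n = len(yv)
    clin = None
    if clinical is not None:
        clin = clinical if isinstance(clinical, pd.DataFrame) else encode_clinical(clinical)
    if spec in ("halving_clinical_forest", "clinical_forest") and clin is None:
        raise ValueError(f"pipeline {spec!r} requires a clinical table")

    # all-sample fit (resubstitution + OOB where the final model is a forest)
    all_idx = np.arange(n)
    all_params = dataclasses.replace(params, seed=_derive_seed(params.seed, 10_000))
    predict_all, sel_all = _fit_pipeline(
        spec, X, clin, yv, all_idx, all_params, alpha, n_select, perm_seed=_derive_seed(cv.seed, 10_000)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        all_acc = accuracy(yv, predict_all(all_idx))
    oob_acc = None
    if spec != "spearman_linear":
        final_cols = sel_all if spec not in ("clinical_forest",) else []
        frame = X[final_cols] if final_cols else pd.DataFrame(index=X.index)
        if spec in ("halving_clinical_forest", "clinical_forest"):
            frame = pd.concat([frame, clin], axis=1)
        if frame.shape[1] > 0:
            oob_acc = fit_forest(frame, yv, all_params).oob_accuracy

    preselected = sel_all if (leaky and spec != "clinical_forest") else None

    cv_accs: list[float] = []
    selected: dict = {}
    for rep in range(cv.repeats):
        folds = make_folds(n, cv.folds, np.random.default_rng([cv.seed, rep]))
        preds = np.full(n, np.nan)
        for k, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(all_idx, test_idx)
            if np.std(yv[train_idx]) == 0:
                warnings.warn(f"constant response in training fold {k}; sentinel predictions")
                preds[test_idx] = float(np.mean(yv[train_idx]))
                continue
            fold_params = dataclasses.replace(params, seed=_derive_seed(params.seed, rep, k))
            predict, sel = _fit_pipeline(
                spec, X, clin, yv, train_idx, fold_params, alpha, n_select,
                perm_seed=_derive_seed(cv.seed, rep, k), preselected=preselected,
            )
            preds[test_idx] = predict(test_idx)
            if sel:
                selected[(rep, k)] = sel
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv_accs.append(cv.pool_accuracy(yv, preds, folds))

    return EvaluationResult(
        pipeline=spec,
        all_sample_accuracy=all_acc,
        oob_accuracy=oob_acc,
        cv_accuracies=cv_accs,
        selected_features=selected,
        all_sample_selection=sel_all,
    )


@dataclasses.dataclass
class ModelComparison:
    """Five-pipeline comparison sharing one fold structure per repetition."""

    table: pd.DataFrame
    results: dict[str, EvaluationResult]


def compare_models(
    X: pd.DataFrame | FeatureMatrix,
    clinical: ClinicalTable,
    y,
    cv: CVSpec | None = None,
    params: ForestParams | None = None,
    alpha: float = 0.05,
    n_select: int = 9,
) -> ModelComparison:
    """Evaluate the five comparison pipelines under a common CV protocol.

    All rows use the same ``cv.seed``, hence identical fold assignments per
    repetition, so per-repetition accuracies are paired across pipelines.
    """
    results = {}
    rows = []
    for spec in PIPELINES:
        res = cross_validate(
            spec, X, y, cv=cv, clinical=clinical, params=params, alpha=alpha, n_select=n_select
        )
        results[spec] = res
        sel_label, model_label = _PIPELINE_LABELS[spec]
        rows.append(
            {
                "selection": sel_label,
                "model": model_label,
                "accuracy_all_samples": res.all_sample_accuracy,
                "accuracy_oob": res.oob_accuracy,
                "accuracy_cv_median": res.median_cv_accuracy,
            }
        )
    table = pd.DataFrame(rows, index=pd.Index(PIPELINES, name="pipeline"))
    return ModelComparison(table=table, results=results)


# ---------------------------------------------------------------------------
# Full-analysis driver


_DESK_PROFILE = {"n_trees": 200, "repeats": 5}
_FAITHFUL_PROFILE = {"n_trees": 500, "repeats": 100}


def run_full_analysis(
    config: dict | None = None,
    outdir: str | Path = "metabodelta_run",
    seed: int = 0,
    faithful: bool = False,
) -> dict:
    """End-to-end pipeline: generate/load → preprocess → screen → select → compare.

    ``config`` may contain a ``"generator"`` section (forwarded to
    :class:`~metabodelta.synthetic.GeneratorConfig`) or ``"features"`` /
    ``"clinical"`` paths to delimited-text inputs, plus optional ``"cv"``,
    ``"forest"``, ``"alpha"``, ``"n_select"``, ``"stability_delta"`` and
    ``"normalize_mode"`` settings. Writes the screen table, correlation
    heatmap, selection trace (table and figure), model-comparison table and
    a run-metadata JSON into ``outdir`` and returns the in-memory results.
    """
    from .synthetic import GeneratorConfig, generate_cohort, read_cohort, summarize_response

    t_start = time.time()
    config = dict(config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    profile = _FAITHFUL_PROFILE if faithful else _DESK_PROFILE
    timings: dict[str, float] = {}

    def _tick(stage: str, t0: float) -> None:
        timings[stage] = round(time.time() - t0, 3)

    # --- inputs
    t0 = time.time()
    if "features" in config:
        cohort = read_cohort(Path(config["features"]).parent)
        truth = cohort.truth
    else:
        gen_kwargs = dict(config.get("generator", {}))
        gen_kwargs.setdefault("seed", seed)
        cohort = generate_cohort(GeneratorConfig(**gen_kwargs))
        truth = cohort.truth
    features, clinical = cohort.features, cohort.clinical
    _tick("inputs", t0)

    # --- preprocessing
    t0 = time.time()
    delta = compute_delta_glucose(clinical)
    imputed = impute_lod(features)
    normalized = log_normalize(imputed, mode=config.get("normalize_mode", "feature_median"))
    response_summary = summarize_response(cohort)
    _tick("preprocess", t0)

    # --- univariate screen and collinearity diagnostics
    t0 = time.time()
    alpha = float(config.get("alpha", 0.05))
    screen = spearman_screen(normalized, delta, alpha=alpha)
    significant = select_significant(screen)
    screen.table.to_csv(outdir / "screen.tsv", sep="\t")
    kappa = None
    if significant:
        corr = correlation_matrix(normalized, delta, significant)
        kappa = condition_number(corr)
        corr.to_csv(outdir / "correlation_matrix.tsv", sep="\t")
        plot_correlation_heatmap(corr, path=outdir / "correlation_heatmap.png")
    _tick("screen", t0)

    forest_kwargs = dict(config.get("forest", {}))
    forest_kwargs.setdefault("n_trees", profile["n_trees"])
    forest_kwargs.setdefault("seed", seed)
    params = ForestParams(**forest_kwargs)
    cv_kwargs = dict(config.get("cv", {}))
    cv_kwargs.setdefault("repeats", profile["repeats"])
    cv_kwargs.setdefault("seed", seed)
    cv = CVSpec(**cv_kwargs)

    # --- importance-halving selection trace
    t0 = time.time()
    trace = run_selection_trace(normalized.values, delta, params=params, cv=cv, perm_seed=seed)
    stable_size, stable_ids = select_stable_minimum(
        trace, StabilityRule(float(config.get("stability_delta", 0.02)))
    )
    trace_table = pd.DataFrame(
        {
            "size": trace.sizes,
            "median_cv_accuracy": trace.median_accuracy.loc[trace.sizes].to_numpy(),
            "retained": [",".join(map(str, trace.retained[s])) for s in trace.sizes],
        }
    )
    trace_table.to_csv(outdir / "selection_trace.tsv", sep="\t", index=False)
    plot_selection_trace(trace, path=outdir / "selection_trace.png")
    final_fit = fit_forest(
        normalized.values[trace.retained[stable_size]], delta.to_numpy(), params
    )
    importance = final_fit.importance(perm_seed=seed)
    importance.to_csv(outdir / "importance.tsv", sep="\t")
    _tick("selection", t0)

    # --- model comparison
    t0 = time.time()
    n_select = int(config.get("n_select", stable_size))
    comparison = compare_models(
        normalized.values, clinical, delta, cv=cv, params=params, alpha=alpha, n_select=n_select
    )
    comparison.table.to_csv(outdir / "model_comparison.tsv", sep="\t")
    _tick("comparison", t0)

    metadata = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "faithful": faithful,
        "config": {k: v for k, v in config.items() if k != "generator"},
        "generator": config.get("generator", {}),
        "profile": profile,
        "alpha": alpha,
        "n_select": n_select,
        "response_summary": response_summary,
        "n_significant": len(significant),
        "condition_number": None if kappa is None else (kappa if np.isfinite(kappa) else "inf"),
        "stable_size": stable_size,
        "stable_features": list(map(str, stable_ids)),
        "signal_features_truth": truth.get("signal_features"),
        "timings_s": timings,
        "total_s": round(time.time() - t_start, 3),
    }
    (outdir / "run_metadata.json").write_text(json.dumps(metadata, indent=2))

    return {
        "cohort": cohort,
        "delta": delta,
        "normalized": normalized,
        "screen": screen,
        "significant": significant,
        "condition_number": kappa,
        "trace": trace,
        "stable_size": stable_size,
        "stable_features": stable_ids,
        "importance": importance,
        "comparison": comparison,
        "metadata": metadata,
    }
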
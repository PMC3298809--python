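# metabodelta

Predicting the development of fasting plasma glucose from GC-MS metabolite
profiles with multivariate statistics.

## The problem

Cohort studies that profile blood plasma by gas chromatography–mass
spectrometry produce a samples × metabolites intensity matrix (hundreds of
features, censored below the detection limit) alongside clinical
measurements. A question such studies ask: do baseline metabolite levels
predict how a subject's fasting glucose will develop over the following
years? The response is the annualised glucose change

    Δglucose = (glucose_followup − glucose_baseline) / elapsed_years

in mg/(dl·a). Univariate screening finds metabolites that correlate with
Δglucose, but single metabolites explain little variance and the metabolite
matrix is heavily collinear (metabolites share pathways), so a linear model
on the screened set is unstable and cross-validates poorly. `metabodelta`
implements the multivariate alternative: random-forest regression with
out-of-bag (OOB) permutation importance, iterative importance-halving
feature selection down to a minimal stable metabolite panel, and honest —
leakage-safe — repeated tenfold cross-validation, together with the
univariate screen and collinearity diagnostics that motivate it. It is
aimed at metabolomics analysts who want this workflow as tested,
reusable components rather than a one-off script.

Because no public accession exists for raw data of this kind of cohort, the
package ships a seeded synthetic cohort generator that reproduces the
statistical structure the analysis assumes (correlated lognormal feature
blocks, below-LOD censoring, a planted partly non-linear nine-metabolite
signal, signal-free clinical covariates); every stage is testable end to
end without any download. See `docs/methods.md` for the model and design
choices.

## Core methods

* **Screen** — Spearman rank correlation of each metabolite with Δglucose,
  t-approximation p-values, α = 0.05 filter (no multiplicity correction, by
  design), % variance explained = 100·ρ²; condition number κ of the
  Spearman correlation matrix as a collinearity diagnostic.
* **Forest engine** — bagged regression trees with explicit bootstrap
  bookkeeping; per-tree OOB permutation importance: mean increase in OOB
  MSE when a feature is permuted within each tree's OOB subset, normalised
  by its standard error over trees.
* **Selection** — iteratively discard the less-important half of the
  features (ceiling schedule 286 → 143 → 72 → 36 → 18 → 9 → … → 1); the
  stable panel is the smallest size whose median CV accuracy is within
  δ = 0.02 of the best.
* **Evaluation** — tenfold CV repeated with fresh fold assignments; every
  data-dependent step (screen, halving, fit) re-run inside each training
  fold; accuracy = Pearson r between observed and pooled out-of-fold
  predicted Δglucose; five-pipeline comparison including an
  established-risk-marker (gender, waist, BMI, age, baseline glucose)
  baseline.

## Worked example

```python
import metabodelta as md

# a seeded synthetic cohort with the study's dimensions
cohort = md.generate_cohort(md.GeneratorConfig(seed=0))
print(md.summarize_response(cohort))
# {'n': 172, 'median': 0.801, 'min': -4.515, 'max': 6.584, 'sd': 2.128,
#  'n_decrease': 59, 'n_increase': 113}
```

The cohort's Δglucose distribution matches the emulation targets: median
≈ 0.8 mg/(dl·a), SD ≈ 2.2, about a third of subjects with decreasing
glucose. Preprocess and screen:

```python
delta = md.compute_delta_glucose(cohort.clinical)
X = md.log_normalize(md.impute_lod(cohort.features))   # 0.7 x min LOD rule, ln, centre
screen = md.spearman_screen(X, delta, alpha=0.05)
sig = md.select_significant(screen)
print(len(sig), screen.table.head(3)[["rho", "p_value", "var_explained_pct"]])
# 32    rho   p_value  var_explained_pct
# M249  0.330  0.000010          10.9
# M153  0.329  0.000011          10.8
# M113  0.276  0.000246           7.6
```

32 metabolites pass the filter; the best single metabolite explains ~11 %
of the response variance — screening finds signal but cannot predict.
Fit a forest with OOB importance and run the halving selection:

```python
fit = md.fit_forest(X.values, delta, md.ForestParams(n_trees=200, seed=0))
print(f"resubstitution r = {fit.resubstitution_accuracy:.2f}, OOB r = {fit.oob_accuracy:.2f}")
# resubstitution r = 0.99, OOB r = 0.52

trace = md.run_selection_trace(X.values, delta,
                               params=md.ForestParams(n_trees=200, seed=0),
                               cv=md.CVSpec(repeats=3, seed=0))
size, panel = md.select_stable_minimum(trace)
print(size, panel)
```

The resubstitution accuracy near 1 is bagging optimism; the OOB accuracy
is the honest single-fit estimate. The selection trace shows the accuracy
plateau as features are halved away and identifies the smallest stable
panel. The five-pipeline comparison (`md.compare_models`) then reports, for
each selection/model combination, the all-sample, OOB and median-CV
accuracies — on default cohorts the forest pipelines reach median CV
accuracy ≈ 0.5 where the linear baseline stays ≈ 0.4 and the
clinical-markers-only forest stays near 0.

The same workflow is available from the shell:

```bash
metabodelta generate --out run/ --seed 1
metabodelta screen   --features run/features.tsv --clinical run/clinical.tsv --out run/
metabodelta all      --out run/ --seed 1            # full pipeline, desk scale
metabodelta all      --out run/ --seed 1 --faithful # 500 trees, 100 CV repeats
```

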
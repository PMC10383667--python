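# Methods

This note documents the statistical model behind `ibdsig`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the package's numerical conventions and known limitations.

## Data model

A study is a genes × samples real matrix with four per-sample covariates:
diagnostic class (control / UC / CD), age in years, sex (female = 0,
male = 1) and one of seven biopsy areas (Rectum, Left colon, Right colon,
Ileum, Transverse, Sigmoid, Cecum — fixed order, integer codes 0–6). On
disk it is a UTF-8 TSV with samples as columns: a `sample_id` header row,
the four covariate rows in fixed order, then one row per gene. Expression
values are written with `repr` so a write/read round trip is bit-identical.
Missing covariates are not representable: the data model has no
missing-value semantics, and the generator always emits complete columns.

Two binary tasks are defined by label schemes: `control_vs_ibd`
(control → 0, UC and CD → 1) and `uc_vs_cd` (UC → 0, CD → 1, controls
excluded). Positive class is always label 1 (IBD, or CD). A scheme that
leaves a single class among kept samples is a hard error — classification
is undefined there, and silently proceeding would poison every downstream
metric.

The train/test split takes `round(fraction × n)` training samples
(half-away-from-zero; fraction defaults to 0.8). It is stratified on the raw
class by default so both halves see all classes even at desk scale — an
unstratified split of a 60-sample test set could easily lose a small class;
a flag restores pure random splitting. Per-class quotas are apportioned by
largest remainder and then nudged so every class with ≥ 2 members lands in
both halves while the total train size stays exact.

## Correlation screen

The screen computes, per gene, the Pearson correlation of the expression
row with the 0/1 label (point-biserial correlation). Genes with zero
variance get 0 by convention: no linear association is measurable, and any
other value would either crash a downstream sort or promote a constant
gene. Ranking uses |r|: down-regulated genes are exactly as informative as
up-regulated ones for a classifier, so discarding negative correlates would
be indefensible; a signed mode exists for fidelity experiments. The kept
subset has size `max(1, floor(q/100 × m))` — at q = 1 and m = 56,632 this
is 566 — with ties broken toward the lower gene index so results are
deterministic. The screen runs on training data only; the resulting gene
set is then applied to both splits.

## Monte Carlo subset search

Each of `p_chains` chains restarts from the full filtered subset (the
repeated process is read as independent restarts — continuing one chain
would exhaust the gene pool after a handful of reductions). One iteration
draws β uniformly from [1, size − 1], removes β members uniformly without
replacement, and cross-validates every registry algorithm on the current
subset. Candidate selection uses **training CV accuracy only**; the ten
best candidates are refitted on the whole training split and reported with
held-out test metrics. This is the only protocol in which the test set
plays no role in gene or model selection while still appearing in the
reported tables.

`min_size` defaults to 5: subsets below that size produce degenerate fits
and uninformative leaderboard entries, while signatures in the 15–20 gene
range remain reachable. Seeds fan out from a master seed through
`numpy.random.SeedSequence.spawn`, so chains are independent streams and
results do not depend on evaluation order; identical (study, config, seed)
reproduce leaderboard CSVs byte for byte.

Desk-scale defaults: a 5-algorithm registry (bagged trees, linear SVM,
coarse KNN, simple tree, subspace KNN — one representative per family) and
p = 20 chains at q = 10 on a 500-gene study. The full 23-algorithm registry
and p = 100 are available by configuration; the desk profile exists because
the full configuration multiplies runtime ~25× without changing any
qualitative behavior the tests assert.

## Classifier registry

The 23 algorithm names are conventional point-and-click presets with no
published hyperparameters, so the registry freezes a documented default
table (in `registry_defaults.yaml`, editable without code changes):
fine/medium/coarse KNN use k = 1/10/100; complex/medium/simple trees use
100/20/4 splits (`max_leaf_nodes = splits + 1`); Gaussian SVMs use kernel
scale s = √m/4, √m, 4√m with γ = 1/s²; cosine/cubic/weighted KNN vary the
metric or weighting at k = 10; all ensembles use 30 learners. "Ten times
cross validation" is read as 10-fold CV (the convention of the tool family
these presets come from); folds are stratified by default, and a
repeated-holdout mode is not needed for any property asserted here. KNN
presets clamp k to the training-fold size so coarse KNN stays defined on
small folds.

Scale-sensitive estimators (SVM, KNN, discriminants, logistic, the MLP) are
wrapped in a standardizing pipeline; tree ensembles consume raw features.
RUS-boosting (boosting with per-round random undersampling of the majority
class) has no scikit-learn implementation, so the package provides a
compact SAMME-style version: each round trains a 20-split tree on all
minority samples plus an equal-size weighted draw of majority samples, with
weights updated on the full training set.

Metrics are derived properties of stored confusion counts, so
accuracy = (TP+TN)/total, sensitivity = TP/(TP+FN) and
specificity = TN/(TN+FP) hold by construction. Ratios with zero denominator
are NaN, never 0 — coercion would silently corrupt leaderboards that sort
on these columns.

Covariates (age, sex, region) are not used as classifier features by
default: with the generator producing them independently of class, any
covariate signal a model finds would be an artifact, which makes the
default a detector for leakage rather than a modeling choice.

## ANN baseline

The baseline is a multilayer perceptron with γ hidden layers of 30 neurons,
trained per γ on the training split and scored on the test split; the sweep
returns the argmax with ties to the smaller γ. The desk grid is
{1, 2, 5, 10, 20, 50}: deep grids (hundreds of layers) add hours of
training without improving a 30-neuron-wide network on desk-scale data, and
per-depth failures are recorded and skipped rather than aborting the sweep.

## Lasso arm

`lasso_select` fits an L1-penalized logistic regression on internally
standardized features over a log-spaced penalty grid from the data-driven
λ_max (the smallest penalty that zeroes every coefficient) down four
decades. The penalty is chosen by stratified 10-fold cross-validated
log-loss using the **one-standard-error rule**: the largest penalty whose
CV loss is within one SE of the minimum. The plain CV-minimum tends to
retain spurious genes on pure-noise studies (the usual behavior of
minimum-CV lasso); the 1-SE rule keeps null selections near zero while still recovering
essentially all planted genes at 1.5-SD effects, which is exactly the
asymmetry a feature *selector* (as opposed to a predictor) should have. The
CV-minimum remains available as `lambda_strategy="cv_min"`. The selected
subset then feeds the same registry evaluation as the Monte Carlo arm,
giving the comparison leaderboard.

## Synthetic-data generator

The generator emulates the structure of a multi-region biopsy cohort:
class mix defaulting to the 461/872/1157 control/UC/CD proportions of a
2,490-sample cohort (largest-remainder rounding so counts are exact), ages
from a normal(44.9, 14) discretized and clipped to [19, 82], sexes at the
cohort's 52.8% male rate, and the seven biopsy regions at their observed
frequencies. Expression is per-gene Gaussian noise (baseline mean 8, SD 1 —
a log-intensity-like scale; a log-normal option exists) with
`n_informative` planted genes whose class-conditional means shift by
`effect_size` × SD on the configured contrast; with `informative_task="both"`
the planted set splits evenly between a control-vs-IBD contrast and a
UC-vs-CD contrast with its own effect size. Covariates are generated
independently of class by default (so covariate signal = detectable
artifact); a `confound_region` option ties region to diagnosis for
robustness experiments.

What this does **not** emulate: count-level RNA-seq properties (library
size, overdispersion), gene–gene correlation, batch effects, or any real
biological pathway structure. Passing tests therefore demonstrate that the
*procedure* recovers planted linear-mean signal under clean conditions —
not that any specific gene list from real cohorts is correct.

Default simulation conditions (n = 300 samples, m = 500 genes, 25 planted
genes at effect 1.5, the cohort class mix) are the package's standard
validation fixture: large enough that point-biserial rankings and CV are
stable, small enough that the full search runs in minutes on one CPU.

## Numerical conventions

- Rounding: split sizes round half away from zero; subset sizes floor with
  a minimum of 1; class counts use largest remainder.
- Ties: gene rankings break toward the lower index; leaderboards break
  toward fewer genes, then the algorithm key; the ANN sweep toward fewer
  layers; the final pick prefers the non-ANN model on exact ties.
- All randomness flows from integer seeds through `SeedSequence`; derived
  integer seeds stay below 2³¹.
- Degenerate inputs raise typed errors (single-class labels, empty subsets,
  out-of-range β, q outside (0, 100]) rather than returning sentinel
  values.

## Known limitations

- CV-based candidate selection is subject to winner's curse: on null data
  the top-ranked candidates are systematically the high-variance
  overfitters, whose held-out accuracy then sits *below* the majority rate
  rather than at it. Null-calibration checks should treat "above the upper
  binomial band" as the alarm condition; symmetric bands around the
  majority rate will flag harmless under-performance.
- The registry presets are conventional reconstructions, not bit-level
  replicas of any commercial tool's presets.
- The search evaluates subsets produced by unguided random reduction; it
  finds signal-bearing subsets efficiently but makes no claim of
  optimality among all subsets of a given size.
- Multiclass (3-way) classification and probability calibration are out of
  scope.
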
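# Methods

This note records the modeling choices behind `dffs_qsar`: what each stage
assumes, which knobs matter, what the synthetic benchmark does and does not
emulate, and where the design was genuinely open.

## Data model and preprocessing

Compounds are rows of a descriptor matrix (unique string ids, unique
descriptor names, finite values only — missing cells are rejected at
ingestion rather than imputed, since nothing downstream defines an
imputation semantics). Activity is pIC50 = −log₁₀(molar IC50); the
converter accepts nM / µM / M with nM as the stated default convention, and
label files may carry pIC50 directly.

Uninformative descriptors are removed before anything else. The default
rule (`zero_constant`) drops columns that are identically zero — the
narrow, conservative reading of "constant zero values"; `zero_variance`
generalizes to all constant columns and is the safer choice for data whose
constants are nonzero.

Min–max normalization is fit on the training partition only and applied to
the test partition (`normalize_on="train"`), because fitting on all rows
leaks test-set ranges into training. The flag `normalize_on="all"` exists
to reproduce analyses that normalized before splitting. Test values falling
outside [0, 1] are deliberately not clamped: clamping destroys ordering
information at the extremes. A descriptor constant on the fitted partition
maps to 0 with a warning.

The 8:2 split takes ⌊0.8·n⌋ training rows from a seeded uniform
permutation; the split, like every stochastic stage, draws its seed from
the single run seed through a CRC-based label fan-out (`_seeds.child_seed`),
so stages never share a random stream and a run is reproducible from one
integer.

## Dual-filter feature selection

Three filters score each descriptor against a target:

- **Mutual information.** The discrete MI sum is evaluated on an
  equal-frequency (quantile) binned joint histogram, 16 bins per continuous
  variable by default; variables with ≤ 16 distinct values keep their raw
  categories, which makes MI(X;X) equal the empirical entropy exactly. The
  plug-in estimate carries a positive bias of order (bins−1)²/(2n) —
  ≈ 0.02 nats at n = 5,000 — and loses a little dependence to
  discretization; against the bivariate-Gaussian closed form
  I = −½ln(1−ρ²) at ρ = 0.9 the estimate is low by ≈ 0.04 nats. A
  Kraskov-style k-nearest-neighbour estimator (k = 3) is available where
  binning bias matters. For binary targets the raw two categories are used.
- **Forest impurity** and **boosting gain** run with the libraries'
  published default hyperparameters, on purpose: selection must not depend
  on downstream tuning, and fixed defaults keep the selected subset stable
  under seed changes. Descriptors never used by an ensemble score exactly 0
  and therefore share the worst fractional rank.

Scores become fractional ranks (ties share their mean rank, so every rank
column sums to p(p+1)/2), and the three ranks are averaged — never
re-ranked, so ties in the fused score survive until selection, where they
break lexicographically by descriptor name to keep selection deterministic.
For the five binary endpoints one 40-descriptor set is produced by
averaging the per-endpoint fused ranks (`mean_across_targets`); per-endpoint
selection remains available by calling `select_features` per target.

## Stage 1: activity regression

Four families: bagged random forest, gradient-boosted trees,
histogram-boosted trees, and a cascade forest. The cascade follows the
deep-forest recipe — each layer holds 2 bagged + 2 extremely-randomized
forests; layer l consumes the original features concatenated with layer
l−1's four out-of-fold prediction columns; growth stops when a held-out
20 % validation MSE stops improving (patience 1) or at `max_layers`; the
prediction is the final layer's forest mean. Multi-grained scanning is
omitted because molecular descriptors are unordered tabular features;
sliding windows presuppose sequential or spatial structure.

Hyperparameters are tuned by a budgeted, seeded random search over
versioned per-family spaces (`search_spaces.yaml`) with k-fold CV (default
5). Trial 1 always evaluates the published defaults, which guarantees the
tuned CV score is never worse than the untuned one and makes
feature-set/family comparisons fair at any budget. The tuning objective is
CV-MSE by default with MRE as an alternative. The pipeline default budget
is 10 trials — enough to improve on defaults at desk scale while keeping a
full run in minutes on one CPU.

MRE is undefined when an observed value is exactly 0 (division in the
formula); the implementation raises rather than adding an epsilon, since
pIC50 values are bounded away from 0 in practice and silent fudging would
corrupt comparisons.

## Stage 2: gate and stacking

The gate retains a compound iff its predicted pIC50 ≥ 6 (inclusive by
default; a flag flips to strict >, both defensible readings of a "exceeds
6" rule). Training compounds are gated on out-of-fold stage-1 predictions
— a compound must not be gated by a model that saw its own label; in-sample
(`refit`) and `true_labels` gating exist as flags for sensitivity analysis.
Gated compounds keep their original train/test membership, so stage 2 never
trains on stage-1 test rows.

Per endpoint, the stacking ensemble trains each base classifier on
stratified out-of-fold partitions and collects positive-class probabilities
(not hard labels — the Gaussian naive Bayes meta-learner benefits from
continuous, roughly unimodal inputs) as the meta-feature matrix. Fold
assignment is a function of (compound id, label, seed) — a canonical
per-class id ordering is shuffled by the seeded generator and dealt
round-robin — and every fit consumes id-sorted rows, which makes the
meta-features exactly equivariant under row permutation (bootstrap-based
learners are otherwise row-order sensitive). Base learners are then refit
on all training rows for inference. The SVM base learner emits
probabilities via Platt scaling (decision values through a cross-validated
sigmoid fit). Default base menus per endpoint:
Caco-2: SVM+XGB+LGBM; CYP3A4: kNN+RF+XGB+LGBM; hERG: kNN+RF+XGB;
HOB: kNN+XGB; MN: XGB+LGBM. The decision threshold is fixed at 0.5.

Zero-denominator precision/recall/F1/FPR are reported as 0 with a warning
so that report tables stay machine-readable. AUC is computed as the
Mann–Whitney probability with ties counted ½ (identical to the trapezoidal
ROC area).

## Interpretation

φ is computed from raw 2×2 counts; the chi-square statistic uses no
continuity correction, so the identity χ² = n·φ² is exact and testable
(with Yates' correction the identity breaks, and the φ value itself is the
quantity of interest). Significance stars follow the conventional ladder
\*\*\* p<0.001, \*\* p<0.01, \* p<0.05. A constant endpoint makes φ
undefined; those cells are reported as undefined with the reason instead of
failing the whole matrix.

Tree-Shapley attributions use the path-dependent polynomial-time recursion
over tree paths, with the cover-weighted conditional expectation as the
absent-feature model; the base value is therefore the training-mean
prediction. scikit-learn forests run through the in-package float64 kernel
(numba-accelerated when available, with a pure-Python fallback); lightgbm
models use their built-in exact contribution predictor; xgboost trees are
extracted and pushed through the in-package kernel because the booster's
native contribution output is float32, which cannot meet the 1e−6
local-accuracy contract (thresholds and inputs are routed through float32
to match the booster's comparisons exactly, and a float64 traversal serves
as the independent prediction reference). Local accuracy — attributions
plus base reproduce each prediction — is enforced at 1e−6 on every call,
whatever the computation path. Attributions default to the held-out test
partition: interpretation should not reuse training rows. Deeper-than-one
cascade forests are rejected for attribution (their inner layers consume
augmented features that are not descriptors); single-layer cascades
attribute as the mean of their four forests.

## The synthetic generator

The generator emulates the *statistical shape* of a screening table, not
chemistry: several hundred descriptor columns on mixed scales (normal,
lognormal, uniform, count-like; scales spanning three decades) including a
block of constant-zero columns; a pIC50 equal to an additive signal over a
small informative subset plus one pairwise interaction and one threshold
term, Gaussian noise (`noise_sd`, default 0.5 on a unit-variance signal →
attainable R² ≈ 0.8), rescaled so the pIC50 spread is ≈ 1.3 and a stated
fraction (default 0.624) exceeds the gate at 6.

Endpoint labels use probit links: endpoint j fires when a latent unit
Gaussian Z_j exceeds the quantile of its target prevalence (defaults 0.28,
0.80, 0.65, 0.12, 0.65 — an imbalanced panel with one rare endpoint). The
Z_j share one common factor with per-endpoint loadings; each pair's target
φ is converted to the Gaussian correlation it requires (tetrachoric
inversion via the bivariate normal CDF) and a rank-one λλᵀ model is fit to
those correlations by least squares, so the emitted labels hit the
requested φ matrix up to the rank-one approximation — exactly, for a
single planted pair. An unreachable φ (margins bound the attainable value)
raises with the offending pair named. The common factor and the unique
parts are themselves partly descriptor-driven (`shared_signal` = 0.95,
`unique_signal` = 0.97 by default), which makes the endpoints learnable
from descriptors while carrying label–label association; the per-endpoint
weights on the descriptor pool are orthogonal rows, keeping the unique
parts uncorrelated so the φ calibration stays exact. Two mixes exist:
`dense` (every pool descriptor informative for every endpoint — the
realistic overlap that multi-target rank fusion needs) and `sparse`
(block-diagonal, maximally learnable — used by the separable stacking
benchmark, which also raises the signal shares to 0.99).

What passing tests on this generator show: the pipeline recovers planted
signal, respects out-of-fold discipline, and reproduces planted
associations. What they cannot show: behavior under correlated descriptor
blocks, heavy-tailed assay noise, activity cliffs, or any chemical
realism — descriptors here are independent draws, which real PaDEL tables
are not.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run at desk scale by design: the
default end-to-end benchmark is n = 2,000 × p = 500 with a 10-trial tuning
budget (one run ≈ 2 minutes on a single core); selection recovery uses 20
replicates of n = 1,000 × p = 200; stacking checks use 10 replicates of
n = 1,000; φ recovery uses n = 10,000. The acceptance script reports the
recovery benchmark over 5 replicates.

## Known limitations

- The rank-one latent structure cannot reproduce an arbitrary 5×5 φ matrix;
  residuals of the least-squares fit are the price of a single shared
  factor.
- The cascade forest's early stopping uses one internal validation split;
  on small n its depth choice is noisy (the fitted depth is still bounded
  and the single-layer limit is exact).
- Random search replaces model-based (Bayesian) search for hyperparameters;
  with defaults as trial 1 it is monotone non-harmful, but at small budgets
  it explores less efficiently than an adaptive sampler.
- Attribution supports tree-ensemble regressors only; kernel/linear
  attribution and second-order (interaction) values are out of scope.
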
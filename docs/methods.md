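# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind `radefs`.

## Data model and its assumptions

An observation is one lymph node imaged in one CT phase; a *node* contributes
up to three observations (staging, planning, restaging) that share its class
label and patient. Every piece of machinery that separates data — the 80:20
split, the cross-validation folds, the selector-internal folds, the
calibration folds — partitions **nodes**, never observations, and stratifies
by node class. This is the repeated-measure discipline the cohort structure
demands: phase scans of one node are strongly correlated, and letting them
straddle a train/test boundary would leak identity, not generalization.

## Feature extraction

`extract_features` computes the 120-name manifest natively: 19 first-order
statistics, 16 three-dimensional and 10 two-dimensional shape descriptors,
and 24 + 16 + 16 + 14 + 5 texture features from the GLCM, GLRLM, GLSZM, GLDM
and NGTDM families, using the field's standard formulas on a 16-level
equal-width quantization of the in-mask intensities with 26-connectivity
(13 direction offsets). Names follow the `<family>_<FeatureName>` convention
so extractor output and synthetic tables share one schema.

Numerical choices worth knowing:

- Surface quantities come from a marching-cubes mesh of the mask after a
  light Gaussian anti-aliasing (σ = 0.8 voxels). A binary isosurface is
  jagged and overestimates area by 5–8%, which biases sphericity low; with
  smoothing, a discretized radius-8 ball measures sphericity ≈ 0.99.
  A region too small to survive smoothing falls back to the raw binary mesh.
- Axis lengths are 4·√λ of the voxel-coordinate covariance eigenvalues
  (physical spacing applied); maximum diameters use convex-hull vertices.
- 2D shape is computed on the largest axial slice; perimeter and mesh surface
  come from sub-voxel contours (marching squares).
- Mask semantics: any nonzero voxel is ROI; multi-label masks require an
  explicit `label=`.

## Synthetic cohort generator

`GeneratorConfig` defaults define the study conditions: 78 nodes × 3 phases
= 234 observations; node classes drawn multinomially with probabilities
81/234, 108/234, 45/234; 120 features.

Structure, and how each piece is built:

- **Unit-variance latents.** Every latent variable mixes an observation-level
  and a node-level Gaussian as `(ε_obs + s·ε_node)/√(1+s²)` with
  `s = node_effect_sd = 0.5`, so each feature has variance 1 and within-node
  (phase-to-phase) correlation s²/(1+s²) = 0.2.
- **Correlated blocks.** Four 12-feature blocks share a latent factor with
  loading √r (r = 0.95), giving exact pairwise correlation r inside a block.
  Planted class shifts inflate the variance of their columns and pull those
  pairs below the 0.9 threshold; with that accounted for, ≈ 2.6–2.7% of the
  7140 feature pairs exceed |ρ| = 0.9, the redundancy level typical of
  radiomics tables.
- **Planted signal.** Class-specific mean shifts, in SD units (features are
  unit-SD, so shifts are direct). The defaults mirror the clinical
  expectation that reactive nodes separate on shape, pathologic nodes on
  texture, and ECS nodes on a mix of texture and first-order features, with
  effects of 1.0–1.5 SD. `strong_signal_config` doubles these effects and is
  the designated fixture for end-to-end pipeline checks; its pass threshold
  (held-out macro BACC ≥ 0.85) is calibrated to this fixture, not to any
  clinical result. `recovery_config` is the selector-recovery fixture:
  5 planted features among 40, ±1.5 SD, 120 nodes, no blocks.
- **Non-normality.** 30% of the features (chosen among columns that are
  neither planted nor in a block, so effect sizes and block correlations stay
  exact) are pushed through `exp`, making them log-normal and ensuring the
  Shapiro–Wilk screen has something to reject.

What the generator does **not** emulate: real radiomics features are
deterministic functions of an underlying image, with feature-family
correlation structure, heavy tails and measurement noise tied to acquisition;
here they are draws from a convenient parametric model. Passing tests on
synthetic cohorts therefore validates the *machinery* (leakage discipline,
selector correctness, calibration, Pareto logic), not clinical performance.
The cohort size also embeds a known oddity of the motivating setting: "234
segmented nodes" coexists with "three scans per node", and the data model
keeps both readings (node_id vs observation_id); the generator follows the
78-nodes × 3-phases interpretation.

## Preprocessing

- Z-scoring uses the sample SD (ddof = 1), estimated on training observations
  only and applied to all sides; constant training features are dropped
  everywhere with a warning.
- The Shapiro–Wilk screen runs on raw (pre-standardization) values — the test
  is affine-invariant, so this is a reproducibility convention, not a
  necessity — pooled across classes (a per-class variant is a possible
  extension). A feature is an NDF iff p > α (α = 0.05); constant features are
  flagged undefined. At α = 0 nothing survives; at α = 1 everything
  non-constant does.
- The 80:20 split takes round(0.2 · class node count) test nodes per class
  (at least 1, never all); a class with a single node is a stratification
  error.

## Selection strategies

All wrappers score candidate subsets by balanced accuracy from an internal
node-grouped, class-stratified 3-fold CV on the training partition — never
the outer test set — so selection itself cannot leak. BACC is used because
the classes are imbalanced. The internal default estimator is a minimal
closed-form pooled-covariance LDA (with a small ridge): population-scale
genetic search needs ~10⁵ subset evaluations per run, which estimator
objects cannot sustain; any `ClassifierSpec` can be substituted where
fidelity to a specific classifier matters.

**GA.** Binary chromosomes over the candidate pool; fitness
λ₂·BACC − λ₁·|P|/d − κ·||P|−p_target| (the printed form is a cost; the
implementation maximizes performance-minus-penalty, which reproduces the
stated preference for smaller subsets at equal accuracy). Defaults follow the
reference configuration: population 5000, 500 generations, crossover 0.5,
mutation 0.2, tournament size 3 (roulette available), elitism 1. Mutation
rate is per-chromosome; a mutated chromosome flips each gene with probability
1/d (a per-gene rate of 0.2 would destroy convergence at d = 120).
Initialization density is p/d; an empty chromosome is repaired by activating
one random gene. Replicate runs are combined by selection-frequency
consensus: top-p by frequency, ties broken by mean fitness contribution, then
name. With elitism ≥ 1 the per-run best-fitness trace is nondecreasing.
κ defaults to 1/d when a size target is set.

**SDA.** Sequential elastic-net penalized optimal scoring with q = K−1
directions: alternately solve the elastic-net regression of Yθ on X by cyclic
coordinate descent (covariance updates, tolerance 1e-6, max 1000 sweeps) and
update the score vector θ in closed form, projecting out the constant score
and earlier directions under the class-proportion inner product
(convergence: coefficient change < 1e-6 or 100 iterations). The support is
the union of nonzero coefficient rows; λ is tuned by 30-step log-scale
bisection to hit the requested size, and when the closest achievable support
over- or undershoots, features are ranked by coefficient row norm (padding
ranked features when the support is too small, with a warning). The ridge
weight γ′ defaults to 0.01 — enough to stabilize d ≫ n fits without visibly
biasing the support. A single-direction mode (q = 1) matching the
scalar-response formulation is available. Support size is weakly decreasing
in λ at fixed γ′ (property-tested), and at λ = γ′ = 0, q = 1, n > d the
direction coincides with the least-squares discriminant (cosine ≥ 0.99).

**RFE.** Backward elimination of the `step_n` least-important features per
refit (|coefficients| for linear models, impurity importance for tree
ensembles) until p remain. Kernel SVMs expose no importance vector and are a
capability error as elimination estimators. Stochastic estimators are
replicated with frequency consensus; deterministic ones run once and are pure
functions of (cohort, request).

**RF/XGBoost importance.** Fit on the (standardized) cohort, rank by
importance, take top-p; replicated with distinct sub-seeds from the request
seed. XGBoost's tree count is unspecified upstream; 200 (matching RF) is the
package default, with learning rate 0.01 as given.

## Classifiers

Six library-backed configurations: LDA; SVM with linear, sigmoid and RBF
kernels; random forest (200 trees, max depth 42 — unusually deep, but
implemented as given and overridable); XGBoost (learning rate 0.01). Kernel
formulas are additionally implemented natively for unit testing. Unstated
hyperparameters are pinned for reproducibility: SVM C = 1.0, sigmoid
α = 1/d and offset 0, RBF γ = 'scale'. LDA switches to the lsqr solver with
automatic shrinkage whenever the fold has d ≥ n, keeping large-p grid cells
runnable where the pooled covariance is singular. SVM probabilities use the
adapter's probability mode (internal Platt scaling); all probability rows are
renormalized to sum to 1.

## Evaluation

Balanced accuracy is macro-averaged per-class recall (for binary tasks this
equals the mean of sensitivity and specificity; the macro form generalizes it
to three classes with one definition). F1 is binary against the designated
positive class in the per-class tasks and macro-averaged for the 3-class
summary. AUC is the rank-based area (ties count ½), averaged one-vs-rest for
multi-class scores, and matches brute-force pair counting exactly. Fold
metrics are averaged per fold with SD across folds (pooled-prediction
variants would hide inter-fold variability); a fold whose training side lacks
a class is skipped with an error record. The default plan is stratified
5-fold at seed 42.

## Model selection

The grid enumerates selection methods × estimators × subset sizes ×
classifiers per task; the canonical size ladder is {2..10} ∪ {20,30,…,90}
(17 sizes). Selection results are cached per (task, request) so a subset is
computed once and evaluated under every classifier; individual failures
become error records without stopping the grid. Stage one keeps
configurations with all three metric means ≥ 0.70 (the floor applies to fold
means, matching how the metrics are reported). Stage two applies standard
Pareto dominance — weakly better in all four objectives (three metrics up,
feature count down) and strictly better in one. "Best overall" is not
uniquely defined by a front, so the package adopts the unweighted mean of the
three metric means, ties broken by fewer features then configuration id —
equal weight to the metrics while minimizing features. Per-class tasks are
binary one-vs-rest relabelings of the 3-class cohort.

## One-vs-rest ensemble

Per class: fit the class's best configuration (features + classifier) on the
class-vs-rest relabeling, calibrate its positive-class score with a
Platt-style sigmoid fitted on out-of-fold scores from an internal
node-grouped 3-fold split (sigmoid rather than isotonic: robust at small n),
then refit on all training data. Prediction is confidence voting: argmax of
calibrated probabilities — the weighted-by-certainty combination degenerates
to argmax for a single prediction per submodel, which is the minimal
operational reading — with exact ties resolved by clinical severity
(ecs > pathologic > reactive), biasing against the costliest error of calling
a malignant node benign. Reported confidences are renormalized to sum to 1.
Evaluation reports per-class BACC/AUC/F1 with their range, mean and SD
**across classes** (fold SDs remain available inside MetricSummary), the 3×3
confusion matrix, and per-class ROC curves.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the pipeline at deliberately
scaled sizes — GA at population 200 × 50 generations × 10 runs, grids of
2 methods × 3 sizes × 2 classifiers, recovery over 10 seeds — chosen so the
full suite completes in minutes on one CPU while still exercising every code
path at the cohort scale the generator emulates. The GA's paper-scale
defaults (5000 × 500 × 100 runs) remain the package defaults for real use.

## Known limitations

- The extractor targets fidelity to the standard formula families, not
  bit-compatibility with any particular extraction library; absolute texture
  values depend on quantization and aggregation conventions.
- The generator's planted-shift model cannot express interaction-only signal;
  selector recovery results speak to additive effects.
- SDA's λ-bisection assumes support size is (weakly) monotone in λ, which
  coordinate descent can violate locally; the bisection keeps the
  closest-achievable solution rather than assuming exactness.
- The stated experiment counts of the motivating study (27,000 GA / 17,270
  RFE / 44,360 total) do not factor into any grid expressible from its stated
  dimensions; the grid here is fully configurable instead of reproducing
  those cardinalities, and the quoted "2.2 samples per feature" (vs
  234/120 ≈ 1.95) is likewise documented without reconciliation.
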
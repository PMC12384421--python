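# radefs

Eliminative feature selection and class-specific ensemble classification for
CT lymph-node radiomics.

## The problem

Cervical lymph-node status drives staging and treatment planning in head and
neck squamous cell carcinoma (HNSCC), but conventional CT criteria (axial
diameter, margin irregularity) miss early disease. Radiomics converts the
segmented node into a table of quantitative descriptors — first-order
intensity statistics, 3D/2D shape, and gray-level texture matrices (GLCM,
GLRLM, GLSZM, GLDM, NGTDM) — and asks a classifier to separate three classes:
**reactive** (non-pathologic), **pathologic**, and **pathologic with
extracapsular spread (ECS)**.

The statistical difficulty is the regime: a few hundred observations against
120 features, heavy redundancy (a few percent of feature pairs with
|ρ| > 0.9), and repeated measures (each node imaged in three CT phases —
staging, planning, restaging). `radefs` implements the full pipeline for this
regime, with a synthetic cohort generator so every component can be exercised
and validated without clinical data.

## What is in the box

| Stage | Module | Core idea |
|---|---|---|
| Extraction | `radefs.extraction` | 120-feature vector from a CT volume + mask (NRRD/DICOM via SimpleITK) |
| Simulation | `radefs.simulate` | cohorts with planted ground truth, correlated blocks, node random effects |
| Preprocessing | `radefs.preprocessing` | Z-scoring (train-only), Shapiro–Wilk normality screen, node-level 80:20 split |
| Selection | `radefs.selection` | GA, SDA, RFE, RF/XGBoost importance, frequency consensus across runs |
| Classifiers | `radefs.classifiers` | LDA, SVM (linear/sigmoid/RBF), RF, XGBoost adapters |
| Evaluation | `radefs.evaluation` | node-grouped stratified 5-fold CV; BACC, OvR AUC, F1 |
| Model selection | `radefs.model_selection` | 0.70 metric floor, then Pareto front over (BACC, AUC, F1, −#features) |
| Ensemble | `radefs.ensemble` | per-class calibrated one-vs-rest submodels, confidence voting |

The genetic-algorithm selector maximizes the weighted-sum fitness

```
fitness(P) = λ₂·c₂(P) − λ₁·c₁(|P|) − κ·||P| − p_target|
```

with `c₂` the internal cross-validated balanced accuracy of subset `P`,
`c₁ = |P|/d` the normalized feature count (equal weights λ₁ = λ₂ = 1 favor the
smaller of two equally accurate subsets), and κ > 0 enabling the soft
subset-size constraint (GAp). Sparse discriminant analysis solves elastic-net
penalized optimal scoring,

```
min_β ‖Yθ − Xβ‖² + λ‖β‖₁ + γ′‖β‖₂²,
```

taking the union of nonzero coefficient rows across the K−1 discriminant
directions as the selected support, with λ tuned by bisection to the requested
subset size.

## Worked example

```python
from radefs import (ClassifierSpec, SelectionRequest, generate_cohort,
                    recovery_config, rfe_select)

cohort, truth = generate_cohort(recovery_config(seed=0))
result = rfe_select(cohort, SelectionRequest(
    "rfe", p=5, runs=1, seed=0, estimator=ClassifierSpec("svm_linear")))
print(sorted(result.selected))
print(len(set(result.selected) & truth.informative()), "of 5 planted recovered")
```

prints

```
['firstorder_Entropy', 'firstorder_Range', 'shape2d_PerimeterSurfaceRatio',
 'shape3d_MajorAxisLength', 'shape3d_SurfaceVolumeRatio']
5 of 5 planted recovered
```

— recursive elimination with a linear-SVM importance ranking finds exactly the
five features the generator planted (±1.5 SD class shifts among 40
candidates). The `examples/` directory walks through every capability the same
way: simulation, extraction, preprocessing, all four selector families, the
grid + Pareto stage, and the calibrated one-vs-rest ensemble. A thin CLI
(`radefs simulate|preprocess|select|grid|pareto|ensemble|report`) wraps the
same functions for shell use.

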
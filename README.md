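# mvbiomarkers

Multi-view, graph-regularized label-subspace learning for extracting
MCI-conversion biomarkers from regional cortical thickness and volume
features.

## The problem

Predicting which subjects with mild cognitive impairment (MCI) will
convert to Alzheimer's disease (pMCI) and which will remain stable
(sMCI) is hard in the raw morphometric feature space: the two groups
overlap heavily. AD patients and normal controls (NC), however,
separate cleanly on the same features. This package learns a compact
representation from those *auxiliary* AD/NC subjects and transfers it
to the MCI subjects — which also sidesteps double-dipping, since the
target subjects never influence their own representation.

Two projections U, V ∈ R^{d×c} (one per morphological view) are
learned by minimizing

```
Q(U,V) = λ(‖Y − X_CTᵀU‖² + ‖Y − X_CVᵀV‖²)      label regression
       + (1−λ)‖X_CTᵀU − X_CVᵀV‖²               cross-view consistency
       + α(tr(UᵀX_CT L_CT X_CTᵀU) + …)          graph regularization
       + β(‖U‖² + ‖V‖²)                         ridge
```

where Y is the one-hot AD/NC indicator and L_CT, L_CV are Laplacians
of per-view kNN heat-kernel graphs. The optimizer alternates exact
closed-form ridge updates from zero initialization, so the objective
is provably nonincreasing. MCI subjects are then projected
(Fea = ZᵀU, ZᵀV) and fused into the final nonnegative biomarker

```
Fea = η·|Fea_CT|⊙|Fea_CT| + (1−η)·|Fea_CV|⊙|Fea_CV|
```

which a conventional classifier (decision tree, RBF or linear SVM)
evaluates under repeated stratified 10-fold cross-validation with an
ACC/SEN/SPE/AUC panel and paired t-tests. A synthetic-cohort module
generates two-view AD/NC/pMCI/sMCI populations with controllable
separation, cross-view coupling and noise, so the whole pipeline is
testable without any clinical data. See `docs/methods.md` for the
model details and design rationale.

## Worked example

```python
import numpy as np
import mvbiomarkers as mv
from mvbiomarkers.evaluation import CVConfig, run_protocol

spec = mv.CohortSpec(
    n_per_group={"AD": 150, "NC": 150, "pMCI": 100, "sMCI": 100},
    delta=3.0, rho=0.7, seed=1,
)
cohort = mv.generate_cohort(spec)
aux = cohort.subset(np.isin(cohort.group_labels, ["AD", "NC"]))
target = cohort.subset(np.isin(cohort.group_labels, ["pMCI", "sMCI"]))

model = mv.fit_model(aux.X_CT, aux.X_CV, aux.group_labels, ("AD", "NC"), mv.HyperParams())
print(f"solver: {model.trace.n_iter} iterations, final objective {model.trace.objective_values[-1]:.3f}")

from mvbiomarkers.biomarkers import biomarkers_from_model
Fea = biomarkers_from_model(model, target.X_CT, target.X_CV)
print(f"biomarkers: {Fea.shape[0]} subjects x {Fea.shape[1]} dims, all >= 0: {bool((Fea >= 0).all())}")

cfg = CVConfig(n_repeats=20, base_seed=1, classifier="svm-linear")
res = run_protocol(aux, target, mv.HyperParams(), cfg)
print(f"ACC={res.mean.acc:.4f} SEN={res.mean.sen:.4f} SPE={res.mean.spe:.4f} AUC={res.mean.auc:.4f}")
```

prints

```
solver: 44 iterations, final objective 17.912
biomarkers: 200 subjects x 2 dims, all >= 0: True
ACC=0.9540 SEN=0.9545 SPE=0.9535 AUC=0.9869
```

The solver converged in 44 alternating updates; the 200 MCI-like
target subjects get a 2-dimensional nonnegative biomarker (one
coordinate per auxiliary class); and a linear SVM on that biomarker
separates pMCI-like from sMCI-like subjects with 95.4% mean accuracy
over 20 repeats of 10-fold cross-validation — high because this
synthetic cohort is built to be cleanly separable (delta = 3 within-
class standard deviations between AD and NC means).

The same pipeline is available from the shell:

```sh
mvbiomarkers simulate --seed 1 --out-dir data/
mvbiomarkers fit --ct data/aux_ct.csv --cv data/aux_cv.csv \
    --labels data/aux_labels.csv --model-out model.json
mvbiomarkers transform --ct data/tgt_ct.csv --cv data/tgt_cv.csv \
    --labels data/tgt_labels.csv --model model.json --out biomarkers.csv
mvbiomarkers evaluate --seed 1 ... --out-dir run/
mvbiomarkers report --summary run/summary.json
```

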
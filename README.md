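# ltr-ehr

Interpretable logistic tensor regression (LTR) for predicting which
heart-failure patients warrant evaluation for advanced therapies (heart
transplantation or mechanical circulatory support) from paired EHR visits:
the medical codes and lab values of one hospital visit, plus the irregular
number of days until the next visit, predict the referral decision made at
that next visit.

The package is aimed at clinical-ML researchers who want a risk model that
uses medical codes *and* explains itself: both models expose code-level
weights, at the population level and per patient.

## Models

Each sample is (X, x, t, y): X ∈ R^{M×D} stacks word2vec embeddings of the
codes present at the visit (zero rows elsewhere), x ∈ R^d holds labs/vitals,
t is the gap in days, y ∈ {0,1}. Irregular time enters through a sine/cosine
positional encoding PE(t) of length D+d applied multiplicatively to X's
columns and x's entries.

**Standard LTR** — a bilinear logistic classifier with global code weights
u ∈ R^M:

    P(y=1) = σ( [uᵀX | xᵀ] v + b ),    u ∈ R^M, v ∈ R^{D+d}, b ∈ R.

**Personalized LTR** — replaces u by an embedding-space weight w ∈ R^D
acting through the sample Gram matrix S = XᵀX:

    P(y=1) = σ( [wᵀS | xᵀ] v + b ),    with per-patient code weights u_i = X_i w,

an attention formulation whose code weights vary by patient while training
only D parameters. Both are fit by Adam on the cross-entropy plus an L1
penalty λ‖u‖₁ (resp. λ‖w‖₁) that concentrates the model on few codes, with
Kaiming-uniform initialization, patient-wise validation early stopping and
exhaustive grid search over (lr, λ).

Because no paired-visit referral cohort can be shared, the package includes
a seeded synthetic cohort generator with known ground truth (code
vocabulary with phenotype-group structure, group-correlated code
co-occurrence, class-structured labs, log-normal gap times, labels from a
known sparse LTR model), which powers all tests and reproduction scripts.
See `docs/methods.md` for the model, generator and protocol details.

## Worked example

```python
import ltr_ehr as L

# a synthetic cohort sized like a single-center study: 300 patients, 557 pairs
vocab  = L.generate_vocabulary(n_codes=200, n_groups=20, seed=1)
cohort = L.generate_cohort(vocab, n_patients=300, n_pairs=557, D=8, seed=1)

# code embeddings from visits-as-documents, evaluated against phenotype groups
emb = L.train_embeddings(cohort, D=16, method="sgns", epochs=8, seed=1)
print(f"embedding pair AUC: {L.evaluate_embedding_auc(emb):.3f}")

# patient-wise stratified 10-fold CV comparing both LTR models with baselines
# (a larger cohort so per-code weights are estimable; see docs/methods.md)
from ltr_ehr.evaluation import run_cv
vocab2  = L.generate_vocabulary(n_codes=80, n_groups=12, seed=1)
cohort2 = L.generate_cohort(vocab2, n_patients=1000, n_pairs=2000, D=8,
                            sparsity=0.3, code_rate=6, seed=1)
emb_true = L.CodeEmbedding(vocab2, cohort2.truth.embedding_true)
plan   = L.make_fold_plan(cohort2, k=10, test_ratio=0.2, seed=1)
cfg    = L.TrainConfig(lr=0.05, lam=1e-3, max_steps=2000, seed=1,
                       val_fraction=0.15, patience=30, n_restarts=2)
report = run_cv(cohort2, emb_true, models=("s-ltr", "p-ltr", "lr", "nb"),
                plan=plan, train_cfg=cfg, seed=1)
print(report.summary[["model", "auc_mean", "auc_std", "f1_mean"]].to_string(index=False))
```

Output:

```
embedding pair AUC: 0.995
model  auc_mean  auc_std  f1_mean
s-ltr  0.918787 0.025876 0.847179
p-ltr  0.621612 0.054575 0.285960
   lr  0.584238 0.062713 0.000000
   nb  0.599769 0.057150 0.337019
```

The embedding pair AUC of 0.995 says that cosine similarity of the learned
code vectors almost perfectly classifies whether two diagnosis codes share
a phenotype group — the embeddings captured the co-occurrence structure.
In the CV table, Standard LTR (AUC 0.92, F1 0.85) clearly outperforms the
pooled-feature baselines (AUC ≈ 0.58–0.60): the bilinear model exploits
the per-code structure that global pooling averages away. The Personalized
model trails here because the synthetic truth is a Standard-LTR with an
arbitrary per-code weight vector, which its D-parameter attention cannot
represent exactly — a property of the generator, discussed in
`docs/methods.md`.

A fitted Standard model is interpreted at the population level with
`L.population_importance(fit, cohort, min_weight=0.1, min_patients=30)`
(codes ranked by weight, filtered to those carried by enough patients), a
Personalized fit per patient with `L.personalized_importance(fit, sample)`,
and single-code counterfactuals with
`L.code_perturbation_risk(fit, pair, emb, code, "add")`, which returns the
predicted risk before and after toggling one code.

## Command line

The same pipeline runs end to end from a YAML config:

```sh
ltr-ehr run --config run.yaml      # simulate -> embed -> fit -> evaluate -> interpret
ltr-ehr simulate --out demo --n-patients 250 --n-pairs 500 --seed 1
ltr-ehr embed --cohort demo --out demo/emb.txt --dim 16
ltr-ehr fit --model standard --cohort demo --embedding demo/emb.txt --out demo/fit.json
ltr-ehr evaluate --cohort demo --embedding demo/emb.txt --out demo/report.json
ltr-ehr interpret --cohort demo --fit demo/fit.json --out demo/importance.csv
```

Each stage persists its output (cohort CSV + vocabulary/truth JSON,
word2vec-text embeddings, parameter JSON, report JSON/TSV, importance CSV)
and a rerun resumes from whatever already exists; a manifest records the
config hash and per-stage timings.

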
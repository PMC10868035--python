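# Methods

## The prediction problem

Each training sample is a pair of consecutive hospital visits of a
heart-failure patient. Features come from the first visit: the multiset of
medical codes recorded there (diagnoses, procedures, drug classes), a small
vector of labs/vitals (d = 4 by default: systolic blood pressure, heart
rate, chloride, sodium), and the elapsed time t between the two visits in
days. The binary label says whether, at the second visit, the patient
warranted evaluation for advanced therapies (heart transplantation or
mechanical circulatory support). A patient with n consecutive visits
contributes n − 1 pairs, so all data splitting is patient-wise.

## Models

Codes are mapped to vectors in R^D by word2vec trained on visits-as-
documents, and stacked into the sample matrix X ∈ R^{M×D} with a nonzero
row for every code present (presence-based: duplicates collapse; a counts
mode exists behind a flag). Irregular gap time enters through a fixed
sine/cosine positional encoding PE(t) of length D + d (D + d must be even),
applied multiplicatively: column k of X is scaled by PE entry k, lab entry
k by PE entry D + k. The multiplicative application differs from the
additive transformer convention and is the intended formulation here; an
additive mode exists for ablation. t is used raw, in days.

**Standard LTR.** logit = [uᵀX | xᵀ] v + b with u ∈ R^M global code
weights, v ∈ R^{D+d}, b ∈ R; probability through a sigmoid. u_m is the
population-level importance of code m.

**Personalized LTR.** Replaces u by an embedding-space weight w ∈ R^D
acting through the sample Gram matrix S = XᵀX: logit = [wᵀS | xᵀ] v + b.
Since wᵀXᵀX = (Xw)ᵀX this is the Standard model with per-patient code
weights u_i = X_i w — an attention mechanism with only D trainable weight
parameters. Both algebraic routes are implemented and verified equal to
1e-10. The output nonlinearity is a sigmoid; a tanh mode (affinely mapped
into (0,1)) exists behind a flag for comparison.

**Loss.** Mean binary cross-entropy plus λ‖u‖₁ (λ‖w‖₁ for Personalized),
computed stably from logits as softplus(z) − y·z. Logits are clamped to
|z| ≤ 30. Labels are stored as {0,1}; the equivalent {−1,+1} logistic-loss
convention is handled at the loss boundary.

## Identifiability and the reporting convention

The bilinear form is scale/sign non-identifiable: (u, v[:D]) →
(αu, v[:D]/α) leaves every logit unchanged for any α ≠ 0, including
α < 0. Fitted and generated parameters are therefore reported in a
canonical orientation: (u, v[:D]) is flipped jointly so that the signed
energy Σ_m u_m|u_m| is positive. The anchor is odd under the flip, so both
members of a flip pair canonicalize identically, and squaring the
magnitudes makes it depend on the few dominant weights rather than the many
near-zero ones, which is what makes it stable under refitting. This is a
pure reporting convention; predictions never change. Consequently,
recovery of generated code weights is only defined up to a positive scale,
and is measured by cosine similarity after unit-norm alignment.

## Training

Full-batch Adam (β₁ = 0.9, β₂ = 0.999), Kaiming-uniform initialization
with bound √(6/fan_in) (fan_in = M for u, D for w, D + d for v and b), and
early stopping on a patient-wise validation split (default 10%, evaluated
every 25 steps, patience 20 evaluations); the parameters of the best
validation evaluation are returned. The L1 term is handled by a proximal
soft-threshold step inside Adam (threshold λ·lr/(√v̂+ε) per coordinate), so
shrunk weights become exact zeros; the exported analytic gradient keeps the
sign-subgradient convention (0 at 0) and matches central finite differences
to a relative 1e-5.

The objective is non-convex in (u, v) jointly and a fraction of random
initializations converges to clearly inferior stationary points whose
code-weight direction is nearly orthogonal to the good family. Two remedies
are provided: `fit(n_restarts=k)` reruns from fresh seeds and keeps the run
with the best validation AUC (discrimination tracks the generating signal
more reliably than cross-entropy, whose value is dominated by calibration
in the presence of label noise); `fit_averaged` additionally screens
restarts by validation AUC and direction alignment, resolves the per-run
scale/sign ambiguity, and averages the aligned parameter vectors, which
shrinks direction noise roughly by √k. Validation-based early stopping is
load-bearing: on near-separable cohorts the unconstrained fit drifts into
the saturated regime and per-code weights degrade.

Hyperparameters (lr, λ) come from an exhaustive grid search (defaults
lr ∈ {1e-3, 1e-2}, λ ∈ {0, 1e-3, 1e-2, 1e-1}) selected by validation AUC on
a patient-wise internal split, ties broken toward smaller λ, then smaller
lr, followed by a refit on the full training data.

## Evaluation protocol

A 0.2 fraction of patients is held out entirely; the remainder is split
into ten stratified patient-wise folds (a patient is stratified as positive
if any of their pairs is positive; disjointness is asserted on every run).
Metrics: accuracy and F1 = 2TP/(FN + 2TP + FP) at threshold 0.5, AUC
(midrank ties), AUPRC (step integration). Baselines — logistic regression,
linear SVM (decision-function scores; no Platt scaling), Gaussian naive
Bayes, random forest — consume the (D+d)-vector obtained by averaging all
M rows of X (zeros included, matching the global-pooling definition;
a nonzero-row mean exists behind a flag) concatenated with labs. Weight
transfer replaces the unweighted mean by Σ_m weight_m·X[m,:], with weights
from a Standard-LTR fit (global u) or a Personalized fit (per-sample
u_i = X_i w, recomputed for test samples from their own inputs — no
leakage, w comes from the training fold). Model comparison uses Cohen's D
on fold AUCs with the pooled-SD formula (≥0.8 large, 0.5–0.8 moderate).

## Synthetic cohort generator

No public paired-visit referral cohort exists, so the package ships a
seeded generator with a known ground truth:

* **Vocabulary** — codes styled after ICD-10/CPT-4/VA drug classes in
  proportions 5970:2229:239 (scaled), each assigned to a phenotype group
  (the Phecode analog used to evaluate embeddings).
* **Visits** — code count 1 + Poisson(code_rate, default 5); each visit
  draws codes mostly (group_fidelity, default 0.75) from one phenotype
  group, creating the within-group co-occurrence embeddings must learn.
* **Gap times** — log-normal with median 60 days and σ = 0.75 (heavy tail;
  exercises the positional encoding nontrivially).
* **Labs** — per-class Gaussians whose means/SDs default to published
  end-stage heart-failure summary statistics (e.g. systolic BP
  102.74 ± 14.95 positive vs 121.68 ± 22.74 negative), mixed through a
  latent severity indicator (prevalence 0.35); labs enter the generating
  logit standardized by the population moments.
* **Labels** — drawn Bernoulli(sigmoid(logit)) from the Standard-LTR
  forward model with PE applied, using a ground-truth embedding matrix
  (N(0,1) entries), a sparse code-weight vector u_true (default: 20% of
  codes nonzero, magnitudes U(15, 30), 60% positive by count), unit-norm
  v[:D], and then flipped with probability `noise`. The default weight
  scale is deliberately strong: the Bernoulli draw is itself a large noise
  source, and cohorts whose outcome is mostly attributable to the recorded
  codes are the regime the models target. An explicit u_true can be
  injected. All parameters, per-sample probabilities and the label RNG
  seed are recorded, so labels regenerate exactly.

What the generator does **not** emulate: longitudinal within-patient
correlation beyond sharing a patient id, code hierarchies/real Phecode
maps, missingness, measurement error in labs, informative visit timing,
and any personalized (input-dependent) generative weight structure. In
particular, because the truth is a Standard-LTR with an arbitrary per-code
u, the Personalized model (D parameters) cannot represent the generating
mechanism exactly and underperforms Standard LTR on these cohorts — a
property of the synthetic design, not evidence about real data. Passing
tests demonstrate correctness of the machinery and recoverability under
the stated conditions, not clinical performance.

## Study conditions

* **Parameter recovery** — M = 50 codes in 10 groups, 1000 patients / 2000
  pairs, sparsity 0.4, code_rate 8 (so nearly every visit carries signal),
  flip noise 0.05; fit with λ = 1e-3, lr 0.05, validation fraction 0.15,
  patience 60, 6 restarts averaged. Measured: cosine ≥ 0.9 between fitted
  and generating code weights and held-out AUC ≥ 0.9, per seed.
* **Interpretation recovery** — explicit truth with exactly five dominant
  positive weights (9.0 … 6.6) and five smaller negative ones; moderate
  scale and low group fidelity 0.3, because per-code weight estimation
  needs probabilities off the saturated region (where cross-entropy
  carries little per-code Fisher information) and weak co-occurrence
  confounding; λ = 3e-3 shrinks null-code noise below the top-weight gaps.
  Measured: the importance report's top five equal the truth's five
  positive codes.
* **Model comparison / transfer** — default-condition cohorts; the
  comparison study fixes the embedding to the generating matrix so it
  isolates classifier differences (embedding quality is measured
  separately by the pair-classification AUC).

## Numerical choices

Logit clamp ±30; probabilities implicitly bounded by the clamp; loss from
logits via logaddexp (no cancellation at confident predictions);
classification threshold 0.5; L1 subgradient 0 at 0; proximal threshold
uses Adam's per-coordinate step scale; cosine pairs involving a zero vector
are excluded from embedding evaluation (cosine undefined); codes with zero
presence variance get Pearson r = 0 by convention; importance-report ties
break by weight, then patient count, then code string. All randomness flows
through named integer seeds; repeated runs are byte-identical.

## Known limitations

Two-visit pairs only (no longer histories); no code-hierarchy or
cross-category interaction modeling; word2vec is a small-corpus
single-threaded implementation (adequate for the cohort sizes here, not
for millions of visits); grid search is exhaustive over small grids;
Cohen's D is the only significance-style comparison; the generator's
group structure is flat (one group per code).
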
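"""Patient-wise cross-validation, baselines, weight transfer, metrics.

All data splitting is patient-wise: every sample of a patient lands in the
same fold, preventing leakage between paired visits of the same patient. A
fraction of patients (default 0.2) is held out entirely; the remainder is
partitioned into k stratified folds (stratified on the patient-level label:
positive if any of the patient's pairs is positive). Each CV iteration
trains on k-1 folds and evaluates on the held-out fold.

Baselines (logistic regression, linear SVM, Gaussian naive Bayes, random
forest) consume a (D+d)-vector per sample: the mean over all M rows of the
stacked code matrix (zeros included) concatenated with the labs. Weight
transfer replaces that unweighted mean with the aggregation
sum_m weight_m X[m, :], where the weights are the global u of a Standard
LTR fit (or the per-sample u_i = X_i w of a Personalized fit) trained on
the same training fold.

Metrics: accuracy and F1 = 2TP / (FN + 2TP + FP) at threshold 0.5, AUC
(midrank tie handling) and AUPRC (step integration). Model comparison uses
Cohen's D on the fold AUCs with the pooled-SD formula.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .code_embedding import CodeEmbedding, SampleTensor, build_sample_tensor
from .exceptions import DegenerateInputError, InvalidArgumentError
from .ltr_models import PersonalizedLTRParams, StandardLTRParams, predict_proba
from .synthetic_cohort import Cohort
from .temporal_encoding import apply_pe
from .training import TrainConfig, fit

LTR_MODELS = ("s-ltr", "p-ltr")
BASELINE_MODELS = ("lr", "svm", "nb", "rf")
ALL_MODELS = LTR_MODELS + BASELINE_MODELS


@dataclass
class FoldPlan:
    """A patient-wise split: a test holdout plus k disjoint CV folds."""

    test_holdout: set
    folds: list  # list of sets of patient ids

    def validate(self, cohort: Cohort) -> None:
        groups = [self.test_holdout] + list(self.folds)
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                inter = groups[i] & groups[j]
                if inter:
                    raise InvalidArgumentError(f"patient overlap between folds: {inter}")
        union = set().union(*groups)
        if union != set(cohort.patient_ids):
            raise InvalidArgumentError("folds + holdout must cover all patients")


def make_fold_plan(
    cohort: Cohort, k: int = 10, test_ratio: float = 0.2, seed: int = 0
) -> FoldPlan:
    """Stratified patient-wise plan: ``test_ratio`` holdout, then k folds."""
    if not 0 <= test_ratio < 1:
        raise InvalidArgumentError("test_ratio must be in [0, 1)")
    plab = cohort.patient_labels()
    pids = sorted(plab)
    rng = np.random.default_rng(seed)

    holdout: set = set()
    if test_ratio > 0:
        for cls in (0, 1):
            cls_pids = [p for p in pids if plab[p] == cls]
            n_hold = int(round(test_ratio * len(cls_pids)))
            holdout.update(rng.permutation(cls_pids)[:n_hold].tolist())
    remaining = [p for p in pids if p not in holdout]
    y = np.array([plab[p] for p in remaining])
    if k > len(remaining):
        raise InvalidArgumentError("k exceeds number of available patients")
    if min((y == 0).sum(), (y == 1).sum()) < k:
        raise DegenerateInputError("too few patients per class for k folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [
        {remaining[i] for i in test_idx}
        for _, test_idx in skf.split(np.zeros(len(remaining)), y)
    ]
    plan = FoldPlan(test_holdout=holdout, folds=folds)
    plan.validate(cohort)
    return plan


# ---------------------------------------------------------------------------
# feature construction for baselines


def pooled_features(sample: SampleTensor) -> np.ndarray:
    """Global pooling over the code axis: mean of all M rows (zeros included)
    concatenated with the labs; a (D+d)-vector."""
    return np.concatenate([sample.X.mean(axis=0), sample.x])


def pooled_features_nonzero(sample: SampleTensor) -> np.ndarray:
    """Variant: mean over the nonzero (present-code) rows only."""
    k = max(len(sample.code_indices), 1)
    return np.concatenate([sample.X.sum(axis=0) / k, sample.x])


def weighted_features(sample: SampleTensor, code_weights: np.ndarray) -> np.ndarray:
    """Weighted aggregation sum_m w_m X[m,:] concatenated with labs."""
    code_weights = np.asarray(code_weights, dtype=float)
    if code_weights.shape != (sample.X.shape[0],):
        raise InvalidArgumentError("code_weights length must equal M")
    if not np.all(np.isfinite(code_weights)):
        raise InvalidArgumentError("code_weights must be finite")
    return np.concatenate([code_weights @ sample.X, sample.x])


# ---------------------------------------------------------------------------
# metrics


def confusion_counts(y_true, y_pred) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return tp, tn, fp, fn


def metrics(y_true, y_score, threshold: float = 0.5) -> dict:
    """accuracy, F1 (2TP/(FN+2TP+FP)), AUC, AUPRC for one evaluation set."""
    y_true = np.asarray(y_true).astype(int)
    y_score = np.asarray(y_score, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise DegenerateInputError("AUC/AUPRC undefined for single-class truth")
    y_pred = (y_score >= threshold).astype(int)
    tp, tn, fp, fn = confusion_counts(y_true, y_pred)
    acc = (tp + tn) / len(y_true)
    f1 = 2 * tp / (fn + 2 * tp + fp) if (fn + 2 * tp + fp) > 0 else 0.0
    return {
        "accuracy": float(acc),
        "f1": float(f1),
        "auc": float(roc_auc_score(y_true, y_score)),
        "auprc": float(average_precision_score(y_true, y_score)),
    }


def cohens_d(a, b) -> float:
    """Standardized mean difference (mean_a - mean_b) / pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidArgumentError("need >=2 values per group")
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        if a.mean() == b.mean():
            return 0.0
        raise DegenerateInputError("zero pooled SD with unequal means")
    return float((a.mean() - b.mean()) / pooled)


def effect_size_label(d: float) -> str:
    """Conventional interpretation: >=0.8 large, 0.5-0.8 moderate, else small."""
    ad = abs(d)
    if ad >= 0.8:
        return "large"
    if ad >= 0.5:
        return "moderate"
    return "small"


# ---------------------------------------------------------------------------
# cross-validated comparison


@dataclass
class EvalReport:
    per_fold: pd.DataFrame                  # columns: model, fold, accuracy..auprc
    summary: pd.DataFrame                   # mean/std per model/metric
    cohens_d: dict                          # {(model_a, model_b): d on AUC}
    holdout: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "per_fold": self.per_fold.to_dict(orient="records"),
            "summary": self.summary.to_dict(orient="records"),
            "cohens_d": {f"{a}|{b}": v for (a, b), v in self.cohens_d.items()},
            "holdout": self.holdout,
            "skipped": self.skipped,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    def to_tsv(self, path) -> None:
        self.summary.to_csv(path, sep="\t", index=False, float_format="%.4f")


def _lab_stats_from(samples: list) -> tuple[np.ndarray, np.ndarray]:
    labs = np.stack([np.asarray(s.labs, dtype=float) for s in samples])
    sd = labs.std(axis=0)
    sd[sd == 0] = 1.0
    return labs.mean(axis=0), sd


def build_tensors(
    cohort: Cohort,
    emb: CodeEmbedding,
    indices: list[int],
    lab_stats: tuple,
    pe_mode: str = "multiplicative",
) -> list[SampleTensor]:
    """PE-applied, lab-standardized tensors for the given sample indices."""
    return [
        apply_pe(
            build_sample_tensor(cohort.samples[i], emb, lab_stats=lab_stats),
            mode=pe_mode,
        )
        for i in indices
    ]


def _baseline_estimator(name: str, seed: int):
    if name == "lr":
        return LogisticRegression(max_iter=2000)
    if name == "svm":
        return SVC(kernel="linear")  # decision_function scores; no Platt scaling
    if name == "nb":
        return GaussianNB()
    if name == "rf":
        return RandomForestClassifier(random_state=seed)
    raise InvalidArgumentError(f"unknown baseline {name!r}")


def _baseline_scores(est, F_train, y_train, F_test) -> np.ndarray:
    est.fit(F_train, y_train)
    if hasattr(est, "predict_proba"):
        return est.predict_proba(F_test)[:, 1]
    # margin scores mapped through a sigmoid only to land in (0,1); ranking
    # (AUC/AUPRC) is unaffected and 0.5 corresponds to the margin threshold 0
    z = est.decision_function(F_test)
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))


def run_cv(
    cohort: Cohort,
    emb: CodeEmbedding,
    models: tuple = ALL_MODELS,
    plan: FoldPlan | None = None,
    transfer: str = "none",
    train_cfg: TrainConfig | None = None,
    seed: int = 0,
    pe_mode: str = "multiplicative",
) -> EvalReport:
    """Cross-validated comparison of LTR models and pooled-feature baselines.

    ``transfer`` switches the baselines' code aggregation: "none" = unweighted
    mean pooling, "standard"/"personalized" = aggregation weighted by the code
    weights of the corresponding LTR model fit on the same training fold. The
    0.2 patient holdout of the plan is evaluated once, at the end, with models
    trained on all CV patients.
    """
    if transfer not in ("none", "standard", "personalized"):
        raise InvalidArgumentError(f"unknown transfer mode {transfer!r}")
    models = tuple(m.lower() for m in models)
    for m in models:
        if m not in ALL_MODELS:
            raise InvalidArgumentError(f"unknown model {m!r}")
    plan = plan or make_fold_plan(cohort, seed=seed)
    plan.validate(cohort)
    cfg = train_cfg or TrainConfig(seed=seed)

    sample_pids = cohort.patient_ids
    rows = []
    skipped = []
    for fold_id, test_pids in enumerate(plan.folds):
        train_pids = set().union(*(f for j, f in enumerate(plan.folds) if j != fold_id))
        tr_idx = [i for i, p in enumerate(sample_pids) if p in train_pids]
        te_idx = [i for i, p in enumerate(sample_pids) if p in test_pids]
        assert not (set(sample_pids[i] for i in tr_idx) & set(sample_pids[i] for i in te_idx))
        y_tr = cohort.labels[tr_idx]
        y_te = cohort.labels[te_idx]
        if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
            skipped.append({"fold": fold_id, "reason": "single-class train or test"})
            warnings.warn(f"fold {fold_id} skipped: single-class data")
            continue
        fold_rows = _eval_fold(
            cohort, emb, models, transfer, cfg, tr_idx, te_idx, y_tr, y_te, pe_mode
        )
        for r in fold_rows:
            r["fold"] = fold_id
            rows.append(r)

    per_fold = pd.DataFrame(rows)
    summary_rows = []
    for m in models:
        sub = per_fold[per_fold["model"] == m]
        row = {"model": m}
        for met in ("accuracy", "f1", "auc", "auprc"):
            row[f"{met}_mean"] = float(sub[met].mean())
            row[f"{met}_std"] = float(sub[met].std(ddof=1)) if len(sub) > 1 else 0.0
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)

    dvals = {}
    for ref in LTR_MODELS:
        if ref not in models:
            continue
        ref_auc = per_fold[per_fold["model"] == ref]["auc"].to_numpy()
        for m in models:
            if m == ref:
                continue
            m_auc = per_fold[per_fold["model"] == m]["auc"].to_numpy()
            if len(ref_auc) >= 2 and len(m_auc) >= 2:
                try:
                    dvals[(ref, m)] = cohens_d(ref_auc, m_auc)
                except DegenerateInputError:
                    pass

    holdout: dict = {}
    if plan.test_holdout:
        cv_pids = set().union(*plan.folds)
        tr_idx = [i for i, p in enumerate(sample_pids) if p in cv_pids]
        te_idx = [i for i, p in enumerate(sample_pids) if p in plan.test_holdout]
        y_tr, y_te = cohort.labels[tr_idx], cohort.labels[te_idx]
        if len(np.unique(y_tr)) == 2 and len(np.unique(y_te)) == 2:
            for r in _eval_fold(
                cohort, emb, models, transfer, cfg, tr_idx, te_idx, y_tr, y_te, pe_mode
            ):
                holdout[r.pop("model")] = r

    return EvalReport(
        per_fold=per_fold,
        summary=summary,
        cohens_d=dvals,
        holdout=holdout,
        skipped=skipped,
    )


def _eval_fold(cohort, emb, models, transfer, cfg, tr_idx, te_idx, y_tr, y_te, pe_mode):
    lab_stats = _lab_stats_from([cohort.samples[i] for i in tr_idx])
    T_tr = build_tensors(cohort, emb, tr_idx, lab_stats, pe_mode)
    T_te = build_tensors(cohort, emb, te_idx, lab_stats, pe_mode)

    rows = []
    fits: dict[str, object] = {}
    need_standard = "s-ltr" in models or transfer == "standard"
    need_pers = "p-ltr" in models or transfer == "personalized"
    if need_standard:
        fits["standard"] = fit("standard", T_tr, cfg)
    if need_pers:
        fits["personalized"] = fit("personalized", T_tr, cfg)

    if "s-ltr" in models:
        p = predict_proba(fits["standard"].params, T_te)
        rows.append({"model": "s-ltr", **metrics(y_te, p)})
    if "p-ltr" in models:
        p = predict_proba(fits["personalized"].params, T_te)
        rows.append({"model": "p-ltr", **metrics(y_te, p)})

    baselines = [m for m in models if m in BASELINE_MODELS]
    if baselines:
        if transfer == "none":
            F_tr = np.stack([pooled_features(s) for s in T_tr])
            F_te = np.stack([pooled_features(s) for s in T_te])
        elif transfer == "standard":
            u = fits["standard"].params.u
            F_tr = np.stack([weighted_features(s, u) for s in T_tr])
            F_te = np.stack([weighted_features(s, u) for s in T_te])
        else:  # personalized: input-dependent weights u_i = X_i w
            w = fits["personalized"].params.w
            F_tr = np.stack([weighted_features(s, s.X @ w) for s in T_tr])
            F_te = np.stack([weighted_features(s, s.X @ w) for s in T_te])
        for name in baselines:
            est = _baseline_estimator(name, seed=cfg.seed)
            scores = _baseline_scores(est, F_tr, y_tr, F_te)
            rows.append({"model": name, **metrics(y_te, scores)})
    return rows
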
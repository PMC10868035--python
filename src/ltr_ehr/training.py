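"""Model fitting: Adam, Kaiming-uniform init, early stopping, grid search.

Training is full-batch by default (cohorts here are a few hundred to a few
thousand samples), with an optional mini-batch mode. Parameters are
initialized Kaiming-uniform, U(-sqrt(6/fan_in), +sqrt(6/fan_in)) with fan_in
the parameter's input dimension (M for u, D for w, D+d for v and b). Early
stopping watches a patient-wise validation split when ``val_fraction > 0``
and the training objective otherwise. Hyperparameters (learning rate, L1
strength lambda) are chosen by exhaustive grid search with validation AUC as
the selection metric, ties broken toward smaller lambda then smaller lr, and
a final refit on the full training data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import roc_auc_score

from .code_embedding import SampleTensor
from .exceptions import DegenerateInputError, InvalidArgumentError
from .ltr_models import (
    Batch,
    LossConfig,
    PersonalizedLTRParams,
    StandardLTRParams,
    _batch_logits,
    canonicalize_orientation,
    gradient,
    loss,
    predict_proba,
    sigmoid,
)


@dataclass
class TrainConfig:
    lr: float = 1e-2
    lam: float = 0.0
    max_steps: int = 5000
    patience: int = 20              # evaluations without improvement before stop
    eval_every: int = 25
    val_fraction: float = 0.1
    seed: int = 0
    batch_size: int | None = None   # None = full batch
    n_restarts: int = 1             # random restarts; best monitored loss wins
    output: str = "sigmoid"
    lr_grid: list = field(default_factory=lambda: [1e-3, 1e-2])
    lambda_grid: list = field(default_factory=lambda: [0.0, 1e-3, 1e-2, 1e-1])

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.max_steps < 1:
            raise InvalidArgumentError("lr must be > 0 and max_steps >= 1")
        if not self.lr_grid or not self.lambda_grid:
            raise InvalidArgumentError("grids must be non-empty")
        if not 0 <= self.val_fraction < 1:
            raise InvalidArgumentError("val_fraction must be in [0, 1)")


@dataclass
class FitResult:
    params: StandardLTRParams | PersonalizedLTRParams
    history: np.ndarray             # per-step training objective
    chosen_hparams: dict
    model_kind: str
    val_history: list = field(default_factory=list)  # (step, val objective)
    val_auc: float | None = None    # AUC of the returned params on the val split
    search_log: list = field(default_factory=list)   # grid-search audit rows


def kaiming_uniform(fan_in: int, size, rng: np.random.Generator) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=size)


def _init_params(model_kind: str, M: int, D: int, d: int, rng: np.random.Generator):
    v = kaiming_uniform(D + d, D + d, rng)
    b = float(kaiming_uniform(D + d, (), rng))
    if model_kind == "standard":
        return StandardLTRParams(u=kaiming_uniform(M, M, rng), v=v, b=b)
    if model_kind == "personalized":
        return PersonalizedLTRParams(w=kaiming_uniform(D, D, rng), v=v, b=b)
    raise InvalidArgumentError(f"unknown model kind {model_kind!r}")


class _Adam:
    """Adam over a list of same-shaped parameter arrays."""

    def __init__(self, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params_list, grads_list):
        self.t += 1
        out = []
        for i, (p, g) in enumerate(zip(params_list, grads_list)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            out.append(p - self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out

    def effective_step(self, i: int) -> np.ndarray:
        """Per-coordinate step scale lr/(sqrt(vhat)+eps) for parameter i."""
        vhat = self.v[i] / (1 - self.b2**self.t)
        return self.lr / (np.sqrt(vhat) + self.eps)


def _unpack(params):
    if isinstance(params, StandardLTRParams):
        return [params.u, params.v, np.array(params.b)]
    return [params.w, params.v, np.array(params.b)]


def _repack(params, arrays):
    if isinstance(params, StandardLTRParams):
        return StandardLTRParams(u=arrays[0], v=arrays[1], b=float(arrays[2]))
    return PersonalizedLTRParams(w=arrays[0], v=arrays[1], b=float(arrays[2]))


def _patient_val_split(samples, val_fraction, rng):
    """Patient-wise validation split, stratified on patient-level label."""
    by_pid: dict[str, list[int]] = {}
    for i, s in enumerate(samples):
        by_pid.setdefault(s.patient_id or f"_anon{i}", []).append(i)
    pids = sorted(by_pid)
    plab = {p: max(samples[i].y for i in by_pid[p]) for p in pids}
    val_pids: set[str] = set()
    for cls in (0, 1):
        cls_pids = [p for p in pids if plab[p] == cls]
        n_val = int(round(val_fraction * len(cls_pids)))
        if n_val and len(cls_pids) > n_val:
            val_pids.update(rng.permutation(cls_pids)[:n_val].tolist())
    val_idx = [i for p in val_pids for i in by_pid[p]]
    train_idx = [i for i in range(len(samples)) if i not in set(val_idx)]
    return train_idx, sorted(val_idx)


def fit(
    model_kind: str,
    samples: list[SampleTensor],
    cfg: TrainConfig | None = None,
) -> FitResult:
    """Fit one LTR model on PE-applied sample tensors.

    Deterministic per ``cfg.seed``. Returns the parameters from the best
    validation evaluation (canonically oriented), the per-step training
    objective, and the hyperparameters used.

    The bilinear logit makes the objective non-convex and some
    initializations converge to clearly inferior stationary points;
    ``cfg.n_restarts > 1`` reruns the optimization from fresh Kaiming draws
    (derived deterministically from ``cfg.seed``) and keeps the best run.
    Restarts are ranked by validation AUC when a validation split exists
    (discrimination tracks the generating signal more reliably than
    cross-entropy, which is sensitive to calibration under label noise) and
    by the final training objective otherwise.
    """
    cfg = cfg or TrainConfig()
    if cfg.n_restarts > 1:
        best = None
        for r in range(cfg.n_restarts):
            sub_cfg = replace(cfg, n_restarts=1,
                              seed=int((cfg.seed + 7919 * r) % (2**31 - 1)))
            res = _fit_once(model_kind, samples, sub_cfg)
            score = (-res.val_auc if res.val_auc is not None
                     else res.history[-1])
            if best is None or score < best[0]:
                best = (score, res)
        return best[1]
    return _fit_once(model_kind, samples, cfg)


def _fit_once(
    model_kind: str,
    samples: list[SampleTensor],
    cfg: TrainConfig,
) -> FitResult:
    y = np.array([s.y for s in samples])
    if len(np.unique(y)) < 2 or min((y == 0).sum(), (y == 1).sum()) < 2:
        raise DegenerateInputError("need >=2 samples in each class")
    rng = np.random.default_rng(cfg.seed)
    M, D = samples[0].X.shape
    d = samples[0].x.shape[0]

    if cfg.val_fraction > 0:
        tr_idx, va_idx = _patient_val_split(samples, cfg.val_fraction, rng)
        if not va_idx or len(np.unique(y[tr_idx])) < 2:
            tr_idx, va_idx = list(range(len(samples))), []
    else:
        tr_idx, va_idx = list(range(len(samples))), []
    train_batch = Batch.from_samples([samples[i] for i in tr_idx])
    val_batch = Batch.from_samples([samples[i] for i in va_idx]) if va_idx else None

    params = _init_params(model_kind, M, D, d, rng)
    lcfg = LossConfig(lambda_l1=cfg.lam)
    adam = _Adam([a.shape for a in _unpack(params)], lr=cfg.lr)

    history = []
    val_history = []
    best = (np.inf, params.copy(), 0)
    bad_evals = 0
    N = len(train_batch)
    for step in range(cfg.max_steps):
        if cfg.batch_size is not None and cfg.batch_size < N:
            idx = rng.choice(N, size=cfg.batch_size, replace=False)
            sub = Batch(X=train_batch.X[idx], labs=train_batch.labs[idx], y=train_batch.y[idx])
        else:
            sub = train_batch
        # proximal treatment of the L1 term: Adam steps on the smooth
        # cross-entropy gradient, then the code-weight block is
        # soft-thresholded by lambda times the per-coordinate step scale.
        # This yields exact zeros, which plain subgradient steps do not.
        g = gradient(params, sub, LossConfig(0.0))
        arrays = adam.step(_unpack(params), _unpack(g))
        if cfg.lam > 0:
            thresh = cfg.lam * adam.effective_step(0)
            arrays[0] = np.sign(arrays[0]) * np.maximum(np.abs(arrays[0]) - thresh, 0.0)
        params = _repack(params, arrays)
        history.append(loss(params, train_batch, lcfg))
        if (step + 1) % cfg.eval_every == 0:
            monitor = (
                loss(params, val_batch, LossConfig(0.0))
                if val_batch is not None
                else history[-1]
            )
            val_history.append((step + 1, monitor))
            if monitor < best[0] - 1e-9:
                best = (monitor, params.copy(), step + 1)
                bad_evals = 0
            else:
                bad_evals += 1
                if bad_evals >= cfg.patience:
                    break
    if val_history:
        params = best[1]

    val_auc = None
    if val_batch is not None and len(np.unique(val_batch.y)) == 2:
        val_auc = float(
            roc_auc_score(val_batch.y, sigmoid(_batch_logits(params, val_batch)))
        )

    if isinstance(params, StandardLTRParams):
        params.u, params.v = canonicalize_orientation(params.u, params.v, D)
    else:
        params.w, params.v = canonicalize_orientation(params.w, params.v, D)
    return FitResult(
        params=params,
        history=np.array(history),
        chosen_hparams={"lr": cfg.lr, "lambda": cfg.lam},
        model_kind=model_kind,
        val_history=val_history,
        val_auc=val_auc,
    )


def fit_averaged(
    model_kind: str,
    samples: list[SampleTensor],
    cfg: TrainConfig | None = None,
    auc_tolerance: float = 0.05,
    align_threshold: float = 0.6,
) -> FitResult:
    """Multi-start fit with restart averaging.

    Runs ``cfg.n_restarts`` independent fits, screens out inferior
    stationary points (validation AUC more than ``auc_tolerance`` below the
    best, or code-weight direction nearly orthogonal to the best run — the
    non-convex objective's spurious optima are near-orthogonal to the good
    family), resolves the per-restart scale/sign ambiguity by normalizing
    the code weights to unit norm (rescaling v[:D] to compensate, which
    leaves predictions unchanged), and averages the aligned parameter
    vectors. Averaging k noisy estimates of the same direction shrinks the
    direction error roughly by sqrt(k).
    """
    cfg = cfg or TrainConfig()
    k = max(cfg.n_restarts, 2)
    runs = []
    for r in range(k):
        sub_cfg = replace(cfg, n_restarts=1,
                          seed=int((cfg.seed + 7919 * r) % (2**31 - 1)))
        runs.append(_fit_once(model_kind, samples, sub_cfg))
    if any(r.val_auc is None for r in runs):
        raise DegenerateInputError("fit_averaged needs a validation split")
    best = max(runs, key=lambda r: r.val_auc)

    def weights_of(res):
        return res.params.u if model_kind == "standard" else res.params.w

    D = samples[0].X.shape[1]
    ref = weights_of(best)
    ref = ref / np.linalg.norm(ref)
    ws, vDs, vds, bs, kept = [], [], [], [], []
    for res in runs:
        if res.val_auc < best.val_auc - auc_tolerance:
            continue
        w = weights_of(res)
        norm = np.linalg.norm(w)
        if norm == 0:
            continue
        unit = w / norm
        align = float(unit @ ref)
        if abs(align) < align_threshold:
            continue
        sign = 1.0 if align >= 0 else -1.0
        ws.append(sign * unit)
        vDs.append(sign * res.params.v[:D] * norm)
        vds.append(res.params.v[D:])
        bs.append(res.params.b)
        kept.append(res)
    w_avg = np.mean(ws, axis=0)
    v_avg = np.concatenate([np.mean(vDs, axis=0), np.mean(vds, axis=0)])
    b_avg = float(np.mean(bs))
    w_avg, v_avg = canonicalize_orientation(w_avg, v_avg, D)
    if model_kind == "standard":
        params = StandardLTRParams(u=w_avg, v=v_avg, b=b_avg)
    else:
        params = PersonalizedLTRParams(w=w_avg, v=v_avg, b=b_avg)
    return FitResult(
        params=params,
        history=best.history,
        chosen_hparams={**best.chosen_hparams, "restarts_kept": len(kept)},
        model_kind=model_kind,
        val_history=best.val_history,
        val_auc=best.val_auc,
    )


def grid_search(
    model_kind: str,
    samples: list[SampleTensor],
    cfg: TrainConfig | None = None,
) -> FitResult:
    """Exhaustive (lr, lambda) grid search selected by validation AUC.

    Every grid cell is fit on a patient-wise internal split; the winner
    (ties: smaller lambda, then smaller lr) is refit on the full data.
    """
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    val_fraction = cfg.val_fraction if cfg.val_fraction > 0 else 0.2
    tr_idx, va_idx = _patient_val_split(samples, val_fraction, rng)
    y_val = np.array([samples[i].y for i in va_idx])
    if not va_idx or len(np.unique(y_val)) < 2:
        raise DegenerateInputError("validation split lacks both classes")
    train = [samples[i] for i in tr_idx]
    val_batch = Batch.from_samples([samples[i] for i in va_idx])

    log = []
    best_key = None
    best_cell = None
    for lam in cfg.lambda_grid:
        for lr in cfg.lr_grid:
            cell_cfg = replace(cfg, lr=lr, lam=lam, val_fraction=0.0)
            res = fit(model_kind, train, cell_cfg)
            auc = float(roc_auc_score(y_val, predict_proba(res.params, val_batch)))
            log.append({"lr": lr, "lambda": lam, "val_auc": auc})
            # maximize AUC; ties -> smaller lambda, then smaller lr
            key = (-auc, lam, lr)
            if best_key is None or key < best_key:
                best_key, best_cell = key, (lr, lam)
    lr, lam = best_cell
    final = fit(model_kind, samples, replace(cfg, lr=lr, lam=lam))
    final.chosen_hparams = {"lr": lr, "lambda": lam}
    final.search_log = log
    return final


def training_accuracy(result: FitResult, samples: list[SampleTensor]) -> float:
    p = predict_proba(result.params, samples)
    y = np.array([s.y for s in samples])
    return float(np.mean((p >= 0.5).astype(int) == y))
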
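"""Standard and Personalized logistic tensor regression.

Both models classify a paired-visit sample represented by a stacked code
matrix X in R^{M x D} (PE-scaled), a lab vector x in R^d, and produce a
probability through a sigmoid of a bilinear logit.

Standard LTR
    logit = [u^T X | x^T] v + b,  u in R^M global code weights,
    v in R^{D+d}, b in R. u_m measures the population-level importance of
    code m.

Personalized LTR
    Replaces the M-dimensional u with an embedding-space weight w in R^D
    acting through the sample Gram matrix S = X^T X:
    logit = [w^T S | x^T] v + b. Since w^T X^T X = (X w)^T X, this is the
    Standard model with per-sample code weights u_i = X_i w — an attention
    mechanism whose weights vary by patient while depending on only D
    parameters.

Training minimizes mean binary cross-entropy plus an L1 penalty on the code
weight (u, resp. w), which pushes the model to concentrate on a small number
of codes. Logits are clamped to |logit| <= 30 and the cross-entropy is
evaluated stably from logits (softplus form), so probabilities never reach
0 or 1 inside a log; gradients are analytic, with the sign subgradient
(0 at 0) for the L1 term.

The bilinear form is scale/sign non-identifiable: (u, v[:D]) -> (alpha u,
v[:D]/alpha) leaves every logit unchanged for any alpha != 0. Parameters
are therefore reported in a canonical orientation (see
:func:`canonicalize_orientation`), which changes no prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .code_embedding import SampleTensor
from .exceptions import InvalidArgumentError

LOGIT_CLAMP = 30.0


@dataclass
class StandardLTRParams:
    u: np.ndarray  # (M,) code weights
    v: np.ndarray  # (D+d,)
    b: float

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise InvalidArgumentError("parameters must be finite")

    def copy(self) -> "StandardLTRParams":
        return StandardLTRParams(self.u.copy(), self.v.copy(), float(self.b))


@dataclass
class PersonalizedLTRParams:
    w: np.ndarray  # (D,) embedding-space weights
    v: np.ndarray  # (D+d,)
    b: float

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if not (np.all(np.isfinite(self.w)) and np.all(np.isfinite(self.v))):
            raise InvalidArgumentError("parameters must be finite")

    def copy(self) -> "PersonalizedLTRParams":
        return PersonalizedLTRParams(self.w.copy(), self.v.copy(), float(self.b))


@dataclass
class LossConfig:
    """lambda_l1 scales the L1 penalty on the code-weight parameter."""

    lambda_l1: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda_l1 < 0:
            raise InvalidArgumentError("lambda_l1 must be >= 0")


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -LOGIT_CLAMP, LOGIT_CLAMP)))


def canonicalize_orientation(weights: np.ndarray, v: np.ndarray, D: int):
    """Canonical orientation: flip (weights, v[:D]) jointly so that the
    signed energy of the code weights, sum_m w_m |w_m|, is positive (no-op
    when it is exactly zero).

    ``weights`` is the code-weight parameter (u for Standard, w for
    Personalized). The anchor is odd under the sign half of the
    non-identifiability, (weights, v[:D]) -> (-weights, -v[:D]), so two
    parameter vectors related by that flip always canonicalize identically.
    Squaring the magnitudes makes the anchor dominated by the few large
    weights and insensitive to the many near-zero ones. A pure reporting
    convention — predictions are unchanged."""
    weights, v = np.array(weights, dtype=float), np.array(v, dtype=float)
    if np.sum(weights * np.abs(weights)) < 0:
        weights = -weights
        v = v.copy()
        v[:D] = -v[:D]
    return weights, v


# backwards-compatible alias used by the cohort generator
canonicalize_standard = canonicalize_orientation


# ---------------------------------------------------------------------------
# forward models


def _check_dims_standard(params: StandardLTRParams, sample: SampleTensor) -> int:
    M, D = sample.X.shape
    d = sample.x.shape[0]
    if params.u.shape != (M,) or params.v.shape != (D + d,):
        raise InvalidArgumentError(
            f"dimension mismatch: u{params.u.shape}, v{params.v.shape} "
            f"vs X({M},{D}), x({d},)"
        )
    return D


def logit_standard(params: StandardLTRParams, sample: SampleTensor) -> float:
    D = _check_dims_standard(params, sample)
    return float(
        params.u @ (sample.X @ params.v[:D]) + sample.x @ params.v[D:] + params.b
    )


def forward_standard(params: StandardLTRParams, sample: SampleTensor) -> float:
    """P(y=1) = sigmoid([u^T X | x^T] v + b)."""
    return float(sigmoid(logit_standard(params, sample)))


def _check_dims_personalized(params: PersonalizedLTRParams, sample: SampleTensor) -> int:
    M, D = sample.X.shape
    d = sample.x.shape[0]
    if params.w.shape != (D,) or params.v.shape != (D + d,):
        raise InvalidArgumentError(
            f"dimension mismatch: w{params.w.shape}, v{params.v.shape} "
            f"vs X({M},{D}), x({d},)"
        )
    return D


def personalized_code_weights(
    params: PersonalizedLTRParams, sample: SampleTensor
) -> np.ndarray:
    """Per-patient code weights u_i = X_i w (length M, zero at absent codes)."""
    _check_dims_personalized(params, sample)
    return sample.X @ params.w


def logit_personalized(
    params: PersonalizedLTRParams, sample: SampleTensor, via: str = "gram"
) -> float:
    """Logit via the Gram form w^T (X^T X) or the attention form (X w)^T X.

    The two are algebraically identical; both routes are exposed so the
    identity can be verified numerically.
    """
    D = _check_dims_personalized(params, sample)
    vD, vd = params.v[:D], params.v[D:]
    if via == "gram":
        S = sample.X.T @ sample.X
        core = params.w @ S @ vD
    elif via == "attention":
        u_i = sample.X @ params.w
        core = u_i @ (sample.X @ vD)
    else:
        raise InvalidArgumentError(f"unknown route: {via!r}")
    return float(core + sample.x @ vd + params.b)


def forward_personalized(
    params: PersonalizedLTRParams,
    sample: SampleTensor,
    via: str = "gram",
    output: str = "sigmoid",
) -> float:
    """P(y=1) for the Personalized model.

    ``output="sigmoid"`` (default) maps the logit through the logistic
    function; ``output="tanh"`` applies tanh and affinely rescales
    (tanh+1)/2 into (0,1).
    """
    z = logit_personalized(params, sample, via=via)
    if output == "sigmoid":
        return float(sigmoid(z))
    if output == "tanh":
        return float((np.tanh(z) + 1.0) / 2.0)
    raise InvalidArgumentError(f"unknown output nonlinearity: {output!r}")


def forward(params, sample: SampleTensor) -> float:
    if isinstance(params, StandardLTRParams):
        return forward_standard(params, sample)
    if isinstance(params, PersonalizedLTRParams):
        return forward_personalized(params, sample)
    raise InvalidArgumentError("unknown parameter type")


# ---------------------------------------------------------------------------
# batched loss and gradient


@dataclass
class Batch:
    """Stacked arrays for full-batch training."""

    X: np.ndarray      # (N, M, D)
    labs: np.ndarray   # (N, d)
    y: np.ndarray      # (N,) in {0, 1}

    @classmethod
    def from_samples(cls, samples: list[SampleTensor]) -> "Batch":
        if not samples:
            raise InvalidArgumentError("empty batch")
        X = np.stack([s.X for s in samples])
        labs = np.stack([s.x for s in samples])
        y = np.array([s.y for s in samples], dtype=float)
        return cls(X=X, labs=labs, y=y)

    def __len__(self) -> int:
        return len(self.y)


def _batch_logits(params, batch: Batch) -> np.ndarray:
    D = batch.X.shape[2]
    vD, vd = params.v[:D], params.v[D:]
    if isinstance(params, StandardLTRParams):
        XvD = batch.X @ vD                      # (N, M)
        core = XvD @ params.u
    else:
        XvD = batch.X @ vD                      # (N, M)
        Xw = batch.X @ params.w                 # (N, M) = per-sample u_i
        core = np.einsum("nm,nm->n", Xw, XvD)
    return core + batch.labs @ vd + params.b


def predict_proba(params, samples_or_batch) -> np.ndarray:
    batch = (
        samples_or_batch
        if isinstance(samples_or_batch, Batch)
        else Batch.from_samples(list(samples_or_batch))
    )
    return sigmoid(_batch_logits(params, batch))


def _code_weight_vector(params) -> np.ndarray:
    return params.u if isinstance(params, StandardLTRParams) else params.w


def loss(params, batch, cfg: LossConfig = LossConfig()) -> float:
    """Mean binary cross-entropy + lambda * ||code weights||_1.

    Labels are stored as {0,1}; the {-1,+1} convention appearing in the
    logistic-loss formulation log(1+exp(-y*logit)) is algebraically the same
    cross-entropy and is handled at this boundary.
    """
    if not isinstance(batch, Batch):
        batch = Batch.from_samples(list(batch))
    z = np.clip(_batch_logits(params, batch), -LOGIT_CLAMP, LOGIT_CLAMP)
    # stable cross-entropy from logits: -[y log p + (1-y) log(1-p)]
    # = softplus(z) - y z; avoids cancellation in 1-p at confident logits
    ce = np.mean(np.logaddexp(0.0, z) - batch.y * z)
    return float(ce + cfg.lambda_l1 * np.abs(_code_weight_vector(params)).sum())


def gradient(params, batch, cfg: LossConfig = LossConfig()):
    """Analytic gradient of :func:`loss`; same type/shapes as ``params``.

    The L1 term contributes lambda * sign(.) with subgradient 0 at exactly-0
    coordinates. The logit clamp is treated as the identity (it is inactive
    on any batch where the loss is informative).
    """
    if not isinstance(batch, Batch):
        batch = Batch.from_samples(list(batch))
    N = len(batch)
    D = batch.X.shape[2]
    vD, vd = params.v[:D], params.v[D:]
    z = _batch_logits(params, batch)
    r = (sigmoid(z) - batch.y) / N               # dCE/dlogit per sample
    XvD = batch.X @ vD                           # (N, M)
    if isinstance(params, StandardLTRParams):
        du = r @ XvD + cfg.lambda_l1 * np.sign(params.u)
        dvD = np.einsum("n,nmd,m->d", r, batch.X, params.u)
        g = StandardLTRParams(u=du, v=np.concatenate([dvD, r @ batch.labs]), b=0.0)
    else:
        Xw = batch.X @ params.w
        dw = np.einsum("n,nmd,nm->d", r, batch.X, XvD) + cfg.lambda_l1 * np.sign(
            params.w
        )
        dvD = np.einsum("n,nmd,nm->d", r, batch.X, Xw)
        g = PersonalizedLTRParams(w=dw, v=np.concatenate([dvD, r @ batch.labs]), b=0.0)
    g.b = float(r.sum())
    return g


# ---------------------------------------------------------------------------
# persistence


def params_to_json(params, path_or_none=None, extra: dict | None = None) -> dict:
    """Serialize parameters (exact float round-trip via repr)."""
    if isinstance(params, StandardLTRParams):
        payload = {"kind": "standard", "u": params.u.tolist()}
    elif isinstance(params, PersonalizedLTRParams):
        payload = {"kind": "personalized", "w": params.w.tolist()}
    else:
        raise InvalidArgumentError("unknown parameter type")
    payload["v"] = params.v.tolist()
    payload["b"] = float(params.b)
    if extra:
        payload["meta"] = extra
    if path_or_none is not None:
        with open(path_or_none, "w") as fh:
            json.dump(payload, fh)
    return payload


def params_from_json(source):
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source) as fh:
            payload = json.load(fh)
    else:
        payload = source
    v = np.array(payload["v"], dtype=float)
    b = float(payload["b"])
    if payload["kind"] == "standard":
        return StandardLTRParams(u=np.array(payload["u"], dtype=float), v=v, b=b)
    if payload["kind"] == "personalized":
        return PersonalizedLTRParams(w=np.array(payload["w"], dtype=float), v=v, b=b)
    raise InvalidArgumentError(f"unknown model kind {payload['kind']!r}")
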
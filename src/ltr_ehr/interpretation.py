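"""Code-importance reports and add/remove-code risk simulation.

Three complementary views of a fitted model:

* population level — the Standard LTR code weights u, filtered to codes with
  weight above a threshold and carried by enough patients (guards against
  coincidental codes in small cohorts), ranked by weight;
* patient level — the Personalized LTR per-sample weights u_i = X_i w, one
  row per code present at the visit, ranked by |weight| (a personal risk
  profile);
* counterfactual — toggling a single code in a visit, rebuilding the tensor,
  and comparing predicted risk before/after.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .code_embedding import CodeEmbedding, SampleTensor, build_sample_tensor
from .exceptions import InvalidArgumentError
from .ltr_models import (
    PersonalizedLTRParams,
    StandardLTRParams,
    forward,
    personalized_code_weights,
)
from .synthetic_cohort import Cohort, VisitPair
from .temporal_encoding import apply_pe
from .training import FitResult


def _params_of(fit_or_params, expected):
    p = fit_or_params.params if isinstance(fit_or_params, FitResult) else fit_or_params
    if not isinstance(p, expected):
        raise InvalidArgumentError(f"expected {expected.__name__} fit")
    return p


def patients_per_code(cohort: Cohort) -> np.ndarray:
    """Number of distinct patients carrying each vocabulary code."""
    seen: dict[int, set] = {}
    for s in cohort.samples:
        for c in set(s.codes):
            seen.setdefault(cohort.vocabulary.index(c), set()).add(s.patient_id)
    out = np.zeros(len(cohort.vocabulary), dtype=int)
    for i, pids in seen.items():
        out[i] = len(pids)
    return out


def population_importance(
    fit: FitResult | StandardLTRParams,
    cohort: Cohort,
    min_weight: float = 0.1,
    min_patients: int = 30,
    category_filter: str | None = "diagnosis",
) -> pd.DataFrame:
    """Population-level code ranking from Standard LTR weights.

    Keeps codes with weight > ``min_weight`` carried by at least
    ``min_patients`` distinct patients (and matching ``category_filter`` if
    given), sorted by weight descending; ties broken by patient count
    descending, then code lexicographic. An empty report is valid.
    """
    params = _params_of(fit, StandardLTRParams)
    vocab = cohort.vocabulary
    if params.u.shape != (len(vocab),):
        raise InvalidArgumentError("fit dimensions do not match cohort vocabulary")
    counts = patients_per_code(cohort)
    rows = []
    for i, code in enumerate(vocab.codes):
        if category_filter is not None and vocab.category[i] != category_filter:
            continue
        if params.u[i] > min_weight and counts[i] >= min_patients:
            rows.append(
                {
                    "code": code,
                    "weight": float(params.u[i]),
                    "n_patients_with_code": int(counts[i]),
                    "category": vocab.category[i],
                }
            )
    df = pd.DataFrame(rows, columns=["code", "weight", "n_patients_with_code", "category"])
    if len(df):
        df = df.sort_values(
            by=["weight", "n_patients_with_code", "code"],
            ascending=[False, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
    return df


def personalized_importance(
    fit: FitResult | PersonalizedLTRParams, sample: SampleTensor
) -> pd.DataFrame:
    """Per-patient code weights u_i = X_i w for the codes present at a visit,
    sorted by |weight| descending (ties: code lexicographic)."""
    params = _params_of(fit, PersonalizedLTRParams)
    u_i = personalized_code_weights(params, sample)
    rows = [
        {"code": code, "weight": float(u_i[idx])}
        for code, idx in zip(sample.codes, sample.code_indices)
    ]
    df = pd.DataFrame(rows, columns=["code", "weight"])
    if len(df):
        df["absw"] = df["weight"].abs()
        df = (
            df.sort_values(by=["absw", "code"], ascending=[False, True], kind="mergesort")
            .drop(columns="absw")
            .reset_index(drop=True)
        )
    return df


def code_perturbation_risk(
    fit,
    pair: VisitPair,
    emb: CodeEmbedding,
    code: str,
    action: str,
    lab_stats: tuple | None = None,
    pe_mode: str = "multiplicative",
) -> tuple[float, float]:
    """Predicted risk before/after adding or removing one code from a visit.

    The sample tensor is rebuilt with the code toggled, PE re-applied, and
    the model re-evaluated. For the Personalized model the per-sample weights
    u_i = X_i w are implicitly recomputed, since they depend on the input.
    """
    params = fit.params if isinstance(fit, FitResult) else fit
    if code not in emb.vocabulary:
        raise InvalidArgumentError(f"code {code!r} not in vocabulary")
    present = code in set(pair.codes)
    if action == "add":
        if present:
            raise InvalidArgumentError(f"cannot add {code!r}: already present")
        new_codes = list(pair.codes) + [code]
    elif action == "remove":
        if not present:
            raise InvalidArgumentError(f"cannot remove {code!r}: not present")
        new_codes = [c for c in pair.codes if c != code]
    else:
        raise InvalidArgumentError(f"unknown action {action!r}")

    def risk(codes):
        p = VisitPair(
            patient_id=pair.patient_id,
            codes=codes,
            labs=pair.labs,
            elapsed_days=pair.elapsed_days,
            label=pair.label,
        )
        return forward(params, apply_pe(build_sample_tensor(p, emb, lab_stats), pe_mode))

    return risk(list(pair.codes)), risk(new_codes)


def plot_patient_profile(report: pd.DataFrame, path, title: str = "") -> None:
    """Horizontal bar plot of a personalized importance report (SVG-friendly):
    positive weights one color, negative another, ordered by significance."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, max(2, 0.3 * len(report))))
    if len(report):
        rows = report.iloc[::-1]  # most significant on top
        colors = ["#e6b422" if w >= 0 else "#3b6fb6" for w in rows["weight"]]
        ax.barh(rows["code"], rows["weight"], color=colors)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("code weight")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
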
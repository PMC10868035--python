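"""Seeded synthetic EHR cohorts with a known generating model.

Real advanced-heart-failure referral cohorts cannot be shared, so this module
builds paired-visit samples with the statistical structure the LTR models
assume: a medical-code vocabulary with diagnosis/procedure/drug categories and
phenotype-group structure (a Phecode analog), per-visit code multisets whose
co-occurrence is group-correlated (so embeddings have something to learn),
class-structured lab values, heavy-tailed inter-visit gap times, and binary
labels drawn from a known sparse logistic tensor regression model whose
parameters are recorded as ground truth for recovery experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, InvalidArgumentError

CATEGORIES = ("diagnosis", "procedure", "drug")

#: Default category proportions; mirrors a large hospital vocabulary where
#: ICD-10 diagnoses dominate, then CPT procedures, then drug classes.
DEFAULT_CATEGORY_PROPORTIONS = (5970 / 8438, 2229 / 8438, 239 / 8438)

#: Per-class lab summary statistics (mean, SD) used as generator defaults:
#: systolic blood pressure [mmHg], heart rate [bpm], chloride [mmol/L],
#: sodium [mmol/L], for the positive (needs advanced therapies) and negative
#: (too well) classes of an end-stage heart-failure cohort.
DEFAULT_LAB_STATS = {
    "positive": [(102.74, 14.95), (86.09, 18.85), (100.62, 4.88), (137.48, 3.58)],
    "negative": [(121.68, 22.74), (86.15, 16.68), (101.60, 5.79), (138.06, 4.35)],
}
DEFAULT_LAB_NAMES = ("sbp_mmHg", "hr_bpm", "chloride_mmol_L", "sodium_mmol_L")


@dataclass
class CodeVocabulary:
    """A synthetic medical-code vocabulary.

    Attributes
    ----------
    codes : list of str
        Unique identifiers styled after ICD-10 / CPT-4 / VA drug-class codes.
    category : list of str
        Per-code category in ``{"diagnosis", "procedure", "drug"}``.
    group_id : list of int
        Per-code synthetic phenotype-group id (the Phecode analog used to
        evaluate embeddings).
    """

    codes: list[str]
    category: list[str]
    group_id: list[int]

    def __post_init__(self) -> None:
        if len(set(self.codes)) != len(self.codes):
            raise InvalidArgumentError("vocabulary codes must be unique")
        if not (len(self.codes) == len(self.category) == len(self.group_id)):
            raise InvalidArgumentError("codes/category/group_id length mismatch")
        self._index = {c: i for i, c in enumerate(self.codes)}

    def __len__(self) -> int:
        return len(self.codes)

    def index(self, code: str) -> int:
        return self._index[code]

    def __contains__(self, code: str) -> bool:
        return code in self._index

    def category_indices(self, category: str) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.category) if c == category], dtype=int
        )

    def to_dict(self) -> dict:
        return {
            "codes": list(self.codes),
            "category": list(self.category),
            "group_id": [int(g) for g in self.group_id],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CodeVocabulary":
        return cls(codes=d["codes"], category=d["category"], group_id=d["group_id"])


@dataclass
class VisitPair:
    """One training sample: features at a visit, label at the next visit.

    ``codes`` is the multiset of medical codes recorded at the first visit,
    ``labs`` the selected lab/vital values (length d), ``elapsed_days`` the
    gap t_i > 0 to the next visit, and ``label`` the binary outcome (1 =
    warrants evaluation for advanced therapies).
    """

    patient_id: str
    codes: list[str]
    labs: np.ndarray
    elapsed_days: float
    label: int

    def __post_init__(self) -> None:
        self.labs = np.asarray(self.labs, dtype=float)
        if not np.all(np.isfinite(self.labs)):
            raise InvalidArgumentError("labs must be finite")
        if not self.elapsed_days > 0:
            raise InvalidArgumentError("elapsed_days must be > 0")
        if self.label not in (0, 1):
            raise InvalidArgumentError("label must be 0 or 1")


@dataclass
class GroundTruth:
    """Exact record of the generating LTR model for a synthetic cohort."""

    u_true: np.ndarray          # sparse code weights, length M
    v_true: np.ndarray          # regression coefficients, length D + d
    b_true: float
    embedding_true: np.ndarray  # M x D matrix used to generate labels
    noise: float                # label-flip probability
    lab_mix: float              # latent severity prevalence for lab draws
    lab_standardize: tuple      # (means, sds) applied to labs inside the logit
    probs: np.ndarray           # per-sample P(y=1) before label flips
    labels_pre_noise: np.ndarray
    label_seed: int             # seed of the RNG stream that drew the labels

    def to_dict(self) -> dict:
        means, sds = self.lab_standardize
        return {
            "u_true": self.u_true.tolist(),
            "v_true": self.v_true.tolist(),
            "b_true": float(self.b_true),
            "embedding_true": self.embedding_true.tolist(),
            "noise": float(self.noise),
            "lab_mix": float(self.lab_mix),
            "lab_standardize": [list(map(float, means)), list(map(float, sds))],
            "probs": self.probs.tolist(),
            "labels_pre_noise": self.labels_pre_noise.astype(int).tolist(),
            "label_seed": int(self.label_seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            u_true=np.array(d["u_true"], dtype=float),
            v_true=np.array(d["v_true"], dtype=float),
            b_true=float(d["b_true"]),
            embedding_true=np.array(d["embedding_true"], dtype=float),
            noise=float(d["noise"]),
            lab_mix=float(d["lab_mix"]),
            lab_standardize=(
                np.array(d["lab_standardize"][0], dtype=float),
                np.array(d["lab_standardize"][1], dtype=float),
            ),
            probs=np.array(d["probs"], dtype=float),
            labels_pre_noise=np.array(d["labels_pre_noise"], dtype=int),
            label_seed=int(d["label_seed"]),
        )


@dataclass
class Cohort:
    """A list of paired-visit samples plus vocabulary and optional truth."""

    samples: list[VisitPair]
    vocabulary: CodeVocabulary
    truth: GroundTruth | None = None
    lab_names: tuple = field(default=DEFAULT_LAB_NAMES)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=int)

    @property
    def patient_ids(self) -> list[str]:
        return [s.patient_id for s in self.samples]

    def patient_labels(self) -> dict[str, int]:
        """Patient-level label: positive if any of the patient's pairs is."""
        out: dict[str, int] = {}
        for s in self.samples:
            out[s.patient_id] = max(out.get(s.patient_id, 0), s.label)
        return out


# ---------------------------------------------------------------------------
# vocabulary generation


def _icd10_style(rng: np.random.Generator, taken: set) -> str:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    while True:
        code = (
            letters[rng.integers(len(letters))]
            + f"{rng.integers(100):02d}.{rng.integers(10)}"
        )
        if code not in taken:
            return code


def _cpt_style(rng: np.random.Generator, taken: set) -> str:
    while True:
        code = f"{rng.integers(10000, 100000)}"
        if code not in taken:
            return code


def _va_drug_style(rng: np.random.Generator, taken: set) -> str:
    prefixes = ["CV", "GA", "HS", "CN", "BL", "RE", "AM"]
    while True:
        code = prefixes[rng.integers(len(prefixes))] + f"{rng.integers(1000):03d}"
        if code not in taken:
            return code


def generate_vocabulary(
    n_codes: int,
    n_groups: int,
    seed: int,
    proportions: tuple = DEFAULT_CATEGORY_PROPORTIONS,
) -> CodeVocabulary:
    """Generate a vocabulary of ``n_codes`` codes in ``n_groups`` groups.

    Categories are assigned in the given proportions (largest-remainder
    rounding); group ids are assigned within category where possible so that
    groups behave like diagnosis phenotype groups. Deterministic per seed.
    """
    if n_codes <= 0 or n_groups <= 0:
        raise InvalidArgumentError("n_codes and n_groups must be positive")
    if n_groups > n_codes:
        raise InvalidArgumentError("n_groups cannot exceed n_codes")
    rng = np.random.default_rng(seed)
    props = np.asarray(proportions, dtype=float)
    props = props / props.sum()
    counts = np.floor(props * n_codes).astype(int)
    # largest remainder
    rem = props * n_codes - counts
    for i in np.argsort(-rem)[: n_codes - counts.sum()]:
        counts[i] += 1

    taken: set = set()
    codes: list[str] = []
    category: list[str] = []
    makers = (_icd10_style, _cpt_style, _va_drug_style)
    for cat, count, maker in zip(CATEGORIES, counts, makers):
        for _ in range(count):
            c = maker(rng, taken)
            taken.add(c)
            codes.append(c)
            category.append(cat)

    # shuffle code order, then assign groups cycling over a shuffled group order
    order = rng.permutation(n_codes)
    codes = [codes[i] for i in order]
    category = [category[i] for i in order]
    group_of = rng.permutation(n_groups)
    group_id = [int(group_of[i % n_groups]) for i in range(n_codes)]
    return CodeVocabulary(codes=codes, category=category, group_id=group_id)


# ---------------------------------------------------------------------------
# cohort generation


def _lab_population_stats(lab_stats: dict, mix: float) -> tuple[np.ndarray, np.ndarray]:
    """Population mean/SD of the two-class Gaussian lab mixture."""
    pos = np.array(lab_stats["positive"], dtype=float)
    neg = np.array(lab_stats["negative"], dtype=float)
    mean = mix * pos[:, 0] + (1 - mix) * neg[:, 0]
    second = mix * (pos[:, 1] ** 2 + pos[:, 0] ** 2) + (1 - mix) * (
        neg[:, 1] ** 2 + neg[:, 0] ** 2
    )
    sd = np.sqrt(second - mean**2)
    return mean, sd


def _draw_visit_codes(
    rng: np.random.Generator,
    vocab: CodeVocabulary,
    group_members: dict[int, np.ndarray],
    code_rate: float,
    group_fidelity: float,
) -> list[int]:
    n = 1 + rng.poisson(code_rate)
    gids = list(group_members)
    primary = gids[rng.integers(len(gids))]
    members = group_members[primary]
    idx = []
    for _ in range(n):
        if rng.random() < group_fidelity:
            idx.append(int(members[rng.integers(len(members))]))
        else:
            idx.append(int(rng.integers(len(vocab))))
    return idx


def generate_cohort(
    vocab: CodeVocabulary,
    n_patients: int = 300,
    n_pairs: int = 557,
    d: int = 4,
    D: int = 8,
    sparsity: float = 0.2,
    noise: float = 0.05,
    seed: int = 0,
    code_rate: float = 5.0,
    group_fidelity: float = 0.75,
    lab_stats: dict = DEFAULT_LAB_STATS,
    lab_mix: float = 0.35,
    elapsed_median_days: float = 60.0,
    elapsed_sigma: float = 0.75,
    weight_low: float = 15.0,
    weight_high: float = 30.0,
    positive_frac: float = 0.6,
    intercept: float = -4.5,
    u_true: np.ndarray | None = None,
    apply_pe_in_truth: bool = True,
) -> Cohort:
    """Generate a seeded cohort whose labels come from a known sparse LTR model.

    The generating model is the Standard LTR forward model: a ground-truth
    embedding matrix is drawn, positional encoding of the (log-normal) gap
    time is applied to the stacked code matrix and the standardized labs, and
    labels are Bernoulli(sigmoid(logit)) with an optional flip probability
    ``noise``. ``sparsity`` is the fraction of codes with a nonzero
    ground-truth weight; of those, a fixed ``positive_frac`` share (rounded)
    is positive so that a top-positive set always exists. The default weight
    scale is strong (near-deterministic labels for code-rich visits): the
    label's Bernoulli draw is itself a large noise source, and a cohort
    whose outcome is mostly attributable to the recorded codes is the regime
    the models target. An explicit ``u_true`` overrides the random sparse
    draw (its length must be M). Code multisets are group-correlated: each
    visit draws mostly from one phenotype group (``group_fidelity``), which
    is the signal embeddings must learn.
    """
    from .ltr_models import canonicalize_orientation  # local import, avoids cycle
    from .temporal_encoding import positional_encoding

    if n_patients <= 0 or n_pairs <= 0:
        raise InvalidArgumentError("n_patients and n_pairs must be positive")
    if n_pairs < n_patients:
        raise InvalidArgumentError("n_pairs must be >= n_patients")
    if not 0 <= noise < 0.5:
        raise InvalidArgumentError("noise must be in [0, 0.5)")
    if not 0 <= sparsity <= 1:
        raise InvalidArgumentError("sparsity must be a fraction")
    if d != len(lab_stats["positive"]):
        raise InvalidArgumentError("d inconsistent with lab_stats dimensions")
    if (D + d) % 2 != 0:
        raise InvalidArgumentError("D + d must be even for positional encoding")

    M = len(vocab)
    ss = np.random.SeedSequence(seed)
    s_struct, s_label = ss.spawn(2)
    rng = np.random.default_rng(s_struct)
    label_seed = int(s_label.generate_state(1)[0] % (2**31))

    # ground-truth parameters
    embedding_true = rng.normal(size=(M, D))
    if u_true is not None:
        u_true = np.asarray(u_true, dtype=float)
        if u_true.shape != (M,):
            raise InvalidArgumentError("explicit u_true must have length M")
        u_true = u_true.copy()
    else:
        k = int(round(sparsity * M))
        u_true = np.zeros(M)
        if k > 0:
            support = rng.choice(M, size=k, replace=False)
            mags = rng.uniform(weight_low, weight_high, size=k)
            n_pos = int(round(positive_frac * k))
            signs = np.array([1.0] * n_pos + [-1.0] * (k - n_pos))
            rng.shuffle(signs)
            u_true[support] = mags * signs
    vD = rng.normal(size=D)
    vD /= np.linalg.norm(vD)
    vd = rng.normal(size=d)
    vd *= 0.5 / max(np.linalg.norm(vd), 1e-12)
    v_true = np.concatenate([vD, vd])
    b_true = float(intercept)
    u_true, v_true = canonicalize_orientation(u_true, v_true, D)
    vD, vd = v_true[:D], v_true[D:]  # use the canonicalized orientation below

    # patient/pair allocation: everyone has >=1 pair
    extra = rng.multinomial(n_pairs - n_patients, np.full(n_patients, 1 / n_patients))
    pair_counts = 1 + extra
    group_members = {}
    gids = np.asarray(vocab.group_id)
    for g in np.unique(gids):
        group_members[int(g)] = np.flatnonzero(gids == g)

    lab_means, lab_sds = _lab_population_stats(lab_stats, lab_mix)
    pos_stats = np.array(lab_stats["positive"], dtype=float)
    neg_stats = np.array(lab_stats["negative"], dtype=float)

    samples: list[VisitPair] = []
    code_idx_per_sample: list[list[int]] = []
    logits = []
    for p in range(n_patients):
        pid = f"P{p:05d}"
        for _ in range(pair_counts[p]):
            idx = _draw_visit_codes(rng, vocab, group_members, code_rate, group_fidelity)
            t = float(np.exp(rng.normal(np.log(elapsed_median_days), elapsed_sigma)))
            z = rng.random() < lab_mix
            stats = pos_stats if z else neg_stats
            labs = rng.normal(stats[:, 0], stats[:, 1])
            labs_std = (labs - lab_means) / lab_sds

            uniq = sorted(set(idx))
            pe = positional_encoding(t, D, d).values if apply_pe_in_truth else np.ones(D + d)
            # presence-based stacked matrix restricted to present rows
            Xrows = embedding_true[uniq] * pe[:D]
            logit = float(
                u_true[uniq] @ (Xrows @ vD) + (labs_std * pe[D:]) @ vd + b_true
            )
            logits.append(logit)
            code_idx_per_sample.append(idx)
            samples.append(
                VisitPair(
                    patient_id=pid,
                    codes=[vocab.codes[i] for i in idx],
                    labs=labs,
                    elapsed_days=t,
                    label=0,  # filled below
                )
            )

    logits = np.asarray(logits)
    probs = 1.0 / (1.0 + np.exp(-np.clip(logits, -30, 30)))
    lrng = np.random.default_rng(label_seed)
    labels_pre = (lrng.random(len(probs)) < probs).astype(int)
    flips = lrng.random(len(probs)) < noise
    labels = np.where(flips, 1 - labels_pre, labels_pre)
    for s, y in zip(samples, labels):
        s.label = int(y)

    truth = GroundTruth(
        u_true=u_true,
        v_true=v_true,
        b_true=b_true,
        embedding_true=embedding_true,
        noise=noise,
        lab_mix=lab_mix,
        lab_standardize=(lab_means, lab_sds),
        probs=probs,
        labels_pre_noise=labels_pre,
        label_seed=label_seed,
    )
    return Cohort(samples=samples, vocabulary=vocab, truth=truth)


def regenerate_labels(cohort: Cohort) -> np.ndarray:
    """Re-draw labels from the stored GroundTruth's seeded label stream.

    With ``noise=0`` this reproduces the cohort's labels exactly; with noise,
    it reproduces them including the recorded flips.
    """
    t = cohort.truth
    if t is None:
        raise InvalidArgumentError("cohort has no ground truth")
    lrng = np.random.default_rng(t.label_seed)
    labels_pre = (lrng.random(len(t.probs)) < t.probs).astype(int)
    flips = lrng.random(len(t.probs)) < t.noise
    return np.where(flips, 1 - labels_pre, labels_pre)


# ---------------------------------------------------------------------------
# code-label correlation screen


def code_label_correlation_screen(cohort: Cohort) -> pd.DataFrame:
    """Pearson correlation of each code's binary presence with the label.

    Returns a DataFrame with columns ``code`` and ``pearson_r`` sorted by
    absolute correlation (descending). Codes whose presence has zero variance
    get r = 0 by convention. Report-only: no codes are removed.
    """
    y = cohort.labels.astype(float)
    if len(y) < 2 or np.var(y) == 0:
        raise DegenerateInputError("need >=2 samples with label variance > 0")
    M = len(cohort.vocabulary)
    presence = np.zeros((len(cohort), M))
    for i, s in enumerate(cohort.samples):
        for c in set(s.codes):
            presence[i, cohort.vocabulary.index(c)] = 1.0
    pv = presence.var(axis=0)
    yc = y - y.mean()
    cov = presence.T @ yc / len(y)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(pv > 0, cov / np.sqrt(pv * y.var()), 0.0)
    df = pd.DataFrame({"code": cohort.vocabulary.codes, "pearson_r": r})
    df = df.reindex(df["pearson_r"].abs().sort_values(ascending=False, kind="stable").index)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# serialization


def write_cohort(cohort: Cohort, csv_path, json_path) -> None:
    """One CSV row per sample + a JSON sidecar (vocabulary, ground truth)."""
    rows = []
    for s in cohort.samples:
        row = {"patient_id": s.patient_id, "codes": "|".join(s.codes)}
        for name, v in zip(cohort.lab_names, s.labs):
            row[name] = float(f"{v:.12g}")
        row["elapsed_days"] = float(f"{s.elapsed_days:.12g}")
        row["label"] = s.label
        rows.append(row)
    pd.DataFrame(rows).to_csv(csv_path, index=False, float_format="%.12g")
    sidecar = {
        "vocabulary": cohort.vocabulary.to_dict(),
        "lab_names": list(cohort.lab_names),
        "truth": cohort.truth.to_dict() if cohort.truth is not None else None,
    }
    with open(json_path, "w") as fh:
        json.dump(sidecar, fh)


def read_cohort(csv_path, json_path) -> Cohort:
    with open(json_path) as fh:
        sidecar = json.load(fh)
    vocab = CodeVocabulary.from_dict(sidecar["vocabulary"])
    lab_names = tuple(sidecar["lab_names"])
    df = pd.read_csv(csv_path, dtype={"codes": str, "patient_id": str})
    df["codes"] = df["codes"].fillna("")
    samples = []
    for _, row in df.iterrows():
        codes = [c for c in str(row["codes"]).split("|") if c]
        samples.append(
            VisitPair(
                patient_id=row["patient_id"],
                codes=codes,
                labs=np.array([row[n] for n in lab_names], dtype=float),
                elapsed_days=float(row["elapsed_days"]),
                label=int(row["label"]),
            )
        )
    truth = (
        GroundTruth.from_dict(sidecar["truth"]) if sidecar["truth"] is not None else None
    )
    return Cohort(samples=samples, vocabulary=vocab, truth=truth, lab_names=lab_names)
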
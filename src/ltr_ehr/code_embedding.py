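"""Medical-code embeddings and per-sample stacked tensors.

Each hospital visit is treated as a "medical document" whose words are the
medical codes recorded at that visit; word2vec (skip-gram with negative
sampling, or CBOW) then maps every code to a vector in R^D. A sample's
feature matrix X_i in R^{M x D} stacks the embedding vectors at the rows of
the codes present in the visit (all other rows zero; presence-based, so a
code repeated within a visit contributes one row).

Embedding quality is evaluated as in phenome-wide practice: pairs of
diagnosis codes are labeled positive when they share a phenotype group (the
Phecode analog carried by the synthetic vocabulary), and the cosine
similarity of their vectors is scored by AUC against that indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.metrics import roc_auc_score

from ._word2vec import train_word2vec
from .exceptions import DegenerateInputError, InvalidArgumentError, MissingCodeError
from .synthetic_cohort import Cohort, CodeVocabulary, VisitPair


@dataclass
class CodeEmbedding:
    """Vocabulary -> R^D map stored as an (M, D) matrix in vocabulary order."""

    vocabulary: CodeVocabulary
    matrix: np.ndarray
    method: str = "sgns"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != len(self.vocabulary):
            raise InvalidArgumentError("embedding rows must match vocabulary size")
        if not np.all(np.isfinite(self.matrix)):
            raise InvalidArgumentError("embedding vectors must be finite")

    @property
    def D(self) -> int:
        return self.matrix.shape[1]

    def vector(self, code: str) -> np.ndarray:
        if code not in self.vocabulary:
            raise MissingCodeError(code)
        return self.matrix[self.vocabulary.index(code)]


@dataclass
class SampleTensor:
    """One model-ready sample: stacked code matrix, labs, gap time, label."""

    X: np.ndarray              # (M, D); nonzero rows only at present codes
    x: np.ndarray              # (d,) lab vector (standardized if stats given)
    t: float                   # elapsed days
    y: int                     # label in {0, 1}
    code_indices: np.ndarray   # sorted unique vocabulary indices present
    codes: list = field(default_factory=list)
    patient_id: str = ""
    pe_applied: bool = False


def train_embeddings(
    cohort: Cohort,
    D: int = 100,
    method: str = "sgns",
    epochs: int = 20,
    window: int | None = None,
    negatives: int = 5,
    lr: float = 0.05,
    seed: int = 0,
) -> CodeEmbedding:
    """Train code embeddings on the cohort's visit documents.

    One sentence per visit; codes within a sentence are shuffled each epoch
    (seeded) because they carry no order, and the default context window is
    the whole visit. Codes never observed get a zero vector. Single-threaded
    and deterministic per seed.
    """
    if D < 2:
        raise InvalidArgumentError("embedding dimension D must be >= 2")
    if len(cohort) == 0:
        raise InvalidArgumentError("empty corpus")
    method = method.lower()
    if method not in ("sgns", "cbow"):
        raise InvalidArgumentError("method must be 'sgns' or 'cbow'")
    vocab = cohort.vocabulary
    sentences = [[vocab.index(c) for c in s.codes] for s in cohort.samples]
    if all(len(s) == 0 for s in sentences):
        raise InvalidArgumentError("empty corpus")
    matrix = train_word2vec(
        sentences,
        vocab_size=len(vocab),
        dim=D,
        method=method,
        epochs=epochs,
        window=window,
        negatives=negatives,
        lr=lr,
        seed=seed,
    )
    return CodeEmbedding(vocabulary=vocab, matrix=matrix, method=method)


def build_sample_tensor(
    pair: VisitPair,
    emb: CodeEmbedding,
    lab_stats: tuple | None = None,
    use_counts: bool = False,
) -> SampleTensor:
    """Stack embedding vectors into the M x D sample matrix X_i.

    Presence convention by default: duplicate codes collapse to one nonzero
    row (``use_counts=True`` multiplies rows by within-visit multiplicity
    instead). ``lab_stats=(means, sds)`` standardizes the lab vector.
    """
    vocab = emb.vocabulary
    for c in pair.codes:
        if c not in vocab:
            raise MissingCodeError(c)
    M, D = emb.matrix.shape
    X = np.zeros((M, D))
    idx_counts: dict[int, int] = {}
    for c in pair.codes:
        i = vocab.index(c)
        idx_counts[i] = idx_counts.get(i, 0) + 1
    idx = np.array(sorted(idx_counts), dtype=int)
    if len(idx):
        X[idx] = emb.matrix[idx]
        if use_counts:
            X[idx] *= np.array([idx_counts[i] for i in idx])[:, None]
    x = np.asarray(pair.labs, dtype=float)
    if lab_stats is not None:
        means, sds = lab_stats
        x = (x - np.asarray(means)) / np.asarray(sds)
    return SampleTensor(
        X=X,
        x=x,
        t=float(pair.elapsed_days),
        y=int(pair.label),
        code_indices=idx,
        codes=[vocab.codes[i] for i in idx],
        patient_id=pair.patient_id,
    )


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DegenerateInputError("cosine similarity undefined for zero vectors")
    return float(a @ b / (na * nb))


def evaluate_embedding_auc(
    emb: CodeEmbedding,
    max_pairs: int = 200_000,
    seed: int = 0,
) -> float:
    """Pair-classification AUC of the embedding against phenotype groups.

    Over all unordered pairs of diagnosis-category codes with nonzero
    vectors, score = cosine similarity, positive = same group id. When the
    pair count exceeds ``max_pairs`` the negatives are subsampled (seeded);
    all positive pairs are kept.
    """
    vocab = emb.vocabulary
    diag = vocab.category_indices("diagnosis")
    norms = np.linalg.norm(emb.matrix, axis=1)
    diag = diag[norms[diag] > 0]  # zero vectors excluded: cosine undefined
    if len(diag) < 2:
        raise DegenerateInputError("need >=2 nonzero diagnosis vectors")
    gid = np.asarray(vocab.group_id)[diag]
    unit = emb.matrix[diag] / norms[diag][:, None]

    pairs = np.array(list(combinations(range(len(diag)), 2)), dtype=int)
    same = gid[pairs[:, 0]] == gid[pairs[:, 1]]
    if not same.any():
        raise DegenerateInputError("no positive (same-group) diagnosis pairs")
    if not (~same).any():
        raise DegenerateInputError("no negative (cross-group) diagnosis pairs")
    if len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        neg = np.flatnonzero(~same)
        keep_neg = rng.choice(neg, size=max(1, max_pairs - int(same.sum())), replace=False)
        keep = np.concatenate([np.flatnonzero(same), keep_neg])
        pairs, same = pairs[keep], same[keep]
    scores = np.einsum("ij,ij->i", unit[pairs[:, 0]], unit[pairs[:, 1]])
    return float(roc_auc_score(same.astype(int), scores))


# ---------------------------------------------------------------------------
# persistence: standard word2vec text format


def save_word2vec_text(emb: CodeEmbedding, path) -> None:
    M, D = emb.matrix.shape
    with open(path, "w") as fh:
        fh.write(f"{M} {D}\n")
        for code, vec in zip(emb.vocabulary.codes, emb.matrix):
            fh.write(code + " " + " ".join(repr(float(v)) for v in vec) + "\n")


def load_word2vec_text(path, vocabulary: CodeVocabulary, method: str = "sgns") -> CodeEmbedding:
    with open(path) as fh:
        header = fh.readline().split()
        M, D = int(header[0]), int(header[1])
        matrix = np.zeros((len(vocabulary), D))
        for _ in range(M):
            parts = fh.readline().rstrip("\n").split(" ")
            code, vals = parts[0], parts[1:]
            if code in vocabulary:
                matrix[vocabulary.index(code)] = [float(v) for v in vals]
    return CodeEmbedding(vocabulary=vocabulary, matrix=matrix, method=method)
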
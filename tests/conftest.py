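import numpy as np
import pytest

from ltr_ehr import (
    CodeEmbedding,
    CodeVocabulary,
    generate_cohort,
    generate_vocabulary,
)
from ltr_ehr.evaluation import _lab_stats_from, build_tensors


@pytest.fixture(scope="session")
def vocab20():
    return generate_vocabulary(20, 5, seed=11)


@pytest.fixture(scope="session")
def cohort_small(vocab20):
    return generate_cohort(vocab20, n_patients=40, n_pairs=80, D=8, seed=11)


@pytest.fixture(scope="session")
def emb_true(cohort_small):
    """Embedding equal to the cohort's generating matrix."""
    return CodeEmbedding(
        vocabulary=cohort_small.vocabulary, matrix=cohort_small.truth.embedding_true
    )


@pytest.fixture(scope="session")
def tensors_small(cohort_small, emb_true):
    stats = _lab_stats_from(cohort_small.samples)
    return build_tensors(
        cohort_small, emb_true, list(range(len(cohort_small))), stats
    )


@pytest.fixture()
def diag_vocab4():
    """Four diagnosis codes in two phenotype groups (hand-built)."""
    return CodeVocabulary(
        codes=["I50.1", "I50.2", "N18.3", "N18.4"],
        category=["diagnosis"] * 4,
        group_id=[0, 0, 1, 1],
    )


def random_params(rng, M, D, d, kind="standard"):
    from ltr_ehr import PersonalizedLTRParams, StandardLTRParams

    v = rng.normal(size=D + d)
    b = float(rng.normal())
    if kind == "standard":
        return StandardLTRParams(u=rng.normal(size=M), v=v, b=b)
    return PersonalizedLTRParams(w=rng.normal(size=D), v=v, b=b)


def random_sample(rng, M, D, d, n_codes=3):
    from ltr_ehr.code_embedding import SampleTensor

    idx = np.sort(rng.choice(M, size=min(n_codes, M), replace=False))
    X = np.zeros((M, D))
    X[idx] = rng.normal(size=(len(idx), D))
    return SampleTensor(
        X=X,
        x=rng.normal(size=d),
        t=float(rng.uniform(1, 400)),
        y=int(rng.integers(2)),
        code_indices=idx,
        codes=[f"C{i}" for i in idx],
    )
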
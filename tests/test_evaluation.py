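"""Cross-validation plans, pooled/weighted features, metrics, Cohen's D."""

import itertools

import numpy as np
import pytest

from ltr_ehr import (
    CodeEmbedding,
    Cohort,
    DegenerateInputError,
    InvalidArgumentError,
    VisitPair,
    cohens_d,
    effect_size_label,
    make_fold_plan,
    metrics,
    pooled_features,
    weighted_features,
)
from ltr_ehr.evaluation import run_cv
from tests.conftest import random_sample


class TestFoldPlan:
    def test_exhaustive_partition_one_patient_per_fold(self):
        samples = [
            VisitPair(patient_id=f"P{i}", codes=[], labs=np.zeros(4),
                      elapsed_days=1.0, label=i % 2)
            for i in range(20)
        ]
        from ltr_ehr import generate_vocabulary

        cohort = Cohort(samples=samples, vocabulary=generate_vocabulary(5, 2, seed=0))
        plan = make_fold_plan(cohort, k=10, test_ratio=0.0, seed=1)
        assert plan.test_holdout == set()
        assert all(len(f) == 2 for f in plan.folds)

    def test_patient_disjointness_everywhere(self, cohort_small):
        plan = make_fold_plan(cohort_small, k=5, test_ratio=0.2, seed=2)
        groups = [plan.test_holdout] + plan.folds
        for a, b in itertools.combinations(groups, 2):
            assert not (a & b)
        assert set().union(*groups) == set(cohort_small.patient_ids)

    def test_holdout_count_follows_per_class_rounding(self):
        from ltr_ehr import generate_cohort, generate_vocabulary

        vocab = generate_vocabulary(60, 10, seed=3)
        cohort = generate_cohort(vocab, n_patients=300, n_pairs=557, D=8, seed=3)
        plan = make_fold_plan(cohort, k=10, test_ratio=0.2, seed=3)
        plab = cohort.patient_labels()
        n_pos = sum(plab.values())
        expected = round(0.2 * n_pos) + round(0.2 * (300 - n_pos))
        assert len(plan.test_holdout) == expected
        assert abs(len(plan.test_holdout) - 60) <= 1

    def test_folds_stratified_within_one_patient(self, cohort_small):
        plan = make_fold_plan(cohort_small, k=5, test_ratio=0.2, seed=4)
        plab = cohort_small.patient_labels()
        remaining = [p for p in plab if p not in plan.test_holdout]
        global_frac = np.mean([plab[p] for p in remaining])
        for f in plan.folds:
            pos = sum(plab[p] for p in f)
            assert abs(pos - global_frac * len(f)) <= 1.0

    def test_too_many_folds_rejected(self, cohort_small):
        with pytest.raises((InvalidArgumentError, DegenerateInputError)):
            make_fold_plan(cohort_small, k=100, test_ratio=0.0, seed=0)


class TestFeatureConstruction:
    def test_pooled_length_and_zero_matrix(self):
        rng = np.random.default_rng(0)
        s = random_sample(rng, M=10, D=100, d=4, n_codes=0)
        s.X[:] = 0.0
        f = pooled_features(s)
        assert f.shape == (104,)
        assert np.all(f[:100] == 0)
        np.testing.assert_array_equal(f[100:], s.x)

    def test_pooled_divides_by_total_code_count(self, vocab20, emb_true):
        from ltr_ehr import build_sample_tensor

        pair = VisitPair(patient_id="P0", codes=vocab20.codes[:2], labs=np.zeros(4),
                         elapsed_days=1.0, label=0)
        s = build_sample_tensor(pair, emb_true)
        f = pooled_features(s)
        expected = (emb_true.matrix[vocab20.index(vocab20.codes[0])]
                    + emb_true.matrix[vocab20.index(vocab20.codes[1])]) / 20
        np.testing.assert_allclose(f[:8], expected, atol=1e-12)

    def test_uniform_weights_reduce_to_pooled(self):
        rng = np.random.default_rng(1)
        s = random_sample(rng, M=12, D=6, d=4)
        np.testing.assert_allclose(
            weighted_features(s, np.full(12, 1 / 12)), pooled_features(s), atol=1e-12
        )

    def test_one_hot_weight_selects_code_row(self):
        rng = np.random.default_rng(2)
        s = random_sample(rng, M=8, D=6, d=4, n_codes=3)
        c = int(s.code_indices[0])
        w = np.zeros(8)
        w[c] = 1.0
        np.testing.assert_allclose(weighted_features(s, w)[:6], s.X[c], atol=1e-12)

    def test_weighted_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        s = random_sample(rng, M=9, D=5, d=3)
        w = rng.normal(size=9)
        expected = np.zeros(5)
        for m in range(9):
            expected += w[m] * s.X[m]
        got = weighted_features(s, w)
        np.testing.assert_allclose(got[:5], expected, atol=1e-12)
        np.testing.assert_array_equal(got[5:], s.x)

    def test_weight_length_mismatch(self):
        rng = np.random.default_rng(4)
        s = random_sample(rng, M=9, D=5, d=3)
        with pytest.raises(InvalidArgumentError):
            weighted_features(s, np.ones(4))


def _bruteforce_auc(y, scores):
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = sum(1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg)
    return total / (len(pos) * len(neg))


class TestMetrics:
    def test_perfect_predictions(self):
        m = metrics([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert m == {"accuracy": 1.0, "f1": 1.0, "auc": 1.0, "auprc": 1.0}

    def test_hand_confusion_table(self):
        # TP=2, FP=1, FN=1, TN=6
        y_true = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        score = [0.9, 0.8, 0.1, 0.7, 0.2, 0.2, 0.3, 0.1, 0.05, 0.4]
        m = metrics(y_true, score)
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["f1"] == pytest.approx(4 / 6)

    def test_auc_matches_concordant_pair_count_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(4, 21))
            y = np.r_[np.ones(n // 2, dtype=int), np.zeros(n - n // 2, dtype=int)]
            rng.shuffle(y)
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # forces ties
            m = metrics(y, scores)
            assert m["auc"] == pytest.approx(_bruteforce_auc(y, scores), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        s = rng.normal(size=30)
        a = metrics(y, s)["auc"]
        b = metrics(y, np.exp(2.0 * s))["auc"]
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_truth_rejected(self):
        with pytest.raises(DegenerateInputError):
            metrics([1, 1, 1], [0.1, 0.5, 0.9])


class TestCohensD:
    def test_identical_lists_zero(self):
        assert cohens_d([0.8, 0.9, 0.7], [0.8, 0.9, 0.7]) == 0.0

    def test_constant_shift_equals_shift_over_sd(self):
        rng = np.random.default_rng(7)
        b = rng.normal(size=10)
        a = b + 0.3
        s = np.std(b, ddof=1)
        assert cohens_d(a, b) == pytest.approx(0.3 / s, rel=1e-12)

    def test_matches_hand_formula(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=10), rng.normal(size=10)
        pooled = np.sqrt((9 * a.var(ddof=1) + 9 * b.var(ddof=1)) / 18)
        assert cohens_d(a, b) == pytest.approx((a.mean() - b.mean()) / pooled, rel=1e-12)

    def test_degenerate_cases(self):
        with pytest.raises(InvalidArgumentError):
            cohens_d([1.0], [1.0, 2.0])
        with pytest.raises(DegenerateInputError):
            cohens_d([1.0, 1.0], [2.0, 2.0])

    def test_effect_size_convention(self):
        assert effect_size_label(0.85) == "large"
        assert effect_size_label(-0.9) == "large"
        assert effect_size_label(0.6) == "moderate"
        assert effect_size_label(0.2) == "small"


def _deterministic_cohort():
    """Label == presence of a designated risk code; perfectly separable."""
    from ltr_ehr import CodeVocabulary

    vocab = CodeVocabulary(
        codes=["RISK0", "A00.0", "B00.0", "C00.0"],
        category=["diagnosis"] * 4,
        group_id=[0, 1, 1, 1],
    )
    rng = np.random.default_rng(9)
    samples = []
    for i in range(60):
        y = i % 2
        codes = (["RISK0"] if y else []) + [vocab.codes[1 + rng.integers(3)]]
        # constant gap time and zero labs keep the pooled feature exactly
        # proportional to risk-code presence
        samples.append(
            VisitPair(patient_id=f"P{i}", codes=codes, labs=np.zeros(4),
                      elapsed_days=30.0, label=y)
        )
    # large embedding scale so the risk-code coordinate dominates the
    # regularized fit after pooling divides by M and PE scales columns
    emb = CodeEmbedding(vocabulary=vocab, matrix=40.0 * np.eye(4))
    return Cohort(samples=samples, vocabulary=vocab), emb


class TestRunCV:
    def test_separable_cohort_perfect_auc_every_fold(self):
        cohort, emb = _deterministic_cohort()
        plan = make_fold_plan(cohort, k=4, test_ratio=0.0, seed=0)
        report = run_cv(cohort, emb, models=("lr",), plan=plan, transfer="none", seed=0)
        assert (report.per_fold["auc"] == 1.0).all()
        assert report.skipped == []

    def test_report_structure_and_cohens_d(self, cohort_small, emb_true):
        from ltr_ehr import TrainConfig

        plan = make_fold_plan(cohort_small, k=4, test_ratio=0.2, seed=1)
        cfg = TrainConfig(lr=0.05, lam=1e-3, max_steps=150, seed=1, val_fraction=0.0)
        report = run_cv(cohort_small, emb_true, models=("s-ltr", "lr"), plan=plan,
                        transfer="none", train_cfg=cfg, seed=1)
        assert set(report.per_fold["model"]) == {"s-ltr", "lr"}
        assert set(report.summary.columns) >= {"model", "auc_mean", "auc_std"}
        assert ("s-ltr", "lr") in report.cohens_d
        assert "s-ltr" in report.holdout
        for met in ("accuracy", "f1", "auc", "auprc"):
            assert report.per_fold[met].between(0, 1).all()

    def test_report_serialization(self, cohort_small, emb_true, tmp_path):
        from ltr_ehr import TrainConfig

        plan = make_fold_plan(cohort_small, k=3, test_ratio=0.0, seed=2)
        cfg = TrainConfig(lr=0.05, max_steps=80, seed=2, val_fraction=0.0)
        report = run_cv(cohort_small, emb_true, models=("lr",), plan=plan,
                        train_cfg=cfg, seed=2)
        report.to_json(tmp_path / "r.json")
        report.to_tsv(tmp_path / "r.tsv")
        assert (tmp_path / "r.json").stat().st_size > 0
        assert "auc_mean" in (tmp_path / "r.tsv").read_text()

    def test_unknown_model_rejected(self, cohort_small, emb_true):
        with pytest.raises(InvalidArgumentError):
            run_cv(cohort_small, emb_true, models=("xgb",))
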
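"""LTR forward models, losses, analytic gradients, canonicalization."""

import numpy as np
import pytest

from ltr_ehr import (
    InvalidArgumentError,
    LossConfig,
    PersonalizedLTRParams,
    StandardLTRParams,
    forward_personalized,
    forward_standard,
    gradient,
    logit_personalized,
    logit_standard,
    loss,
    params_from_json,
    params_to_json,
    personalized_code_weights,
)
from ltr_ehr.ltr_models import canonicalize_orientation
from tests.conftest import random_params, random_sample


class TestForwardStandard:
    def test_zero_logit_gives_half(self):
        rng = np.random.default_rng(0)
        s = random_sample(rng, M=6, D=8, d=4)
        s.x = np.zeros(4)
        p = StandardLTRParams(u=np.zeros(6), v=rng.normal(size=12), b=0.0)
        assert forward_standard(p, s) == 0.5

    def test_bilinear_scale_invariance(self):
        rng = np.random.default_rng(1)
        s = random_sample(rng, M=6, D=8, d=4)
        p = random_params(rng, 6, 8, 4)
        v2 = p.v.copy()
        v2[:8] /= 2
        p2 = StandardLTRParams(u=2 * p.u, v=v2, b=p.b)
        assert forward_standard(p, s) == pytest.approx(forward_standard(p2, s), abs=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            M, D, d = 7, 6, 2
            s = random_sample(rng, M, D, d)
            p = random_params(rng, M, D, d)
            expected = p.b + sum(s.x[k] * p.v[D + k] for k in range(d))
            for m in range(M):
                for k in range(D):
                    expected += p.u[m] * s.X[m, k] * p.v[k]
            assert logit_standard(p, s) == pytest.approx(expected, abs=1e-10)

    def test_dimension_mismatch(self):
        rng = np.random.default_rng(3)
        s = random_sample(rng, M=6, D=8, d=4)
        with pytest.raises(InvalidArgumentError):
            forward_standard(StandardLTRParams(u=np.zeros(5), v=np.zeros(12), b=0.0), s)


class TestForwardPersonalized:
    def test_zero_logit_gives_half(self):
        rng = np.random.default_rng(4)
        s = random_sample(rng, M=6, D=8, d=4)
        s.x = np.zeros(4)
        p = PersonalizedLTRParams(w=np.zeros(8), v=rng.normal(size=12), b=0.0)
        assert forward_personalized(p, s) == 0.5

    def test_gram_equals_attention_route(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            s = random_sample(rng, M=9, D=5, d=3, n_codes=int(rng.integers(0, 6)))
            p = random_params(rng, 9, 5, 3, kind="personalized")
            zg = logit_personalized(p, s, via="gram")
            za = logit_personalized(p, s, via="attention")
            assert zg == pytest.approx(za, abs=1e-10)

    def test_single_code_weight_is_dot_product(self, vocab20, emb_true):
        from ltr_ehr import build_sample_tensor, apply_pe
        from ltr_ehr.synthetic_cohort import VisitPair

        pair = VisitPair(patient_id="P0", codes=[vocab20.codes[4]], labs=np.zeros(4),
                         elapsed_days=60.0, label=1)
        s = apply_pe(build_sample_tensor(pair, emb_true))
        rng = np.random.default_rng(6)
        p = random_params(rng, 20, 8, 4, kind="personalized")
        u_i = personalized_code_weights(p, s)
        assert np.count_nonzero(u_i) <= 1
        assert u_i[4] == pytest.approx(s.X[4] @ p.w, abs=1e-12)

    def test_tanh_output_in_unit_interval(self):
        rng = np.random.default_rng(7)
        s = random_sample(rng, M=6, D=8, d=4)
        p = random_params(rng, 6, 8, 4, kind="personalized")
        pt = forward_personalized(p, s, output="tanh")
        assert 0.0 <= pt <= 1.0


class TestLoss:
    def test_zero_params_ln2(self):
        rng = np.random.default_rng(8)
        batch = [random_sample(rng, 6, 8, 4) for _ in range(5)]
        for b in batch:
            b.x = np.zeros(4)
        p = StandardLTRParams(u=np.zeros(6), v=np.zeros(12), b=0.0)
        assert loss(p, batch, LossConfig(0.0)) == pytest.approx(np.log(2), abs=1e-12)

    def test_confident_predictions_vanishing_loss(self):
        rng = np.random.default_rng(9)
        batch = []
        for _ in range(6):
            s = random_sample(rng, 4, 8, 4, n_codes=0)
            s.X[:] = 0.0
            s.x = np.zeros(4)
            batch.append(s)
        # drive each sample's logit to +/-12 via the intercept-matching labels
        for s in batch:
            s.y = 1
        p = StandardLTRParams(u=np.zeros(4), v=np.zeros(12), b=12.0)
        assert loss(p, batch, LossConfig(0.0)) < 1e-3

    def test_matches_scalar_resummation(self):
        rng = np.random.default_rng(10)
        batch = [random_sample(rng, 6, 4, 2) for _ in range(7)]
        p = random_params(rng, 6, 4, 2)
        lam = 0.1
        total = 0.0
        for s in batch:
            z = logit_standard(p, s)
            prob = 1 / (1 + np.exp(-z))
            total += -(s.y * np.log(prob) + (1 - s.y) * np.log(1 - prob))
        expected = total / len(batch) + lam * np.abs(p.u).sum()
        assert loss(p, batch, LossConfig(lam)) == pytest.approx(expected, abs=1e-10)

    def test_scale_invariance_at_lambda_zero(self):
        rng = np.random.default_rng(11)
        batch = [random_sample(rng, 6, 4, 2) for _ in range(5)]
        p = random_params(rng, 6, 4, 2)
        v2 = p.v.copy()
        v2[:4] /= 3.0
        p2 = StandardLTRParams(u=3.0 * p.u, v=v2, b=p.b)
        assert loss(p, batch, LossConfig(0.0)) == pytest.approx(
            loss(p2, batch, LossConfig(0.0)), abs=1e-10
        )

    def test_empty_batch_rejected(self):
        rng = np.random.default_rng(12)
        p = random_params(rng, 6, 4, 2)
        with pytest.raises(InvalidArgumentError):
            loss(p, [], LossConfig(0.0))

    def test_probabilities_clamped_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(13)
        s = random_sample(rng, 4, 8, 4)
        p = StandardLTRParams(u=1e6 * np.ones(4), v=np.ones(12), b=1e6)
        prob = forward_standard(p, s)
        assert 0.0 < prob < 1.0


def _fd_gradient(params, batch, cfg, eps=1e-6):
    """Central finite differences over every coordinate."""

    def f(p):
        return loss(p, batch, cfg)

    g = {}
    for name in ("u", "w", "v"):
        if not hasattr(params, name):
            continue
        arr = getattr(params, name)
        out = np.zeros_like(arr)
        for i in range(arr.size):
            pp, pm = params.copy(), params.copy()
            getattr(pp, name)[i] += eps
            getattr(pm, name)[i] -= eps
            out[i] = (f(pp) - f(pm)) / (2 * eps)
        g[name] = out
    pp, pm = params.copy(), params.copy()
    pp.b += eps
    pm.b -= eps
    g["b"] = (f(pp) - f(pm)) / (2 * eps)
    return g


@pytest.mark.parametrize("kind", ["standard", "personalized"])
@pytest.mark.parametrize("lam", [0.0, 0.1])
class TestGradient:
    def test_matches_central_finite_differences(self, kind, lam):
        rng = np.random.default_rng(14)
        batch = [random_sample(rng, 6, 4, 2) for _ in range(5)]
        params = random_params(rng, 6, 4, 2, kind=kind)  # nonzero coords for lam>0
        cfg = LossConfig(lam)
        g = gradient(params, batch, cfg)
        fd = _fd_gradient(params, batch, cfg)
        name = "u" if kind == "standard" else "w"
        for attr, expected in ((name, fd[name]), ("v", fd["v"])):
            got = getattr(g, attr)
            np.testing.assert_allclose(got, expected, rtol=1e-5, atol=1e-8)
        assert g.b == pytest.approx(fd["b"], rel=1e-5, abs=1e-8)


class TestGradientConventions:
    def test_l1_subgradient_zero_at_zero_coordinates(self):
        rng = np.random.default_rng(15)
        batch = [random_sample(rng, 6, 4, 2) for _ in range(4)]
        p = random_params(rng, 6, 4, 2)
        p.u[[1, 3]] = 0.0
        g0 = gradient(p, batch, LossConfig(0.0))
        g1 = gradient(p, batch, LossConfig(0.5))
        np.testing.assert_allclose(g1.u[[1, 3]], g0.u[[1, 3]], atol=1e-15)
        nz = [0, 2, 4, 5]
        np.testing.assert_allclose(g1.u[nz] - g0.u[nz], 0.5 * np.sign(p.u[nz]), atol=1e-12)

    def test_balanced_symmetric_batch_has_zero_intercept_gradient(self):
        rng = np.random.default_rng(16)
        batch = []
        for y in (0, 1, 0, 1):
            s = random_sample(rng, 4, 4, 2, n_codes=0)
            s.X[:] = 0.0
            s.x = np.zeros(2)
            s.y = y
            batch.append(s)
        p = StandardLTRParams(u=np.zeros(4), v=np.zeros(6), b=0.0)
        g = gradient(p, batch, LossConfig(0.0))
        assert g.b == pytest.approx(0.0, abs=1e-15)


class TestCanonicalization:
    def test_orientation_flip_preserves_predictions(self):
        rng = np.random.default_rng(17)
        s = random_sample(rng, 6, 8, 4)
        p = random_params(rng, 6, 8, 4)
        p.u = -np.abs(p.u)  # force a flip
        u2, v2 = canonicalize_orientation(p.u, p.v, 8)
        p2 = StandardLTRParams(u=u2, v=v2, b=p.b)
        assert u2.sum() > 0
        assert forward_standard(p, s) == pytest.approx(forward_standard(p2, s), abs=1e-12)

    def test_already_canonical_untouched(self):
        u = np.array([1.0, 2.0, -0.5])
        v = np.arange(6.0)
        u2, v2 = canonicalize_orientation(u, v, 4)
        np.testing.assert_array_equal(u, u2)
        np.testing.assert_array_equal(v, v2)


class TestPersistence:
    @pytest.mark.parametrize("kind", ["standard", "personalized"])
    def test_json_round_trip_exact(self, kind, tmp_path):
        rng = np.random.default_rng(18)
        p = random_params(rng, 6, 8, 4, kind=kind)
        path = tmp_path / "params.json"
        params_to_json(p, path, extra={"lambda": 0.01})
        back = params_from_json(path)
        assert type(back) is type(p)
        np.testing.assert_array_equal(back.v, p.v)
        assert back.b == p.b
        name = "u" if kind == "standard" else "w"
        np.testing.assert_array_equal(getattr(back, name), getattr(p, name))
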
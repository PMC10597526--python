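"""Mutation-effect estimators against closed-form and brute-force oracles."""

import autograd.numpy as anp
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnacoding.attribution import (
    MutationEffectMatrix,
    agreement_with_ism,
    ig_uniform_ism,
    input_gradient,
    integrated_gradients,
    inter_replicate_agreement,
    ism,
    make_score_fn,
    mdig,
    median_positionwise_cosine,
    pearson_flat,
    sign_convention_diagnostic,
    taylor,
    tune_beta,
)
from rnacoding.model import ModelConfig, init_params, one_hot
from rnacoding.sequences import Transcript

SEQ = "GAUGAAACCCUAAG"


def _linear_score_fn(w):
    """S(x) = sum_ik w_ik x_ik — every estimator is exact on this scorer."""

    def score(xb):
        return anp.sum(w * xb, axis=(-2, -1))

    return score


def _linear_ism_oracle(w, seq):
    """Closed form: delta-S(i, j->b) = w_ib - w_ij."""
    base_idx = {b: k for k, b in enumerate("ACGU")}
    out = np.zeros((len(seq), 3))
    for i, ref in enumerate(seq):
        j = base_idx[ref]
        c = 0
        for k in range(4):
            if k == j:
                continue
            out[i, c] = w[i, k] - w[i, j]
            c += 1
    return out


@pytest.fixture(scope="module")
def w():
    return np.random.RandomState(0).randn(len(SEQ), 4)


class TestLinearOracle:
    def test_ism_closed_form(self, w):
        m = ism(_linear_score_fn(w), transcript=SEQ)
        assert m.values.shape == (len(SEQ), 3)
        assert np.abs(m.values - _linear_ism_oracle(w, SEQ)).max() < 1e-9

    def test_taylor_equals_ism(self, w):
        fn = _linear_score_fn(w)
        assert np.abs(taylor(fn, transcript=SEQ).values - ism(fn, transcript=SEQ).values).max() < 1e-9

    def test_ig_uniform_equals_ism(self, w):
        fn = _linear_score_fn(w)
        m = ig_uniform_ism(fn, transcript=SEQ, steps=4)
        assert np.abs(m.values - ism(fn, transcript=SEQ).values).max() < 1e-9

    def test_mdig_beta_one_equals_ism(self, w):
        fn = _linear_score_fn(w)
        m = mdig(fn, transcript=SEQ, beta=1.0, steps=2)
        assert np.abs(m.values - ism(fn, transcript=SEQ).values).max() < 1e-9

    def test_mdig_scales_with_beta(self, w):
        fn = _linear_score_fn(w)
        half = mdig(fn, transcript=SEQ, beta=0.5, steps=2)
        full = ism(fn, transcript=SEQ)
        assert np.abs(half.values - 0.5 * full.values).max() < 1e-9

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_estimator_equivalence_property(self, seed):
        w = np.random.RandomState(seed).randn(len(SEQ), 4)
        fn = _linear_score_fn(w)
        ref = ism(fn, transcript=SEQ).values
        assert np.abs(taylor(fn, transcript=SEQ).values - ref).max() < 1e-6
        assert np.abs(ig_uniform_ism(fn, transcript=SEQ, steps=2).values - ref).max() < 1e-6
        assert np.abs(mdig(fn, transcript=SEQ, beta=1.0, steps=2).values - ref).max() < 1e-6


class TestIsmContract:
    def test_shape_and_batching_invariance(self):
        w = np.random.RandomState(1).randn(len(SEQ), 4)
        fn = _linear_score_fn(w)
        a = ism(fn, transcript=SEQ, batch_size=7).values
        b = ism(fn, transcript=SEQ, batch_size=512).values
        assert np.array_equal(a, b)

    def test_alt_bases_exclude_endogenous(self):
        m = ism(_linear_score_fn(np.zeros((len(SEQ), 4))), transcript=SEQ)
        alts = m.alt_bases()
        for i, ref in enumerate(SEQ):
            assert ref not in alts[i]
            assert len(set(alts[i])) == 3

    def test_dense_roundtrip(self):
        w = np.random.RandomState(2).randn(len(SEQ), 4)
        m = ism(_linear_score_fn(w), transcript=SEQ)
        dense = m.to_dense()
        base_idx = {b: k for k, b in enumerate("ACGU")}
        for i, ref in enumerate(SEQ):
            assert dense[i, base_idx[ref]] == 0.0


class TestIntegratedGradients:
    def test_zero_path(self):
        w = np.random.RandomState(0).randn(6, 4)
        x = one_hot("ACGUAC")
        attr, resid = integrated_gradients(_linear_score_fn(w), x, x, steps=3)
        assert np.allclose(attr, 0)
        assert resid < 1e-9

    def test_linear_exact_at_any_steps(self):
        w = np.random.RandomState(1).randn(6, 4)
        x = one_hot("ACGUAC")
        baseline = np.full_like(x, 0.25)
        for steps in (1, 3, 16):
            attr, resid = integrated_gradients(_linear_score_fn(w), x, baseline, steps=steps)
            assert np.allclose(attr, (x - baseline) * w, atol=1e-9)
            assert resid < 1e-7

    def test_steps_validated(self):
        x = one_hot("AC")
        with pytest.raises(ValueError):
            integrated_gradients(_linear_score_fn(np.zeros((2, 4))), x, x, steps=0)

    def test_completeness_residual_shrinks_on_nonlinear_model(self):
        cfg = ModelConfig(window_length=6, hidden_dim=8, n_heads=2,
                          n_encoder_layers=1, n_decoder_layers=1)
        params = init_params(cfg, seed=0)
        fn = make_score_fn(params, cfg)
        x = one_hot("AUGGCACGUAUC")
        baseline = np.full_like(x, 0.25)
        residuals = [integrated_gradients(fn, x, baseline, steps=s)[1] for s in (2, 4, 8, 16, 32)]
        assert residuals[-1] < residuals[0]
        # monotone within a small noise allowance
        for a, b in zip(residuals, residuals[1:]):
            assert b <= a * 1.25


class TestGradients:
    def test_zero_gradient_gives_zero_taylor(self):
        fn = _linear_score_fn(np.zeros((len(SEQ), 4)))
        assert np.allclose(taylor(fn, transcript=SEQ).values, 0)

    def test_input_gradient_matches_finite_difference_on_model(self):
        cfg = ModelConfig(window_length=6, hidden_dim=8, n_heads=2,
                          n_encoder_layers=1, n_decoder_layers=1)
        params = init_params(cfg, seed=1)
        fn = make_score_fn(params, cfg)
        seq = "AUGGCACG"
        g = input_gradient(fn, transcript=seq)
        x = one_hot(seq)
        eps = 1e-5
        for idx in [(0, 0), (3, 2), (7, 3)]:
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            fd = (float(fn(xp[None])[0]) - float(fn(xm[None])[0])) / (2 * eps)
            assert g[idx] == pytest.approx(fd, abs=1e-4)


class TestMdigValidation:
    @pytest.mark.parametrize("beta", [0.0, -0.2, 1.5])
    def test_beta_range(self, beta):
        with pytest.raises(ValueError):
            mdig(_linear_score_fn(np.zeros((len(SEQ), 4))), transcript=SEQ, beta=beta)

    def test_sign_diagnostic_reports(self):
        cfg = ModelConfig(window_length=6, hidden_dim=8, n_heads=2,
                          n_encoder_layers=1, n_decoder_layers=1)
        params = init_params(cfg, seed=2)
        t = Transcript("t", "AUGGCACGUAUCGGA", "NC")
        d = sign_convention_diagnostic(params, cfg, t, beta=0.5, steps=4)
        assert d["better"] in ("plus", "minus")
        assert -1 <= d["pearson_plus"] <= 1


def _mat(values):
    L = len(values)
    return MutationEffectMatrix(np.asarray(values, dtype=float), "A" * L, method="ism")


class TestAgreementMetrics:
    def test_identity(self):
        m = _mat(np.random.RandomState(0).randn(5, 3))
        assert pearson_flat(m, m) == pytest.approx(1.0)
        assert median_positionwise_cosine(m, m) == pytest.approx(1.0)

    def test_negation(self):
        m = np.random.RandomState(1).randn(5, 3)
        assert pearson_flat(m, -m) == pytest.approx(-1.0)

    def test_hand_cosine(self):
        a = np.array([[1.0, 0.0, 0.0]])
        b = np.array([[1.0, 1.0, 0.0]])
        assert median_positionwise_cosine(a, b) == pytest.approx(1 / np.sqrt(2))

    def test_inter_replicate_mean_over_pairs(self):
        A, B, C = object(), object(), object()
        table = {frozenset([id(A), id(B)]): 1.0,
                 frozenset([id(A), id(C)]): 0.5,
                 frozenset([id(B), id(C)]): 0.5}
        metric = lambda x, y: table[frozenset([id(x), id(y)])]
        assert inter_replicate_agreement([A, B, C], metric) == pytest.approx(2 / 3)

    def test_two_replicates_single_pair(self):
        m1 = _mat(np.random.RandomState(0).randn(4, 3))
        m2 = _mat(np.random.RandomState(1).randn(4, 3))
        assert inter_replicate_agreement([m1, m2]) == pytest.approx(pearson_flat(m1, m2))

    def test_agreement_with_ism_matched_pairs(self):
        metric = lambda x, y: 0.25 if x is y else 0.75
        a, b = object(), object()
        assert agreement_with_ism([a, b], [a, object()], metric) == pytest.approx(0.5)

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError):
            inter_replicate_agreement([_mat(np.zeros((2, 3)))])


def test_tune_beta_prefers_exact_setting():
    """On a linear scorer MDIG is exact at every beta; the tuner must return a
    grid member with correlation ~1."""
    w = np.random.RandomState(3).randn(len(SEQ), 4)
    fn = _linear_score_fn(w)
    t = Transcript("t", SEQ, "NC")
    best, results = tune_beta(fn, None, [t], grid=(0.25, 1.0), steps=2)
    assert best in (0.25, 1.0)
    assert results[1.0] == pytest.approx(1.0, abs=1e-9)
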
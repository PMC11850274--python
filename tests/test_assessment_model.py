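"""The assessment network against an independent brute-force oracle."""

import numpy as np
import pytest

from stylegauge.embedding import EmbeddedSequence
from stylegauge.assessment_model import (
    ModelConfig,
    attention_report,
    backward_batch,
    forward,
    forward_batch,
    init_params,
    load_checkpoint,
    loss_and_grads,
    make_ablation,
    mse_loss,
    save_checkpoint,
)

from conftest import make_post


# -- independent oracle: the network composed step by step, scalar style ----


def _sig(x):
    return 1.0 / (1.0 + np.exp(-x))


def oracle_forward(params, X, reps, cfg):
    """Naive single-sequence composition of the architecture: two LSTM
    layers, tanh attention scores, Att^T H pooling, concatenation with
    the six set representations, two tanh affine layers."""
    seq = X
    for layer in ("lstm1", "lstm2"):
        W, U, b = params[f"{layer}_W"], params[f"{layer}_U"], params[f"{layer}_b"]
        H = U.shape[0]
        h = np.zeros(H)
        c = np.zeros(H)
        outs = []
        for t in range(seq.shape[0]):
            z = seq[t] @ W + h @ U + b
            i, f = _sig(z[:H]), _sig(z[H : 2 * H])
            g, o = np.tanh(z[2 * H : 3 * H]), _sig(z[3 * H :])
            c = f * c + i * g
            h = o * np.tanh(c)
            outs.append(h.copy())
        seq = np.stack(outs)
    H2 = seq
    if cfg.ablation == "no_attention":
        pooled = H2.mean(axis=0)
        att = None
    else:
        att = np.tanh(H2 @ params["W1"][:, 0] + params["b1"][0])
        pooled = att @ H2
    C = pooled if cfg.ablation == "no_injection" else np.concatenate([pooled, reps])
    U_ = np.tanh(C @ params["W2"] + params["b2"])
    y = np.tanh(U_ @ params["W3"] + params["b3"])
    return y, att, pooled, C


def toy_setup(n=3, d_e=3, d_h=4, d_w=2, d_u=5, ablation="full", seed=0):
    cfg = ModelConfig(d_e=d_e, d_h=d_h, d_w=d_w, d_u=d_u, ablation=ablation, seed=seed)
    params = init_params(cfg)
    rng = np.random.default_rng(seed + 1)
    X = rng.standard_normal((n, d_e))
    reps = rng.standard_normal(6 * d_w)
    return cfg, params, X, reps


class TestInitParams:
    def test_seed_reproducibility(self):
        cfg = ModelConfig(d_e=8, d_h=4, d_w=2, seed=9)
        p1, p2 = init_params(cfg), init_params(cfg)
        assert all(np.array_equal(p1[k], p2[k]) for k in p1)

    def test_published_concat_width(self):
        cfg = ModelConfig(d_e=384, d_h=300, d_w=300, d_u=128)
        assert cfg.concat_width == 2100
        assert init_params(cfg)["W2"].shape == (2100, 128)

    def test_toy_concat_width(self):
        cfg = ModelConfig(d_e=5, d_h=4, d_w=2)
        assert init_params(cfg)["W2"].shape[0] == 4 + 6 * 2

    def test_no_injection_width(self):
        cfg = ModelConfig(d_e=5, d_h=4, d_w=2, ablation="no_injection")
        assert cfg.concat_width == 4


class TestForwardOracle:
    @pytest.mark.parametrize(
        "n,d_e,d_h,d_w,ablation",
        [
            (1, 2, 2, 1, "full"),
            (3, 3, 4, 2, "full"),
            (2, 4, 3, 4, "full"),
            (3, 3, 4, 2, "no_attention"),
            (3, 3, 4, 2, "no_injection"),
        ],
    )
    def test_matches_bruteforce_composition(self, n, d_e, d_h, d_w, ablation):
        cfg, params, X, reps = toy_setup(n, d_e, d_h, d_w, ablation=ablation)
        trace = forward(EmbeddedSequence("u", X), reps, params, cfg)
        y_exp, att_exp, pooled_exp, C_exp = oracle_forward(params, X, reps, cfg)
        assert np.allclose(trace.scores, y_exp, atol=1e-6)
        assert np.allclose(trace.pooled, pooled_exp, atol=1e-6)
        assert np.allclose(trace.concat, C_exp, atol=1e-6)
        if att_exp is not None:
            assert np.allclose(trace.attention, att_exp, atol=1e-6)

    def test_handset_single_step(self):
        """n=1 with hand-set parameters, all arithmetic worked out below."""
        cfg = ModelConfig(d_e=1, d_h=1, d_w=1, d_u=1, seed=0)
        params = init_params(cfg)
        for k in params:
            params[k] = np.zeros_like(params[k])
        params["lstm1_W"][:] = 1.0   # gates: i=f=g=o share pre-activation x
        params["lstm2_W"][:] = 1.0
        params["W1"][:] = 1.0
        params["W2"][:] = 1.0
        params["W3"][:] = 1.0
        x = 2.0
        # layer 1: z=2 -> i=o=f=sig(2), g=tanh(2); c=i*g; h1=o*tanh(c)
        i = _sig(2.0)
        c1 = i * np.tanh(2.0)
        h1 = i * np.tanh(c1)
        # layer 2 input h1
        i2 = _sig(h1)
        c2 = i2 * np.tanh(h1)
        h2 = i2 * np.tanh(c2)
        att = np.tanh(h2)
        pooled = att * h2
        C = pooled + 6 * 0.5  # six scalar reps of 0.5 each, W2 all ones
        u = np.tanh(C)
        y = np.tanh(u)
        trace = forward(
            EmbeddedSequence("u", np.array([[x]])), np.full(6, 0.5), params, cfg
        )
        assert np.allclose(trace.scores, [y, y, y], atol=1e-6)

    def test_outputs_strictly_inside_unit_cube(self):
        cfg, params, X, reps = toy_setup(n=4)
        trace = forward(EmbeddedSequence("u", X * 50), reps * 50, params, cfg)
        assert np.all(np.abs(trace.scores) < 1.0)


class TestBatchingAndMasking:
    def test_batched_equals_one_by_one(self):
        cfg, params, _, reps = toy_setup()
        rng = np.random.default_rng(2)
        seqs = [rng.standard_normal((n, cfg.d_e)) for n in (1, 3, 2)]
        n_max = 3
        X = np.zeros((3, n_max, cfg.d_e))
        mask = np.zeros((3, n_max))
        for b, s in enumerate(seqs):
            X[b, : len(s)] = s
            mask[b, : len(s)] = 1
        Y_batch, _ = forward_batch(params, X, mask, reps, cfg)
        for b, s in enumerate(seqs):
            trace = forward(EmbeddedSequence("u", s), reps, params, cfg)
            assert np.allclose(Y_batch[b], trace.scores, atol=1e-6)

    def test_padding_does_not_leak(self):
        cfg, params, _, reps = toy_setup()
        rng = np.random.default_rng(3)
        s = rng.standard_normal((2, cfg.d_e))
        X1 = s[None]
        X2 = np.concatenate([s, 99.0 * np.ones((3, cfg.d_e))])[None]
        m1 = np.ones((1, 2))
        m2 = np.array([[1, 1, 0, 0, 0.0]])
        Y1, _ = forward_batch(params, X1, m1, reps, cfg)
        Y2, _ = forward_batch(params, X2, m2, reps, cfg)
        assert np.allclose(Y1, Y2, atol=1e-10)

    def test_no_attention_pooling_is_masked_mean(self):
        cfg, params, X, reps = toy_setup(ablation="no_attention")
        trace = forward(EmbeddedSequence("u", X), reps, params, cfg)
        assert np.allclose(trace.pooled, trace.hidden.mean(axis=0), atol=1e-10)


class TestGradients:
    @pytest.mark.parametrize("ablation", ["full", "no_attention", "no_injection"])
    def test_finite_difference_check(self, ablation):
        """Analytic gradients match central differences to 1e-4."""
        cfg, params, _, reps = toy_setup(n=3, ablation=ablation, seed=4)
        rng = np.random.default_rng(5)
        X = rng.standard_normal((2, 3, cfg.d_e))
        mask = np.array([[1, 1, 1], [1, 1, 0.0]])
        T = rng.uniform(-0.8, 0.8, (2, 3))
        _, grads = loss_and_grads(params, X, mask, reps, T, cfg)
        eps = 1e-6
        for k, P in params.items():
            flat = P.reshape(-1)
            for idx in rng.choice(flat.size, size=min(6, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = loss_and_grads(params, X, mask, reps, T, cfg)
                flat[idx] = orig - eps
                lm, _ = loss_and_grads(params, X, mask, reps, T, cfg)
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[k].reshape(-1)[idx] == pytest.approx(num, abs=1e-4)

    def test_forward_deterministic(self):
        cfg, params, X, reps = toy_setup()
        t1 = forward(EmbeddedSequence("u", X), reps, params, cfg)
        t2 = forward(EmbeddedSequence("u", X), reps, params, cfg)
        assert np.array_equal(t1.scores, t2.scores)


def test_set_representation_order_matters():
    """Permuting the six injected representations changes the output, so
    the concatenation order is a fixed part of the contract."""
    cfg, params, X, reps = toy_setup(seed=6)
    reps_mat = reps.reshape(6, cfg.d_w)
    permuted = reps_mat[[1, 0, 2, 3, 5, 4]].ravel()
    y1 = forward(EmbeddedSequence("u", X), reps, params, cfg).scores
    y2 = forward(EmbeddedSequence("u", X), permuted, params, cfg).scores
    assert not np.allclose(y1, y2)


class TestAttentionReport:
    def _posts_and_trace(self, n=4):
        cfg, params, X, reps = toy_setup(n=n, seed=7)
        posts = [make_post(f"post {i}", day=i) for i in range(n)]
        trace = forward(EmbeddedSequence("u", X), reps, params, cfg)
        return posts, trace

    def test_weights_sum_to_one(self):
        posts, trace = self._posts_and_trace()
        report = attention_report(posts, trace)
        assert sum(e["weight"] for e in report) == pytest.approx(1.0, abs=1e-9)
        assert [e["rank"] for e in report] == [1, 2, 3, 4]

    def test_equal_scores_uniform_weights(self):
        posts, trace = self._posts_and_trace()
        trace.attention = np.zeros(len(posts))
        report = attention_report(posts, trace)
        assert all(e["weight"] == pytest.approx(0.25) for e in report)

    def test_length_mismatch_errors(self):
        posts, trace = self._posts_and_trace()
        with pytest.raises(ValueError):
            attention_report(posts[:-1], trace)


class TestAblation:
    def test_variants(self):
        cfg = ModelConfig(d_e=4, d_h=3, d_w=2)
        assert make_ablation(cfg, "no_attention").ablation == "no_attention"
        assert make_ablation(cfg, "no_injection").concat_width == 3

    @pytest.mark.parametrize("bad", ["full", "identity", ""])
    def test_must_name_a_variant(self, bad):
        with pytest.raises(ValueError):
            make_ablation(ModelConfig(d_e=4, d_h=3, d_w=2), bad)


def test_checkpoint_round_trip(tmp_path):
    cfg, params, X, reps = toy_setup(seed=8)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(str(path), params, cfg)
    params2, cfg2 = load_checkpoint(str(path))
    assert cfg2 == cfg
    assert all(np.array_equal(params[k], params2[k]) for k in params)
    y1 = forward(EmbeddedSequence("u", X), reps, params, cfg).scores
    y2 = forward(EmbeddedSequence("u", X), reps, params2, cfg2).scores
    assert np.array_equal(y1, y2)


def test_width_mismatch_names_stage():
    cfg, params, X, reps = toy_setup()
    with pytest.raises(ValueError, match="embedding stage"):
        forward(EmbeddedSequence("u", X[:, :-1]), reps, params, cfg)
    with pytest.raises(ValueError, match="injection stage"):
        forward(EmbeddedSequence("u", X), reps[:-1], params, cfg)
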
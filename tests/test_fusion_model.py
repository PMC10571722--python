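"""Dual-branch network: residual identities, shape algebra, dual oracles.

Oracles here are independent straight-line re-implementations written with
explicit loops/steps, so they share no code path with the vectorized model.
"""

import numpy as np
import pytest
from scipy.special import erf

from cellfusion.fusion_model import (
    Adam,
    ConfigurationError,
    DualGlobalFusionModel,
    MixerBranchConfig,
    ModelConfig,
    ViTBranchConfig,
    attention_fwd,
    desk_model_config,
    fuse,
    init_params,
    mixer_branch_forward,
    mixer_layer,
    mixer_mlp_block,
    predict_risk,
    transformer_layer,
    tree_leaves,
    vit_branch_forward,
    vit_tokenize,
)

# ---------------------------------------------------------------------------
# independent reference implementations
# ---------------------------------------------------------------------------


def ref_gelu(x):
    return 0.5 * x * (1 + erf(x / np.sqrt(2)))


def ref_mlp(x, W1, b1, W2, b2):
    return ref_gelu(x @ W1 + b1) @ W2 + b2


def ref_layernorm(x, g, b, eps=1e-6):
    mu = x.mean(-1, keepdims=True)
    sd = np.sqrt(x.var(-1, keepdims=True) + eps)
    return (x - mu) / sd * g + b


def ref_mixer_layer(Z, p):
    """Literal transcription: Z' = U + MC(U), U = Z + MP(Z)."""
    ln1 = ref_layernorm(Z, p["ln1"]["g"], p["ln1"]["b"])
    mp = ref_mlp(ln1.T, **p["tok"]).T
    U = Z + mp
    ln2 = ref_layernorm(U, p["ln2"]["g"], p["ln2"]["b"])
    return U + ref_mlp(ln2, **p["ch"])


def ref_attention(Z, p, heads):
    """Loop-based multi-head self-attention on a single (S, D) sequence."""
    S, D = Z.shape
    dh = D // heads
    q, k, v = Z @ p["Wq"] + p["bq"], Z @ p["Wk"] + p["bk"], Z @ p["Wv"] + p["bv"]
    ctx = np.zeros((S, D))
    for h in range(heads):
        sl = slice(h * dh, (h + 1) * dh)
        for i in range(S):
            scores = np.array([q[i, sl] @ k[j, sl] / np.sqrt(dh) for j in range(S)])
            w = np.exp(scores - scores.max())
            w /= w.sum()
            ctx[i, sl] = sum(w[j] * v[j, sl] for j in range(S))
    return ctx @ p["Wo"] + p["bo"]


def _layer_params(kind="mixer", S=4, C=3, seed=0, heads=1):
    cfg = ModelConfig(
        input_resolution=8,
        seed=seed,
        mixer=MixerBranchConfig(depth=1, patch_size=4, channel_dim=C, token_mlp_hidden=5, channel_mlp_hidden=6),
        vit=ViTBranchConfig(depth=1, patch_size=4, embed_dim=C * heads, heads=heads, mlp_hidden=5),
    )
    # token-MLP width must match S: rebuild for arbitrary S
    rng = np.random.default_rng(seed)
    if kind == "mixer":
        return {
            "ln1": {"g": rng.normal(1, 0.1, C), "b": rng.normal(0, 0.1, C)},
            "tok": {"W1": rng.normal(0, 0.5, (S, 5)), "b1": rng.normal(0, 0.1, 5),
                    "W2": rng.normal(0, 0.5, (5, S)), "b2": rng.normal(0, 0.1, S)},
            "ln2": {"g": rng.normal(1, 0.1, C), "b": rng.normal(0, 0.1, C)},
            "ch": {"W1": rng.normal(0, 0.5, (C, 6)), "b1": rng.normal(0, 0.1, 6),
                   "W2": rng.normal(0, 0.5, (6, C)), "b2": rng.normal(0, 0.1, C)},
        }
    D = C * heads
    return {
        "ln1": {"g": rng.normal(1, 0.1, D), "b": rng.normal(0, 0.1, D)},
        "attn": {k: rng.normal(0, 0.5, (D, D)) for k in ("Wq", "Wk", "Wv", "Wo")}
        | {k: rng.normal(0, 0.1, D) for k in ("bq", "bk", "bv", "bo")},
        "ln2": {"g": rng.normal(1, 0.1, D), "b": rng.normal(0, 0.1, D)},
        "mlp": {"W1": rng.normal(0, 0.5, (D, 5)), "b1": rng.normal(0, 0.1, 5),
                "W2": rng.normal(0, 0.5, (5, D)), "b2": rng.normal(0, 0.1, D)},
    }


def _zero_mlp(p):
    for k in ("W1", "b1", "W2", "b2"):
        p[k] = np.zeros_like(p[k])


class TestMixerMlpBlock:
    def test_zero_weights_give_zero(self):
        x = np.random.default_rng(0).normal(size=(4, 3))
        out = mixer_mlp_block(x, np.zeros((3, 5)), np.zeros(5), np.zeros((5, 3)), np.zeros(3))
        np.testing.assert_array_equal(out, 0.0)

    def test_identity_then_zero_projection(self):
        x = np.random.default_rng(0).normal(size=(4, 3))
        out = mixer_mlp_block(x, np.eye(3), np.zeros(3), np.zeros((3, 3)), np.zeros(3))
        np.testing.assert_array_equal(out, 0.0)

    def test_matches_straightline_reimplementation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4, 4))
        W1, b1 = rng.normal(size=(4, 7)), rng.normal(size=7)
        W2, b2 = rng.normal(size=(7, 4)), rng.normal(size=4)
        np.testing.assert_allclose(
            mixer_mlp_block(x, W1, b1, W2, b2), ref_mlp(x, W1, b1, W2, b2), atol=1e-6
        )


class TestMixerLayer:
    def test_zero_mlp_weights_is_identity(self):
        p = _layer_params("mixer", S=4, C=3)
        _zero_mlp(p["tok"])
        _zero_mlp(p["ch"])
        Z = np.random.default_rng(2).normal(size=(4, 3))
        np.testing.assert_allclose(mixer_layer(Z, p), Z, atol=1e-12)

    def test_constant_input_zero_token_mixing_gives_identical_tokens(self):
        p = _layer_params("mixer", S=4, C=3)
        _zero_mlp(p["tok"])
        Z = np.ones((4, 3)) * np.array([0.5, -1.0, 2.0])
        out = mixer_layer(Z, p)
        assert np.ptp(out, axis=0).max() < 1e-12  # every token identical

    def test_term_by_term_oracle(self):
        p = _layer_params("mixer", S=4, C=3, seed=5)
        Z = np.random.default_rng(6).normal(size=(4, 3))
        np.testing.assert_allclose(mixer_layer(Z, p), ref_mixer_layer(Z, p), atol=1e-6)


class TestTransformerLayer:
    def test_zero_output_projections_is_identity(self):
        p = _layer_params("vit", C=4, heads=2)
        p["attn"]["Wo"] = np.zeros_like(p["attn"]["Wo"])
        p["attn"]["bo"] = np.zeros_like(p["attn"]["bo"])
        p["mlp"]["W2"] = np.zeros_like(p["mlp"]["W2"])
        p["mlp"]["b2"] = np.zeros_like(p["mlp"]["b2"])
        Z = np.random.default_rng(3).normal(size=(5, 8))
        np.testing.assert_allclose(transformer_layer(Z, p, heads=2), Z, atol=1e-12)

    def test_single_token_closed_form(self):
        # softmax over one key is 1: MSA is a value then output projection
        p = _layer_params("vit", C=4, heads=2)
        z = np.random.default_rng(4).normal(size=(1, 8))
        out, _ = attention_fwd(z[None], p["attn"], heads=2)
        expected = (z @ p["attn"]["Wv"] + p["attn"]["bv"]) @ p["attn"]["Wo"] + p["attn"]["bo"]
        np.testing.assert_allclose(out[0], expected, atol=1e-10)

    def test_attention_matches_loop_reimplementation(self):
        p = _layer_params("vit", C=4, heads=2, seed=7)
        Z = np.random.default_rng(8).normal(size=(4, 8))
        out, _ = attention_fwd(Z[None], p["attn"], heads=2)
        np.testing.assert_allclose(out[0], ref_attention(Z, p["attn"], 2), atol=1e-6)

    def test_bad_head_divisibility(self):
        with pytest.raises(ConfigurationError):
            ViTBranchConfig(embed_dim=10, heads=4)


class TestBranchForwards:
    def test_full_profile_feature_lengths_and_token_count(self):
        cfg = ModelConfig(seed=0)
        assert (cfg.input_resolution // cfg.mixer.patch_size) ** 2 == 1024
        params = init_params(cfg, np.random.default_rng(0))
        x = np.random.default_rng(1).normal(size=(1, 3, 256, 256))
        z1 = mixer_branch_forward(x, cfg.mixer, params["mixer"])
        z2 = vit_branch_forward(x, cfg.vit, params["vit"])
        assert z1.shape == (1, 128)
        assert z2.shape == (1, 128)

    def test_zero_weight_network_emits_zero_feature(self):
        cfg = desk_model_config(seed=0)
        params = init_params(cfg, np.random.default_rng(0))
        for path, arr in tree_leaves(params):
            arr[...] = 0.0
        x = np.random.default_rng(2).normal(size=(2, 3, 64, 64))
        np.testing.assert_allclose(mixer_branch_forward(x, cfg.mixer, params["mixer"]), 0.0, atol=1e-12)
        np.testing.assert_allclose(vit_branch_forward(x, cfg.vit, params["vit"]), 0.0, atol=1e-12)

    def test_vit_tokenize_arithmetic_and_permutation_equivariance(self):
        cfg = desk_model_config(seed=0)
        rng = np.random.default_rng(3)
        S = (64 // 4) ** 2
        E = rng.normal(size=(3 * 16, 8))
        b = np.zeros(8)
        x = rng.normal(size=(3, 64, 64))
        tokens = vit_tokenize(x, E, b, np.zeros((S, 8)), patch_size=4)
        assert tokens.shape == (1, S, 8)
        # zero projection and zero position embedding -> zero tokens
        np.testing.assert_array_equal(
            vit_tokenize(x, np.zeros_like(E), b, np.zeros((S, 8)), 4), 0.0
        )
        # permuting patches permutes tokens identically when E_pos = 0
        x4 = x.reshape(3, 16, 4, 16, 4)
        x_perm = np.flip(x4, axis=1).reshape(3, 64, 64)  # reverse patch rows
        t_perm = vit_tokenize(x_perm, E, b, np.zeros((S, 8)), 4)
        t_ref = tokens.reshape(1, 16, 16, 8)[:, ::-1].reshape(1, S, 8)
        np.testing.assert_allclose(t_perm, t_ref, atol=1e-12)

    def test_indivisible_resolution_rejected(self):
        cfg = ModelConfig(input_resolution=100)  # 100 % 8 != 0
        with pytest.raises(ConfigurationError):
            DualGlobalFusionModel(cfg).forward(np.zeros((1, 3, 100, 100)), [0])


class TestFuseAndHead:
    def test_default_fused_length_257(self):
        z = np.zeros((1, 128))
        assert fuse(z, z, np.array([1.0])).shape == (1, 257)

    def test_one_hot_event_coordinate(self):
        fused = fuse(np.zeros((1, 4)), np.zeros((1, 4)), np.array([1.0]))
        assert fused[0, -1] == 1.0
        assert np.abs(fused).sum() == 1.0

    def test_mask_contract(self):
        cfg = desk_model_config(seed=0, mask_event=True)
        model = DualGlobalFusionModel(cfg)
        feats = model.features(np.zeros((2, 3, 64, 64)), np.array([1.0, 1.0]))
        assert (feats[:, -1] == 0).all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse(np.zeros((1, 4)), np.zeros((1, 5)), np.array([0.0]))

    def test_head_zero_weights_return_bias(self):
        out = predict_risk(np.ones((1, 5)), np.zeros((5, 1)), np.array([0.7]))
        assert out[0] == pytest.approx(0.7)

    def test_head_affine_linearity(self):
        rng = np.random.default_rng(9)
        W, b = rng.normal(size=(5, 1)), rng.normal(size=1)
        f = rng.normal(size=(1, 5))
        lhs = predict_risk(3.0 * f, W, b) - b
        rhs = 3.0 * (predict_risk(f, W, b) - b)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_head_hand_arithmetic(self):
        W = np.array([[1.0], [2.0], [-1.0], [0.5], [0.0]])
        f = np.array([1.0, 1.0, 2.0, 4.0, 9.0])
        assert predict_risk(f, W, np.array([0.25]))[0] == pytest.approx(1 + 2 - 2 + 2 + 0 + 0.25)


class TestModelContracts:
    @pytest.mark.parametrize("resolution,patch", [(32, 4), (64, 8), (32, 8)])
    def test_shape_algebra(self, resolution, patch):
        cfg = ModelConfig(
            input_resolution=resolution,
            mixer=MixerBranchConfig(depth=1, patch_size=patch, channel_dim=16, token_mlp_hidden=8, channel_mlp_hidden=8),
            vit=ViTBranchConfig(depth=1, patch_size=patch, embed_dim=16, heads=2, mlp_hidden=8),
        )
        model = DualGlobalFusionModel(cfg)
        x = np.random.default_rng(0).normal(size=(2, 3, resolution, resolution))
        feats = model.features(x, np.array([0.0, 1.0]))
        assert feats.shape == (2, 2 * 16 + 1)
        assert model.forward(x, np.array([0.0, 1.0])).shape == (2,)

    def test_ablation_head_sizes(self):
        assert ModelConfig(variant="fusion").head_input_len() == 257
        assert ModelConfig(variant="mixer").head_input_len() == 129
        assert ModelConfig(variant="vit").head_input_len() == 129

    def test_deterministic_given_seed(self):
        cfg = desk_model_config(seed=11)
        x = np.random.default_rng(1).normal(size=(3, 3, 64, 64))
        mu = np.array([1.0, 0.0, 1.0])
        r1 = DualGlobalFusionModel(cfg).forward(x, mu)
        r2 = DualGlobalFusionModel(cfg).forward(x, mu)
        np.testing.assert_array_equal(r1, r2)

    def test_checkpoint_roundtrip(self, tmp_path):
        model = DualGlobalFusionModel(desk_model_config(seed=4))
        x = np.random.default_rng(2).normal(size=(2, 3, 64, 64))
        mu = np.array([1.0, 0.0])
        model.save(tmp_path / "ckpt.npz")
        back = DualGlobalFusionModel.load(tmp_path / "ckpt.npz")
        assert back.config == model.config
        np.testing.assert_array_equal(back.forward(x, mu), model.forward(x, mu))

    def test_adam_descends_on_toy_objective(self):
        # minimize ||W||^2 via grads = 2 W: Adam should shrink the weights
        params = {"W": np.array([1.0, -2.0, 3.0])}
        opt = Adam(params, lr=0.05, beta1=0.9, weight_decay=0.0)
        for _ in range(200):
            opt.step({"W": 2 * params["W"]})
        assert np.abs(params["W"]).max() < 0.05
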
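"""Dual global-fusion network for survival risk prediction (numpy).

The model consumes a fixed-resolution 3-channel embedded WSI map and emits a
scalar risk on the Cox linear-predictor scale.  Two branches see the same
patchified input:

* a Mixer-style *global* branch: patch embedding to ``C`` channels followed by
  ``L`` Mixer layers, each a token-mixing MLP across spatial positions and a
  channel-mixing MLP across channels, both inside residual paths::

      U   = Z + MP(Z)        MP: LN -> transpose to C x S -> MLP -> transpose
      Z'  = U + MC(U)        MC: LN -> row-wise MLP on channels

* a self-attention *inter-patch* branch: linear patch projection plus learned
  position embeddings, then ``L`` pre-norm transformer layers::

      U   = MSA(LN(Z)) + Z
      Z'  = MLP(LN(U)) + U

Every MLP block is FC -> GELU -> FC.  Each branch mean-pools its tokens into
a feature of length 128 (no CLS token; the classification heads of the parent
architectures are removed).  The two features are concatenated together with
the patient's survival-event scalar mu into a fused vector of length
2*128 + 1 = 257, and a single fully connected layer maps it to the risk.

Including mu as an input is unusual — the event indicator is not knowable at
deployment time, a leakage concern — but it is an explicit part of this
architecture; a ``mask_event`` flag zeroes the coordinate for scenarios where
event status must not be used, and evaluation can report both.

Everything here is plain numpy with hand-derived analytic gradients (each
``*_fwd`` returns a cache consumed by the matching ``*_bwd``); correctness is
pinned by finite-difference checks in the test suite.  Parameters and compute
default to float64 (exactness checks); training uses float32 for speed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.special import erf

LN_EPS = 1e-6
INIT_STD = 0.02
DEFAULT_FEATURE_LEN = 128


class ConfigurationError(ValueError):
    """Raised on invalid shape/config combinations."""


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MixerBranchConfig:
    """Global (token/channel-mixing) branch hyperparameters."""

    depth: int = 2
    patch_size: int = 8
    channel_dim: int = DEFAULT_FEATURE_LEN
    token_mlp_hidden: int = 256
    channel_mlp_hidden: int = 512


@dataclass(frozen=True)
class ViTBranchConfig:
    """Inter-patch (self-attention) branch hyperparameters."""

    depth: int = 2
    patch_size: int = 8
    embed_dim: int = DEFAULT_FEATURE_LEN
    heads: int = 4
    mlp_hidden: int = 256

    def __post_init__(self) -> None:
        if self.embed_dim % self.heads != 0:
            raise ConfigurationError(
                f"embed_dim {self.embed_dim} not divisible by heads {self.heads}"
            )


@dataclass(frozen=True)
class ModelConfig:
    """Full dual-branch model configuration.

    ``variant`` selects the fusion model or a single-branch ablation; the
    head input length is 2*len + 1 for the fusion and len + 1 for either
    ablation (the event scalar is always appended).
    """

    input_resolution: int = 256
    in_channels: int = 3
    variant: Literal["fusion", "mixer", "vit"] = "fusion"
    mask_event: bool = False
    seed: int = 0
    dtype: Literal["float32", "float64"] = "float64"
    mixer: MixerBranchConfig = field(default_factory=MixerBranchConfig)
    vit: ViTBranchConfig = field(default_factory=ViTBranchConfig)

    def head_input_len(self) -> int:
        if self.variant == "fusion":
            return self.mixer.channel_dim + self.vit.embed_dim + 1
        if self.variant == "mixer":
            return self.mixer.channel_dim + 1
        return self.vit.embed_dim + 1


def desk_model_config(seed: int = 0, variant: str = "fusion", mask_event: bool = False) -> ModelConfig:
    """Small profile for CPU-scale experiments (resolution 64, dims 32)."""
    return ModelConfig(
        input_resolution=64,
        variant=variant,  # type: ignore[arg-type]
        mask_event=mask_event,
        seed=seed,
        mixer=MixerBranchConfig(depth=2, patch_size=4, channel_dim=32, token_mlp_hidden=64, channel_mlp_hidden=128),
        vit=ViTBranchConfig(depth=2, patch_size=4, embed_dim=32, heads=4, mlp_hidden=64),
    )


# ---------------------------------------------------------------------------
# primitives (forward + backward pairs)
# ---------------------------------------------------------------------------

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(x: np.ndarray) -> np.ndarray:
    """Exact (erf-based) Gaussian error linear unit."""
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(x / _SQRT2)) + x * _INV_SQRT_2PI * np.exp(-0.5 * x * x)


def linear_fwd(x, W, b):
    return x @ W + b, (x, W)


def linear_bwd(dy, cache):
    x, W = cache
    dx = dy @ W.T
    dW = x.reshape(-1, x.shape[-1]).T @ dy.reshape(-1, dy.shape[-1])
    db = dy.reshape(-1, dy.shape[-1]).sum(axis=0)
    return dx, dW, db


def layernorm_fwd(x, gamma, beta):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + LN_EPS)
    xhat = (x - mu) * inv
    return xhat * gamma + beta, (xhat, inv, gamma)


def layernorm_bwd(dy, cache):
    xhat, inv, gamma = cache
    dgamma = (dy * xhat).reshape(-1, xhat.shape[-1]).sum(axis=0)
    dbeta = dy.reshape(-1, dy.shape[-1]).sum(axis=0)
    dxhat = dy * gamma
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dgamma, dbeta


def mlp_block_fwd(x, p):
    """FC -> GELU -> FC applied along the last axis."""
    h, c1 = linear_fwd(x, p["W1"], p["b1"])
    phi = 0.5 * (1.0 + erf(h / _SQRT2))  # cached: reused by the backward pass
    a = h * phi
    y, c2 = linear_fwd(a, p["W2"], p["b2"])
    return y, (c1, h, phi, c2)


def mlp_block_bwd(dy, cache, p, grads):
    c1, h, phi, c2 = cache
    da, dW2, db2 = linear_bwd(dy, c2)
    dh = da * (phi + h * _INV_SQRT_2PI * np.exp(-0.5 * h * h))
    dx, dW1, db1 = linear_bwd(dh, c1)
    grads["W1"] += dW1
    grads["b1"] += db1
    grads["W2"] += dW2
    grads["b2"] += db2
    return dx


def mixer_mlp_block(x, W1, b1, W2, b2) -> np.ndarray:
    """The Mixer MLP applied row-wise: FC -> GELU -> FC (forward only)."""
    y, _ = mlp_block_fwd(np.asarray(x, dtype=np.float64), {"W1": W1, "b1": b1, "W2": W2, "b2": b2})
    return y


def mixer_layer_fwd(Z, p):
    """One Mixer layer on (B, S, C): token mixing then channel mixing."""
    x1, c_ln1 = layernorm_fwd(Z, p["ln1"]["g"], p["ln1"]["b"])
    xt = np.swapaxes(x1, -1, -2)  # (B, C, S)
    mt, c_tok = mlp_block_fwd(xt, p["tok"])
    U = Z + np.swapaxes(mt, -1, -2)
    x2, c_ln2 = layernorm_fwd(U, p["ln2"]["g"], p["ln2"]["b"])
    mc, c_ch = mlp_block_fwd(x2, p["ch"])
    return U + mc, (c_ln1, c_tok, c_ln2, c_ch)


def mixer_layer_bwd(dout, cache, p, grads):
    c_ln1, c_tok, c_ln2, c_ch = cache
    dx2 = mlp_block_bwd(dout, c_ch, p["ch"], grads["ch"])
    dU_ln, dg2, db2 = layernorm_bwd(dx2, c_ln2)
    grads["ln2"]["g"] += dg2
    grads["ln2"]["b"] += db2
    dU = dout + dU_ln
    dmt = np.swapaxes(dU, -1, -2)
    dxt = mlp_block_bwd(dmt, c_tok, p["tok"], grads["tok"])
    dx1 = np.swapaxes(dxt, -1, -2)
    dZ_ln, dg1, db1 = layernorm_bwd(dx1, c_ln1)
    grads["ln1"]["g"] += dg1
    grads["ln1"]["b"] += db1
    return dU + dZ_ln


def attention_fwd(Z, p, heads):
    """Multi-head self-attention on (B, S, D)."""
    B, S, D = Z.shape
    dh = D // heads
    q, cq = linear_fwd(Z, p["Wq"], p["bq"])
    k, ck = linear_fwd(Z, p["Wk"], p["bk"])
    v, cv = linear_fwd(Z, p["Wv"], p["bv"])
    split = lambda t: t.reshape(B, S, heads, dh).transpose(0, 2, 1, 3)
    qh, kh, vh = split(q), split(k), split(v)
    scores = qh @ np.swapaxes(kh, -1, -2)
    scores /= np.sqrt(dh)
    scores -= scores.max(axis=-1, keepdims=True)
    A = np.exp(scores, out=scores)
    A /= A.sum(axis=-1, keepdims=True)
    ctx = (A @ vh).transpose(0, 2, 1, 3).reshape(B, S, D)
    out, co = linear_fwd(ctx, p["Wo"], p["bo"])
    return out, (cq, ck, cv, qh, kh, vh, A, co, heads, dh)


def attention_bwd(dout, cache, p, grads):
    cq, ck, cv, qh, kh, vh, A, co, heads, dh = cache
    B, S = qh.shape[0], qh.shape[2]
    D = heads * dh
    dctx, dWo, dbo = linear_bwd(dout, co)
    grads["Wo"] += dWo
    grads["bo"] += dbo
    dctx_h = dctx.reshape(B, S, heads, dh).transpose(0, 2, 1, 3)
    dA = dctx_h @ np.swapaxes(vh, -1, -2)
    dvh = np.swapaxes(A, -1, -2) @ dctx_h
    # softmax backward (row-wise), in place on dA
    dA -= (dA * A).sum(axis=-1, keepdims=True)
    dA *= A
    dscores = dA
    dscores /= np.sqrt(dh)
    dqh = dscores @ kh
    dkh = np.swapaxes(dscores, -1, -2) @ qh
    merge = lambda t: t.transpose(0, 2, 1, 3).reshape(B, S, D)
    dZ = np.zeros_like(dout)
    for dt, c, wk, bk_ in ((dqh, cq, "Wq", "bq"), (dkh, ck, "Wk", "bk"), (dvh, cv, "Wv", "bv")):
        dzi, dW, db = linear_bwd(merge(dt), c)
        grads[wk] += dW
        grads[bk_] += db
        dZ += dzi
    return dZ


def transformer_layer_fwd(Z, p, heads):
    """Pre-norm residual transformer layer on (B, S, D)."""
    x1, c_ln1 = layernorm_fwd(Z, p["ln1"]["g"], p["ln1"]["b"])
    att, c_att = attention_fwd(x1, p["attn"], heads)
    U = att + Z
    x2, c_ln2 = layernorm_fwd(U, p["ln2"]["g"], p["ln2"]["b"])
    m, c_mlp = mlp_block_fwd(x2, p["mlp"])
    return m + U, (c_ln1, c_att, c_ln2, c_mlp)


def transformer_layer_bwd(dout, cache, p, grads, heads):
    c_ln1, c_att, c_ln2, c_mlp = cache
    dx2 = mlp_block_bwd(dout, c_mlp, p["mlp"], grads["mlp"])
    dU_ln, dg2, db2 = layernorm_bwd(dx2, c_ln2)
    grads["ln2"]["g"] += dg2
    grads["ln2"]["b"] += db2
    dU = dout + dU_ln
    dx1 = attention_bwd(dU, c_att, p["attn"], grads["attn"])
    dZ_ln, dg1, db1 = layernorm_bwd(dx1, c_ln1)
    grads["ln1"]["g"] += dg1
    grads["ln1"]["b"] += db1
    return dU + dZ_ln


def patchify(x: np.ndarray, patch_size: int) -> np.ndarray:
    """(B, C, R, R) -> (B, S, C * ps * ps) with S = (R / ps)^2."""
    B, C, H, W = x.shape
    if H % patch_size or W % patch_size:
        raise ConfigurationError(f"resolution {H}x{W} not divisible by patch size {patch_size}")
    gh, gw = H // patch_size, W // patch_size
    t = x.reshape(B, C, gh, patch_size, gw, patch_size)
    return t.transpose(0, 2, 4, 1, 3, 5).reshape(B, gh * gw, C * patch_size * patch_size)


def unpatchify_grad(dpatches: np.ndarray, in_shape, patch_size: int) -> np.ndarray:
    B, C, H, W = in_shape
    gh, gw = H // patch_size, W // patch_size
    t = dpatches.reshape(B, gh, gw, C, patch_size, patch_size)
    return t.transpose(0, 3, 1, 4, 2, 5).reshape(B, C, H, W)


def fuse(z1: np.ndarray | None, z2: np.ndarray | None, mu: np.ndarray) -> np.ndarray:
    """Concatenate branch features with the event scalar: [z1; z2; mu].

    Either branch may be absent (single-branch ablations).  Batched: inputs
    are (B, len) and mu is (B,); output (B, total_len + 1).
    """
    mu = np.asarray(mu, dtype=np.float64).reshape(-1, 1)
    parts = [np.asarray(z) for z in (z1, z2) if z is not None]
    if not parts:
        raise ValueError("at least one branch feature required")
    lens = {p.shape[-1] for p in parts}
    if len(parts) == 2 and len(lens) != 1:
        raise ValueError(f"branch feature length mismatch: {sorted(lens)}")
    for p in parts:
        if p.shape[0] != mu.shape[0]:
            raise ValueError("batch size mismatch between features and mu")
    return np.concatenate(parts + [mu], axis=-1)


def predict_risk(fused: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Final fully connected layer: risk = fused @ W + b, shape (B,)."""
    fused = np.atleast_2d(fused)
    if fused.shape[-1] != W.shape[0]:
        raise ValueError(f"fused length {fused.shape[-1]} != head input size {W.shape[0]}")
    return (fused @ W + b).reshape(-1)


# ---------------------------------------------------------------------------
# parameter trees
# ---------------------------------------------------------------------------


def _trunc_normal(rng, shape, std=INIT_STD):
    # clipped-at-2-sigma truncated normal
    return np.clip(rng.normal(0.0, std, size=shape), -2 * std, 2 * std)


def _mlp_params(rng, d_in, hidden, d_out):
    return {
        "W1": _trunc_normal(rng, (d_in, hidden)),
        "b1": np.zeros(hidden),
        "W2": _trunc_normal(rng, (hidden, d_out)),
        "b2": np.zeros(d_out),
    }


def _ln_params(dim):
    return {"g": np.ones(dim), "b": np.zeros(dim)}


def init_params(cfg: ModelConfig, rng: np.random.Generator) -> dict:
    """Truncated-normal (std 0.02) projections, zero biases, unit LN gains."""
    R, Cin = cfg.input_resolution, cfg.in_channels
    params: dict = {}
    if cfg.variant in ("fusion", "mixer"):
        m = cfg.mixer
        S = (R // m.patch_size) ** 2
        layers = []
        for _ in range(m.depth):
            layers.append(
                {
                    "ln1": _ln_params(m.channel_dim),
                    "tok": _mlp_params(rng, S, m.token_mlp_hidden, S),
                    "ln2": _ln_params(m.channel_dim),
                    "ch": _mlp_params(rng, m.channel_dim, m.channel_mlp_hidden, m.channel_dim),
                }
            )
        params["mixer"] = {
            "embed": {
                "W": _trunc_normal(rng, (Cin * m.patch_size**2, m.channel_dim)),
                "b": np.zeros(m.channel_dim),
            },
            "layers": layers,
        }
    if cfg.variant in ("fusion", "vit"):
        v = cfg.vit
        S = (R // v.patch_size) ** 2
        layers = []
        for _ in range(v.depth):
            layers.append(
                {
                    "ln1": _ln_params(v.embed_dim),
                    "attn": {
                        "Wq": _trunc_normal(rng, (v.embed_dim, v.embed_dim)),
                        "bq": np.zeros(v.embed_dim),
                        "Wk": _trunc_normal(rng, (v.embed_dim, v.embed_dim)),
                        "bk": np.zeros(v.embed_dim),
                        "Wv": _trunc_normal(rng, (v.embed_dim, v.embed_dim)),
                        "bv": np.zeros(v.embed_dim),
                        "Wo": _trunc_normal(rng, (v.embed_dim, v.embed_dim)),
                        "bo": np.zeros(v.embed_dim),
                    },
                    "ln2": _ln_params(v.embed_dim),
                    "mlp": _mlp_params(rng, v.embed_dim, v.mlp_hidden, v.embed_dim),
                }
            )
        params["vit"] = {
            "embed": {
                "W": _trunc_normal(rng, (Cin * v.patch_size**2, v.embed_dim)),
                "b": np.zeros(v.embed_dim),
            },
            "pos": _trunc_normal(rng, (S, v.embed_dim)),
            "layers": layers,
        }
    params["head"] = {
        "W": _trunc_normal(rng, (cfg.head_input_len(), 1)),
        "b": np.zeros(1),
    }
    return params


def zeros_like_tree(tree):
    if isinstance(tree, dict):
        return {k: zeros_like_tree(v) for k, v in tree.items()}
    if isinstance(tree, list):
        return [zeros_like_tree(v) for v in tree]
    return np.zeros_like(tree)


def tree_leaves(tree, prefix=""):
    """Flatten a parameter tree into (path, array) pairs, sorted by path."""
    if isinstance(tree, dict):
        for k in sorted(tree):
            yield from tree_leaves(tree[k], f"{prefix}{k}.")
    elif isinstance(tree, list):
        for i, v in enumerate(tree):
            yield from tree_leaves(v, f"{prefix}{i}.")
    else:
        yield prefix[:-1], tree


def set_leaf(tree, path: str, value):
    keys = path.split(".")
    node = tree
    for k in keys[:-1]:
        node = node[int(k)] if isinstance(node, list) else node[k]
    last = keys[-1]
    if isinstance(node, list):
        node[int(last)] = value
    else:
        node[last] = value


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


class DualGlobalFusionModel:
    """Dual-branch risk model with explicit forward/backward passes."""

    def __init__(self, config: ModelConfig | None = None, params: dict | None = None):
        self.config = config or ModelConfig()
        self.dtype = np.dtype(self.config.dtype)
        rng = np.random.default_rng(self.config.seed)
        if params is None:
            params = init_params(self.config, rng)
            if self.dtype != np.float64:
                for path, arr in tree_leaves(params):
                    set_leaf(params, path, arr.astype(self.dtype))
        self.params = params

    # -- branch forward passes (cache returned for backward) --

    def _mixer_forward(self, x):
        cfg = self.config.mixer
        p = self.params["mixer"]
        patches = patchify(x, cfg.patch_size)
        Z, c_embed = linear_fwd(patches, p["embed"]["W"], p["embed"]["b"])
        layer_caches = []
        for lp in p["layers"]:
            Z, c = mixer_layer_fwd(Z, lp)
            layer_caches.append(c)
        feat = Z.mean(axis=1)
        return feat, (x.shape, c_embed, layer_caches, Z.shape[1])

    def _mixer_backward(self, dfeat, cache, grads):
        cfg = self.config.mixer
        p, g = self.params["mixer"], grads["mixer"]
        in_shape, c_embed, layer_caches, S = cache
        dZ = np.repeat(dfeat[:, None, :] / S, S, axis=1)
        for lp, lg, c in zip(reversed(p["layers"]), reversed(g["layers"]), reversed(layer_caches)):
            dZ = mixer_layer_bwd(dZ, c, lp, lg)
        dpatches, dW, db = linear_bwd(dZ, c_embed)
        g["embed"]["W"] += dW
        g["embed"]["b"] += db
        return unpatchify_grad(dpatches, in_shape, cfg.patch_size)

    def _vit_forward(self, x):
        cfg = self.config.vit
        p = self.params["vit"]
        patches = patchify(x, cfg.patch_size)
        Z0, c_embed = linear_fwd(patches, p["embed"]["W"], p["embed"]["b"])
        Z = Z0 + p["pos"]
        layer_caches = []
        for lp in p["layers"]:
            Z, c = transformer_layer_fwd(Z, lp, cfg.heads)
            layer_caches.append(c)
        feat = Z.mean(axis=1)
        return feat, (x.shape, c_embed, layer_caches, Z.shape[1])

    def _vit_backward(self, dfeat, cache, grads):
        cfg = self.config.vit
        p, g = self.params["vit"], grads["vit"]
        in_shape, c_embed, layer_caches, S = cache
        dZ = np.repeat(dfeat[:, None, :] / S, S, axis=1)
        for lp, lg, c in zip(reversed(p["layers"]), reversed(g["layers"]), reversed(layer_caches)):
            dZ = transformer_layer_bwd(dZ, c, lp, lg, cfg.heads)
        g["pos"] += dZ.sum(axis=0)
        dpatches, dW, db = linear_bwd(dZ, c_embed)
        g["embed"]["W"] += dW
        g["embed"]["b"] += db
        return unpatchify_grad(dpatches, in_shape, cfg.patch_size)

    # -- full model --

    def forward(self, x: np.ndarray, mu: np.ndarray, return_cache: bool = False):
        """Risks for a batch: x (B, 3, R, R), mu (B,) -> (B,)."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[None]
        mu = np.asarray(mu, dtype=self.dtype).reshape(-1)
        if self.config.mask_event:
            mu = np.zeros_like(mu)
        z1 = z2 = None
        c1 = c2 = None
        if self.config.variant in ("fusion", "mixer"):
            z1, c1 = self._mixer_forward(x)
        if self.config.variant in ("fusion", "vit"):
            z2, c2 = self._vit_forward(x)
        fused = fuse(z1, z2, mu)
        risks, c_head = linear_fwd(fused, self.params["head"]["W"], self.params["head"]["b"])
        risks = risks.reshape(-1)
        if not return_cache:
            return risks
        return risks, (c1, c2, c_head, z1, z2)

    def features(self, x: np.ndarray, mu: np.ndarray) -> np.ndarray:
        """Fused feature vectors (B, head_input_len) without the risk head."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[None]
        mu = np.asarray(mu, dtype=np.float64).reshape(-1)
        if self.config.mask_event:
            mu = np.zeros_like(mu)
        z1 = self._mixer_forward(x)[0] if self.config.variant in ("fusion", "mixer") else None
        z2 = self._vit_forward(x)[0] if self.config.variant in ("fusion", "vit") else None
        return fuse(z1, z2, mu)

    def backward(self, drisks: np.ndarray, cache) -> dict:
        """Gradient tree for d(loss)/d(params) given d(loss)/d(risks)."""
        c1, c2, c_head, z1, z2 = cache
        grads = zeros_like_tree(self.params)
        dfused, dW, db = linear_bwd(np.asarray(drisks, dtype=self.dtype).reshape(-1, 1), c_head)
        grads["head"]["W"] += dW
        grads["head"]["b"] += db
        off = 0
        if z1 is not None:
            d1 = dfused[:, off : off + z1.shape[-1]]
            off += z1.shape[-1]
            self._mixer_backward(d1, c1, grads)
        if z2 is not None:
            d2 = dfused[:, off : off + z2.shape[-1]]
            self._vit_backward(d2, c2, grads)
        return grads

    def predict(self, x: np.ndarray, mu: np.ndarray, chunk: int = 32) -> np.ndarray:
        """Memory-bounded batched inference."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[None]
        mu = np.asarray(mu, dtype=np.float64).reshape(-1)
        out = [self.forward(x[i : i + chunk], mu[i : i + chunk]) for i in range(0, len(x), chunk)]
        return np.concatenate(out)

    # -- persistence --

    def save(self, path: str | Path) -> None:
        """Round-trippable checkpoint: weights + full config in one npz."""
        flat = {path_: arr for path_, arr in tree_leaves(self.params)}
        cfg = json.dumps(asdict(self.config))
        np.savez(Path(path), __config__=np.frombuffer(cfg.encode(), dtype=np.uint8), **flat)

    @classmethod
    def load(cls, path: str | Path) -> "DualGlobalFusionModel":
        data = np.load(Path(path))
        cfg_dict = json.loads(bytes(data["__config__"]).decode())
        cfg = ModelConfig(
            input_resolution=cfg_dict["input_resolution"],
            in_channels=cfg_dict["in_channels"],
            variant=cfg_dict["variant"],
            mask_event=cfg_dict["mask_event"],
            seed=cfg_dict["seed"],
            dtype=cfg_dict.get("dtype", "float64"),
            mixer=MixerBranchConfig(**cfg_dict["mixer"]),
            vit=ViTBranchConfig(**cfg_dict["vit"]),
        )
        model = cls(cfg)
        for path_, _ in tree_leaves(model.params):
            set_leaf(model.params, path_, np.array(data[path_]))
        return model


# ---------------------------------------------------------------------------
# spec-level convenience wrappers (forward only)
# ---------------------------------------------------------------------------


def mixer_layer(Z: np.ndarray, layer_params: dict) -> np.ndarray:
    out, _ = mixer_layer_fwd(np.asarray(Z, dtype=np.float64), layer_params)
    return out


def transformer_layer(Z: np.ndarray, layer_params: dict, heads: int) -> np.ndarray:
    Z = np.asarray(Z, dtype=np.float64)
    squeeze = Z.ndim == 2
    out, _ = transformer_layer_fwd(Z[None] if squeeze else Z, layer_params, heads)
    return out[0] if squeeze else out


def vit_tokenize(x: np.ndarray, E: np.ndarray, b: np.ndarray, E_pos: np.ndarray, patch_size: int) -> np.ndarray:
    """Patchify, project by E, add position embeddings (Z_0 of the ViT branch)."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 3:
        x = x[None]
    patches = patchify(x, patch_size)
    return patches @ E + b + E_pos


def mixer_branch_forward(x: np.ndarray, config: MixerBranchConfig, params: dict) -> np.ndarray:
    """Patchify -> embed -> L mixer layers -> token mean-pool (Z^1)."""
    model = DualGlobalFusionModel.__new__(DualGlobalFusionModel)
    model.config = ModelConfig(
        input_resolution=np.asarray(x).shape[-1], variant="mixer", mixer=config
    )
    model.params = {"mixer": params}
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 3:
        x = x[None]
    return model._mixer_forward(x)[0]


def vit_branch_forward(x: np.ndarray, config: ViTBranchConfig, params: dict) -> np.ndarray:
    """Tokenize -> L transformer layers -> token mean-pool (Z^2)."""
    model = DualGlobalFusionModel.__new__(DualGlobalFusionModel)
    model.config = ModelConfig(
        input_resolution=np.asarray(x).shape[-1], variant="vit", vit=config
    )
    model.params = {"vit": params}
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 3:
        x = x[None]
    return model._vit_forward(x)[0]


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class Adam:
    """Adam with L2 weight decay added to the gradient (coupled, as in
    classic Adam implementations)."""

    def __init__(self, params: dict, lr=1e-4, beta1=0.99, beta2=0.999, eps=1e-8, weight_decay=5e-3):
        self.params = params
        self.lr, self.b1, self.b2, self.eps, self.wd = lr, beta1, beta2, eps, weight_decay
        self._leaves = [arr for _, arr in tree_leaves(params)]
        self.m = [np.zeros_like(a) for a in self._leaves]
        self.v = [np.zeros_like(a) for a in self._leaves]
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        grad_leaves = [arr for _, arr in tree_leaves(grads)]
        for p, g, m, v in zip(self._leaves, grad_leaves, self.m, self.v):
            g = g + self.wd * p
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
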
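"""Window-level rhythm classifier: Time2Vec embedding + transformer encoder.

The model embeds each 250-sample (1 s at 250 Hz) window by summing two
learned projections — one of the scalar sample value, one of a (k+1)-dim
Time2Vec column per time step — into a ``d_model``-wide sequence, runs it
through a stack of post-norm transformer encoder layers (multi-head scaled
dot-product self-attention + position-wise ReLU feed-forward, residual
connections and layer normalization around each sublayer), mean-pools over
time and classifies through a two-layer ReLU/dropout head with softmax over
the five rhythm classes.

The Time2Vec temporal embedding replaces fixed positional encoding:

    t2v(tau)_i = omega_i * tau + phi_i          (i = 0, linear trend)
    t2v(tau)_i = sin(omega_i * tau + phi_i)     (1 <= i <= k, periodic)

with all frequencies and phases learnable, which suits the quasi-periodic
structure of ECG.

Everything — forward, backward, Adam — is implemented in NumPy; gradients
are exercised by finite-difference checks in the test suite.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np


def _softmax_rows_(S2):
    """In-place row softmax on a 2-D view (stable, shift by row max)."""
    S2 -= S2.max(axis=-1, keepdims=True)
    np.exp(S2, out=S2)
    S2 /= S2.sum(axis=-1, keepdims=True)


def _softmax_rows_backward_(A2, dA2):
    """In-place softmax Jacobian-vector product: dA <- A * (dA - sum(dA*A))."""
    dot = np.einsum("ij,ij->i", dA2, A2)
    dA2 -= dot[:, None]
    dA2 *= A2


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ModelConfig:
    """Architectural hyperparameters.

    Defaults follow the full-size configuration: d_model 256, 3 encoder
    layers, 12 attention heads, feed-forward width 1024, dropout 0.25,
    L2 weight decay 0.001, Time2Vec k=2 (3 embedding rows), 250-sample
    windows, 5 classes.  ``key_dim`` is an independent per-head width (12
    heads x 21 = 252 concatenated, projected back to 256 by the output
    matrix); standard multi-head attention does not require
    n_heads * key_dim == d_model.
    """

    d_model: int = 256
    n_layers: int = 3
    n_heads: int = 12
    key_dim: int = 21
    ffn_dim: int = 1024
    dropout: float = 0.25
    l2: float = 1e-3
    t2v_k: int = 2
    window_len: int = 250
    n_classes: int = 5
    pooling: str = "mean"
    head_hidden: int = 64
    dtype: str = "float32"

    def __post_init__(self):
        for name in ("d_model", "n_layers", "n_heads", "key_dim", "ffn_dim", "t2v_k",
                     "window_len", "n_classes", "head_hidden"):
            if getattr(self, name) < (0 if name == "n_layers" else 1):
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.pooling not in ("mean", "last", "cls"):
            raise ValueError(f"unknown pooling {self.pooling!r}")

    @classmethod
    def scaled_down(cls, **overrides) -> "ModelConfig":
        """Reduced configuration for CPU-scale experiments."""
        base = dict(d_model=64, n_layers=2, n_heads=4, key_dim=16, ffn_dim=128,
                    dropout=0.1, head_hidden=32)
        base.update(overrides)
        return cls(**base)


@dataclass
class Time2VecParams:
    """Learnable Time2Vec parameters: frequency and phase per output row."""

    omega: np.ndarray  # (k+1,)
    phi: np.ndarray  # (k+1,)

    def __post_init__(self):
        self.omega = np.asarray(self.omega, dtype=np.float64)
        self.phi = np.asarray(self.phi, dtype=np.float64)
        if self.omega.shape != self.phi.shape or self.omega.ndim != 1:
            raise ValueError("omega and phi must be 1-D vectors of equal length k+1")

    @property
    def k(self) -> int:
        return self.omega.size - 1


@dataclass
class WindowPrediction:
    """Softmax probabilities and raw logits for one 1 s window."""

    probs: np.ndarray  # (n_classes,)
    logits: np.ndarray  # (n_classes,)


# ---------------------------------------------------------------------------
# functional building blocks (spec-level operations)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax; rows sum to 1 and are shift-invariant."""
    z = np.asarray(z, dtype=np.float64) if not isinstance(z, np.ndarray) else z
    m = z.max(axis=axis, keepdims=True)
    e = np.exp(z - m)
    return e / e.sum(axis=axis, keepdims=True)


def time2vec(tau: np.ndarray, params: Time2VecParams) -> np.ndarray:
    """Time2Vec embedding matrix of shape (k+1, len(tau)).

    Row 0 is the linear term omega_0*tau + phi_0; rows 1..k are
    sin(omega_i*tau + phi_i), each bounded in [-1, 1].
    """
    tau = np.atleast_1d(np.asarray(tau, dtype=np.float64))
    args = params.omega[:, None] * tau[None, :] + params.phi[:, None]
    out = np.sin(args)
    out[0] = args[0]
    return out


def scaled_dot_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray,
                         d_k: float | None = None, return_weights: bool = False):
    """softmax(Q K^T / sqrt(d_k)) V.

    Works on plain 2-D matrices and on batched (..., T, d) stacks.  d_k
    defaults to the key width.  Attention-weight rows sum to 1.
    """
    Q, K, V = (np.asarray(a, dtype=np.float64) for a in (Q, K, V))
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError(f"query width {Q.shape[-1]} != key width {K.shape[-1]}")
    if K.shape[-2] != V.shape[-2]:
        raise ValueError(f"key count {K.shape[-2]} != value count {V.shape[-2]}")
    if d_k is None:
        d_k = K.shape[-1]
    S = np.matmul(Q, np.swapaxes(K, -1, -2)) / np.sqrt(d_k)
    A = softmax(S, axis=-1)
    out = np.matmul(A, V)
    return (out, A) if return_weights else out


def layer_norm(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray, eps: float = 1e-5):
    """Normalize each feature vector (last axis) to zero mean / unit variance,
    then apply the learned gain and bias.  Returns (y, cache) for backprop."""
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return gamma * xhat + beta, (xhat, inv, gamma)


def _layer_norm_backward(dy, cache):
    xhat, inv, gamma = cache
    dgamma = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    dbeta = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * gamma
    dx = inv * (
        dxhat
        - dxhat.mean(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
    )
    return dx, dgamma, dbeta


def ffn(X: np.ndarray, W1: np.ndarray, b1: np.ndarray, W2: np.ndarray, b2: np.ndarray) -> np.ndarray:
    """Position-wise feed-forward: max(0, X W1 + b1) W2 + b2.

    Equivalent to two kernel-size-1 convolutions with a ReLU between; every
    position is transformed independently.
    """
    return np.maximum(0.0, X @ W1 + b1) @ W2 + b2


def multi_head_attention(X: np.ndarray, cfg: ModelConfig, weights: dict) -> np.ndarray:
    """Multi-head self-attention over a (..., T, d_model) sequence.

    ``weights`` holds Wq/Wk/Wv of shape (d_model, n_heads*key_dim), their
    biases, and the output projection Wo (n_heads*key_dim, d_model), bo.
    Per-head slices of the projections feed scaled dot-product attention;
    the concatenated heads are projected back to d_model.
    """
    single = X.ndim == 2
    Xb = X[None] if single else X
    out = _mha_forward(Xb, weights, cfg.n_heads, cfg.key_dim)[0]
    return out[0] if single else out


def encoder_layer(X: np.ndarray, cfg: ModelConfig, weights: dict,
                  train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
    """One post-norm encoder layer: LayerNorm(x + MHA(x)), LayerNorm(x + FFN(x)).

    Dropout (rate cfg.dropout) is applied to each sublayer output during
    training only.
    """
    single = X.ndim == 2
    Xb = X[None] if single else X
    attn = _mha_forward(Xb, weights, cfg.n_heads, cfg.key_dim)[0]
    attn, _ = _dropout(attn, cfg.dropout, train, rng)
    h1, _ = layer_norm(Xb + attn, weights["ln1_g"], weights["ln1_b"])
    f = ffn(h1, weights["W1"], weights["b1"], weights["W2"], weights["b2"])
    f, _ = _dropout(f, cfg.dropout, train, rng)
    out, _ = layer_norm(h1 + f, weights["ln2_g"], weights["ln2_b"])
    return out[0] if single else out


def _dropout(x, rate, train, rng):
    if not train or rate <= 0:
        return x, None
    if rng is None:
        raise ValueError("training-mode dropout needs an rng")
    u = rng.random(x.shape, dtype=np.float32) if x.dtype == np.float32 else rng.random(x.shape)
    scale = (u >= rate).astype(x.dtype) / np.asarray(1.0 - rate, dtype=x.dtype)
    return x * scale, scale


def _mha_forward(X, w, n_heads, key_dim):
    """X: (B, T, d).  Returns (out, cache)."""
    B, T, _ = X.shape
    hdk = n_heads * key_dim

    def split(M):  # (B,T,hdk) -> (B,H,T,dk)
        return M.reshape(B, T, n_heads, key_dim).transpose(0, 2, 1, 3)

    Q = split(X @ w["Wq"] + w["bq"])
    K = split(X @ w["Wk"] + w["bk"])
    V = split(X @ w["Wv"] + w["bv"])
    S = np.matmul(Q, K.swapaxes(-1, -2)) / np.asarray(np.sqrt(key_dim), dtype=X.dtype)
    _softmax_rows_(S.reshape(-1, T))
    A = S
    C = np.matmul(A, V).transpose(0, 2, 1, 3).reshape(B, T, hdk)
    out = C @ w["Wo"] + w["bo"]
    return out, (X, Q, K, V, A, C)


# ---------------------------------------------------------------------------
# the trainable model


def _glorot(rng, fan_in, fan_out, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(dtype)


def init_params(cfg: ModelConfig, seed: int = 0) -> dict[str, np.ndarray]:
    """Glorot-uniform weights, zero biases, unit layer-norm gains.

    Time2Vec starts with a unit ramp over the window for the linear row and
    0.5-8 cycles per window for the periodic rows, phases uniform in
    [0, 2pi); all are trainable.
    """
    rng = np.random.default_rng(seed)
    dt = np.dtype(cfg.dtype)
    d, k1, T = cfg.d_model, cfg.t2v_k + 1, cfg.window_len
    p: dict[str, np.ndarray] = {}
    omega = np.empty(k1)
    omega[0] = 1.0 / T
    omega[1:] = rng.uniform(2 * np.pi * 0.5 / T, 2 * np.pi * 8.0 / T, size=k1 - 1)
    phi = np.concatenate([[0.0], rng.uniform(0, 2 * np.pi, size=k1 - 1)])
    p["t2v_omega"] = omega.astype(dt)
    p["t2v_phi"] = phi.astype(dt)
    p["emb_w_sig"] = rng.uniform(-1, 1, size=d).astype(dt) * np.sqrt(3.0 / d, dtype=dt)
    p["emb_W_t2v"] = _glorot(rng, k1, d, dt)
    p["emb_b"] = np.zeros(d, dt)
    hdk = cfg.n_heads * cfg.key_dim
    for i in range(cfg.n_layers):
        pre = f"enc{i}_"
        for nm in ("Wq", "Wk", "Wv"):
            p[pre + nm] = _glorot(rng, d, hdk, dt)
            p[pre + nm.replace("W", "b")] = np.zeros(hdk, dt)
        p[pre + "Wo"] = _glorot(rng, hdk, d, dt)
        p[pre + "bo"] = np.zeros(d, dt)
        p[pre + "ln1_g"] = np.ones(d, dt)
        p[pre + "ln1_b"] = np.zeros(d, dt)
        p[pre + "W1"] = _glorot(rng, d, cfg.ffn_dim, dt)
        p[pre + "b1"] = np.zeros(cfg.ffn_dim, dt)
        p[pre + "W2"] = _glorot(rng, cfg.ffn_dim, d, dt)
        p[pre + "b2"] = np.zeros(d, dt)
        p[pre + "ln2_g"] = np.ones(d, dt)
        p[pre + "ln2_b"] = np.zeros(d, dt)
    p["head_W1"] = _glorot(rng, d, cfg.head_hidden, dt)
    p["head_b1"] = np.zeros(cfg.head_hidden, dt)
    p["head_W2"] = _glorot(rng, cfg.head_hidden, cfg.n_classes, dt)
    p["head_b2"] = np.zeros(cfg.n_classes, dt)
    return p


class RhythmTransformer:
    """Time2Vec + transformer encoder window classifier (NumPy)."""

    def __init__(self, cfg: ModelConfig, seed: int = 0,
                 params: dict[str, np.ndarray] | None = None):
        self.cfg = cfg
        self.seed = seed
        self.params = params if params is not None else init_params(cfg, seed)

    # -- inference ---------------------------------------------------------

    @property
    def t2v_params(self) -> Time2VecParams:
        return Time2VecParams(self.params["t2v_omega"], self.params["t2v_phi"])

    def _layer_weights(self, i: int) -> dict[str, np.ndarray]:
        pre = f"enc{i}_"
        return {k[len(pre):]: v for k, v in self.params.items() if k.startswith(pre)}

    def embed(self, X: np.ndarray):
        """(B, T) windows -> (B, T, d_model) embedded sequence (plus cache)."""
        cfg, p = self.cfg, self.params
        X = np.asarray(X, dtype=p["emb_w_sig"].dtype)
        if X.ndim == 1:
            X = X[None]
        if X.shape[1] != cfg.window_len:
            raise ValueError(f"window length {X.shape[1]} != {cfg.window_len}")
        tau = np.arange(cfg.window_len, dtype=X.dtype)
        args = p["t2v_omega"][:, None] * tau[None, :] + p["t2v_phi"][:, None]
        TV = np.sin(args)
        TV[0] = args[0]
        TVt = TV.T  # (T, k+1)
        E = X[:, :, None] * p["emb_w_sig"] + TVt @ p["emb_W_t2v"] + p["emb_b"]
        return E, (X, tau, args, TVt)

    def forward(self, X: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """Full forward pass.  Returns (probs, logits, cache)."""
        cfg, p = self.cfg, self.params
        h, emb_cache = self.embed(X)
        caches = []
        for i in range(cfg.n_layers):
            w = self._layer_weights(i)
            attn, mha_cache = _mha_forward(h, w, cfg.n_heads, cfg.key_dim)
            attn, m1 = _dropout(attn, cfg.dropout, train, rng)
            h1, ln1c = layer_norm(h + attn, w["ln1_g"], w["ln1_b"])
            Z1 = h1 @ w["W1"] + w["b1"]
            R = np.maximum(0.0, Z1)
            F = R @ w["W2"] + w["b2"]
            F, m2 = _dropout(F, cfg.dropout, train, rng)
            h2, ln2c = layer_norm(h1 + F, w["ln2_g"], w["ln2_b"])
            caches.append((mha_cache, m1, ln1c, h1, Z1, R, m2, ln2c))
            h = h2
        if cfg.pooling == "mean":
            pool = h.mean(axis=1)
        elif cfg.pooling == "last":
            pool = h[:, -1]
        else:  # cls: first position
            pool = h[:, 0]
        H1 = pool @ p["head_W1"] + p["head_b1"]
        Hr = np.maximum(0.0, H1)
        Hd, m3 = _dropout(Hr, cfg.dropout, train, rng)
        logits = Hd @ p["head_W2"] + p["head_b2"]
        probs = softmax(logits.astype(np.float64))
        cache = (emb_cache, caches, h, pool, H1, Hd, m3)
        return probs, logits, cache

    def predict_proba(self, X: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """(n, T) windows -> (n, n_classes) probabilities (inference mode)."""
        X = np.atleast_2d(np.asarray(X))
        out = np.empty((X.shape[0], self.cfg.n_classes))
        for a in range(0, X.shape[0], batch_size):
            out[a : a + batch_size] = self.forward(X[a : a + batch_size])[0]
        return out

    def classify_window(self, window: np.ndarray) -> WindowPrediction:
        probs, logits, _ = self.forward(np.asarray(window)[None])
        return WindowPrediction(probs=probs[0], logits=np.asarray(logits[0], dtype=np.float64))

    # -- training ----------------------------------------------------------

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray,
                       rng: np.random.Generator | None = None, train: bool = True):
        """Mean cross-entropy and gradients for one batch of windows.

        ``y`` holds integer class indices.  L2 regularization is applied by
        the optimizer (as weight decay on matrices), not inside this loss.
        """
        cfg, p = self.cfg, self.params
        probs, logits, cache = self.forward(X, train=train, rng=rng)
        B = probs.shape[0]
        y = np.asarray(y, dtype=int)
        loss = float(-np.mean(np.log(np.maximum(probs[np.arange(B), y], 1e-12))))
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits = (dlogits / B).astype(logits.dtype)

        emb_cache, caches, h_out, pool, H1, Hd, m3 = cache
        g = {k: None for k in p}
        g["head_W2"] = Hd.T @ dlogits
        g["head_b2"] = dlogits.sum(0)
        dHd = dlogits @ p["head_W2"].T
        if m3 is not None:
            dHd = dHd * m3
        dH1 = dHd * (H1 > 0)
        g["head_W1"] = pool.T @ dH1
        g["head_b1"] = dH1.sum(0)
        dpool = dH1 @ p["head_W1"].T
        T = cfg.window_len
        if cfg.pooling == "mean":
            dh = np.broadcast_to(dpool[:, None, :] / T, h_out.shape).copy()
        else:
            dh = np.zeros_like(h_out)
            idx = -1 if cfg.pooling == "last" else 0
            dh[:, idx, :] = dpool

        for i in reversed(range(cfg.n_layers)):
            w = self._layer_weights(i)
            mha_cache, m1, ln1c, h1, Z1, R, m2, ln2c = caches[i]
            pre = f"enc{i}_"
            dr2, dg2, db2 = _layer_norm_backward(dh, ln2c)
            g[pre + "ln2_g"], g[pre + "ln2_b"] = dg2, db2
            dF = dr2 if m2 is None else dr2 * m2
            R2 = R.reshape(-1, R.shape[-1])
            g[pre + "W2"] = R2.T @ dF.reshape(-1, dF.shape[-1])
            g[pre + "b2"] = dF.sum((0, 1))
            dR = dF @ w["W2"].T
            dZ1 = dR * (Z1 > 0)
            h1_2 = h1.reshape(-1, h1.shape[-1])
            g[pre + "W1"] = h1_2.T @ dZ1.reshape(-1, dZ1.shape[-1])
            g[pre + "b1"] = dZ1.sum((0, 1))
            dh1 = dr2 + dZ1 @ w["W1"].T

            dr1, dg1, db1 = _layer_norm_backward(dh1, ln1c)
            g[pre + "ln1_g"], g[pre + "ln1_b"] = dg1, db1
            dattn = dr1 if m1 is None else dr1 * m1
            Xin, Q, K, V, A, C = mha_cache
            B_, T_, _ = Xin.shape
            H, dk = cfg.n_heads, cfg.key_dim
            C2 = C.reshape(-1, C.shape[-1])
            g[pre + "Wo"] = C2.T @ dattn.reshape(-1, dattn.shape[-1])
            g[pre + "bo"] = dattn.sum((0, 1))
            dC = dattn @ w["Wo"].T
            dOh = dC.reshape(B_, T_, H, dk).transpose(0, 2, 1, 3)
            dA = np.matmul(dOh, V.swapaxes(-1, -2))
            dV = np.matmul(A.swapaxes(-1, -2), dOh)
            _softmax_rows_backward_(A.reshape(-1, A.shape[-1]), dA.reshape(-1, dA.shape[-1]))
            dS = dA
            scale = 1.0 / np.sqrt(dk)
            dQ = np.matmul(dS, K) * scale
            dK = np.matmul(dS.swapaxes(-1, -2), Q) * scale

            def merge(M):  # (B,H,T,dk) -> (B,T,hdk)
                return M.transpose(0, 2, 1, 3).reshape(B_, T_, H * dk)

            dQm, dKm, dVm = merge(dQ), merge(dK), merge(dV)
            X2 = Xin.reshape(-1, Xin.shape[-1])
            dXin = dr1.copy()
            for nm, dM in (("Wq", dQm), ("Wk", dKm), ("Wv", dVm)):
                g[pre + nm] = X2.T @ dM.reshape(-1, dM.shape[-1])
                g[pre + nm.replace("W", "b")] = dM.sum((0, 1))
                dXin += dM @ w[nm].T
            dh = dXin

        Xw, tau, args, TVt = emb_cache
        dE = dh
        g["emb_w_sig"] = (dE * Xw[:, :, None]).sum((0, 1))
        g["emb_b"] = dE.sum((0, 1))
        dE_t = dE.sum(0)  # (T, d)
        g["emb_W_t2v"] = TVt.T @ dE_t
        dTVt = dE_t @ p["emb_W_t2v"].T  # (T, k+1)
        darg = dTVt.T  # (k+1, T)
        darg = np.where(
            np.arange(args.shape[0])[:, None] == 0, darg, darg * np.cos(args)
        )
        g["t2v_omega"] = (darg * tau[None, :]).sum(1)
        g["t2v_phi"] = darg.sum(1)
        return loss, g

    def count_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -- persistence -------------------------------------------------------

    def save(self, out_dir: str, extra_card: dict | None = None) -> None:
        """Write ``weights.npz`` plus a JSON model card (config, exact
        parameter count, init seed, any training metadata)."""
        os.makedirs(out_dir, exist_ok=True)
        np.savez(os.path.join(out_dir, "weights.npz"), **self.params)
        card = {
            "config": asdict(self.cfg),
            "parameter_count": self.count_parameters(),
            "init_seed": self.seed,
        }
        if extra_card:
            card.update(extra_card)
        with open(os.path.join(out_dir, "card.json"), "w") as fh:
            json.dump(card, fh, indent=2)

    @classmethod
    def load(cls, out_dir: str) -> "RhythmTransformer":
        with open(os.path.join(out_dir, "card.json")) as fh:
            card = json.load(fh)
        cfg = ModelConfig(**card["config"])
        with np.load(os.path.join(out_dir, "weights.npz")) as npz:
            params = {k: npz[k] for k in npz.files}
        return cls(cfg, seed=card.get("init_seed", 0), params=params)


def embed_window(window: np.ndarray, model: RhythmTransformer) -> np.ndarray:
    """Embed a single window -> (window_len, d_model) sequence."""
    E, _ = model.embed(np.asarray(window))
    return E[0]


def classify_window(window: np.ndarray, model: RhythmTransformer) -> WindowPrediction:
    return model.classify_window(window)


def count_parameters(model: RhythmTransformer) -> int:
    """Exact count of trainable scalars in the model."""
    return model.count_parameters()


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adam with optional L2 weight decay on weight matrices.

    Decay (cfg.l2) is added to the gradient of every parameter whose name
    contains 'W' (projection/linear matrices); biases, layer-norm gains and
    Time2Vec parameters are not decayed.
    """

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in params.items():
            gk = np.asarray(grads[k], dtype=p.dtype)
            if self.weight_decay and "W" in k:
                gk = gk + self.weight_decay * p
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk * gk
            p -= (self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)).astype(p.dtype)
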
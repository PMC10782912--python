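"""Numpy implementation of the 1D CNN with a position-wise attention layer.

Architecture: input (B, N, 1) -> conv1d/relu -> maxpool -> conv1d/relu ->
maxpool -> additive attention over pooled positions (softmax scores + weighted
sum) -> dense/relu/dropout -> dense/relu/dropout -> 1-unit sigmoid.

Everything is explicit forward/backward with an Adam optimizer; no autograd
framework is used so the stack has no dependencies beyond numpy and is
deterministic for a fixed seed on fixed hardware.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["NetSpec", "CNNAttentionNet", "Adam", "bce_loss"]


@dataclass(frozen=True)
class NetSpec:
    """Shape parameters of the network for a given input width."""

    n_windows: int
    conv1_filters: int
    conv1_kernel: int
    pool1: int
    conv2_filters: int
    conv2_kernel: int
    pool2: int
    attention_dim: int
    dense1_units: int
    dense2_units: int
    dropout_rate: float

    def sequence_lengths(self) -> tuple[int, int, int, int]:
        """(conv1 out, pool1 out, conv2 out, pool2 out) lengths; all must be >= 1."""
        l1 = self.n_windows - self.conv1_kernel + 1
        lp1 = l1 // self.pool1
        l2 = lp1 - self.conv2_kernel + 1
        lp2 = l2 // self.pool2
        return l1, lp1, l2, lp2

    def validate(self) -> None:
        l1, lp1, l2, lp2 = self.sequence_lengths()
        if l1 < 1:
            raise ValueError(
                f"input width {self.n_windows} smaller than conv1 kernel "
                f"{self.conv1_kernel}"
            )
        if lp1 < 1 or l2 < 1 or lp2 < 1:
            raise ValueError(
                "configuration collapses the sequence to length 0 "
                f"(lengths {l1}, {lp1}, {l2}, {lp2})"
            )

    @property
    def pooled_length(self) -> int:
        return self.sequence_lengths()[3]

    def receptive_field(self) -> tuple[int, int]:
        """(jump, size): pooled position j covers input [j*jump, j*jump+size)."""
        jump = self.pool1 * self.pool2
        size = (self.pool2 + self.conv2_kernel - 1) * self.pool1 + self.conv1_kernel - 1
        return jump, size


def _conv1d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """x (B, L, Cin), W (k, Cin, Cout) -> (B, L-k+1, Cout) with cached cols."""
    k = W.shape[0]
    cols = sliding_window_view(x, k, axis=1)          # (B, Lout, Cin, k)
    out = np.tensordot(cols, W, axes=([3, 2], [0, 1])) + b
    return out, cols


def _conv1d_backward(dout, cols, W, x_shape):
    # dW[k, cin, cout] = sum_{b,l} cols[b, l, cin, k] * dout[b, l, cout]
    dW = np.tensordot(cols, dout, axes=([0, 1], [0, 1])).transpose(1, 0, 2)
    db = dout.sum(axis=(0, 1))
    dcols = np.tensordot(dout, W, axes=([2], [2]))    # (B, Lout, k, Cin)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    k = W.shape[0]
    lout = dout.shape[1]
    for j in range(k):
        dx[:, j:j + lout, :] += dcols[:, :, j, :]
    return dx, dW, db


def _maxpool_forward(x: np.ndarray, p: int):
    """x (B, L, C) -> (B, L//p, C); trailing remainder positions are dropped."""
    B, L, C = x.shape
    lp = L // p
    xr = x[:, : lp * p, :].reshape(B, lp, p, C)
    idx = xr.argmax(axis=2)
    out = np.take_along_axis(xr, idx[:, :, None, :], axis=2).squeeze(2)
    return out, idx


def _maxpool_backward(dout, idx, p, x_shape):
    B, L, C = x_shape
    lp = dout.shape[1]
    dxr = np.zeros((B, lp, p, C), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[:, :, None, :], dout[:, :, None, :], axis=2)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    dx[:, : lp * p, :] = dxr.reshape(B, lp * p, C)
    return dx


def _softmax(s: np.ndarray) -> np.ndarray:
    z = s - s.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class CNNAttentionNet:
    """The classifier network: parameter store plus forward/backward passes."""

    PARAM_NAMES = ("W1", "b1", "W2", "b2", "Wa", "ba", "va",
                   "Wd1", "bd1", "Wd2", "bd2", "Wo", "bo")

    def __init__(self, spec: NetSpec, seed: int = 0, dtype=np.float32):
        spec.validate()
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        s = spec

        def he(*shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(dtype)

        self.params = {
            "W1": he(s.conv1_kernel, 1, s.conv1_filters, fan_in=s.conv1_kernel),
            "b1": np.zeros(s.conv1_filters, dtype=dtype),
            "W2": he(s.conv2_kernel, s.conv1_filters, s.conv2_filters,
                     fan_in=s.conv2_kernel * s.conv1_filters),
            "b2": np.zeros(s.conv2_filters, dtype=dtype),
            "Wa": he(s.conv2_filters, s.attention_dim, fan_in=s.conv2_filters),
            "ba": np.zeros(s.attention_dim, dtype=dtype),
            "va": he(s.attention_dim, fan_in=s.attention_dim),
            "Wd1": he(s.conv2_filters, s.dense1_units, fan_in=s.conv2_filters),
            "bd1": np.zeros(s.dense1_units, dtype=dtype),
            "Wd2": he(s.dense1_units, s.dense2_units, fan_in=s.dense1_units),
            "bd2": np.zeros(s.dense2_units, dtype=dtype),
            "Wo": he(s.dense2_units, 1, fan_in=s.dense2_units),
            "bo": np.zeros(1, dtype=dtype),
        }

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -------------------------------------------------------------- forward
    def forward(self, X: np.ndarray, train: bool = False,
                dropout_rng: np.random.Generator | None = None) -> dict:
        """Run the network; returns a cache dict with ``prob`` and ``attention``.

        ``attention`` is the (B, pooled_length) softmax score matrix.
        Dropout is applied only when ``train`` is True.
        """
        P = self.params
        s = self.spec
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim != 2 or X.shape[1] != s.n_windows:
            raise ValueError(
                f"expected input of shape (B, {s.n_windows}), got {X.shape}"
            )
        cache: dict = {"X": X}
        x = X[:, :, None]

        z1, cols1 = _conv1d_forward(x, P["W1"], P["b1"])
        a1 = np.maximum(z1, 0)
        p1, idx1 = _maxpool_forward(a1, s.pool1)
        z2, cols2 = _conv1d_forward(p1, P["W2"], P["b2"])
        a2 = np.maximum(z2, 0)
        h, idx2 = _maxpool_forward(a2, s.pool2)        # (B, Lp, F2)

        u = np.tanh(h @ P["Wa"] + P["ba"])             # (B, Lp, A)
        scores = u @ P["va"]                           # (B, Lp)
        att = _softmax(scores)
        ctx = np.einsum("bl,blf->bf", att, h)

        def dense(v, W, b):
            return v @ W + b

        zd1 = dense(ctx, P["Wd1"], P["bd1"])
        ad1 = np.maximum(zd1, 0)
        if train and s.dropout_rate > 0:
            rng = dropout_rng or np.random.default_rng()
            keep = 1.0 - s.dropout_rate
            m1 = (rng.random(ad1.shape) < keep).astype(self.dtype) / keep
            ad1 = ad1 * m1
        else:
            m1 = None
        zd2 = dense(ad1, P["Wd2"], P["bd2"])
        ad2 = np.maximum(zd2, 0)
        if train and s.dropout_rate > 0:
            keep = 1.0 - s.dropout_rate
            m2 = (rng.random(ad2.shape) < keep).astype(self.dtype) / keep
            ad2 = ad2 * m2
        else:
            m2 = None
        logit = (dense(ad2, P["Wo"], P["bo"]))[:, 0]
        prob = 1.0 / (1.0 + np.exp(-logit))

        cache.update(
            x=x, z1=z1, cols1=cols1, a1=a1, p1=p1, idx1=idx1,
            z2=z2, cols2=cols2, a2=a2, h=h, idx2=idx2,
            u=u, att=att, ctx=ctx,
            zd1=zd1, ad1=ad1, m1=m1, zd2=zd2, ad2=ad2, m2=m2,
            logit=logit, prob=prob, attention=att,
        )
        return cache

    def predict_proba(self, X: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        out = np.empty(len(X))
        for i in range(0, len(X), batch_size):
            out[i:i + batch_size] = self.forward(X[i:i + batch_size])["prob"]
        return out

    # ------------------------------------------------------------- backward
    def backward(self, cache: dict, y: np.ndarray) -> dict:
        """Gradients of mean binary cross-entropy w.r.t. every parameter."""
        P = self.params
        s = self.spec
        B = len(y)
        y = np.asarray(y, dtype=self.dtype)

        dlogit = (cache["prob"] - y).astype(self.dtype) / B      # (B,)
        grads: dict = {}
        grads["Wo"] = cache["ad2"].T @ dlogit[:, None]
        grads["bo"] = np.array([dlogit.sum()], dtype=self.dtype)
        dad2 = dlogit[:, None] @ P["Wo"].T
        if cache["m2"] is not None:
            dad2 = dad2 * cache["m2"]
        dzd2 = dad2 * (cache["zd2"] > 0)
        grads["Wd2"] = cache["ad1"].T @ dzd2
        grads["bd2"] = dzd2.sum(axis=0)
        dad1 = dzd2 @ P["Wd2"].T
        if cache["m1"] is not None:
            dad1 = dad1 * cache["m1"]
        dzd1 = dad1 * (cache["zd1"] > 0)
        grads["Wd1"] = cache["ctx"].T @ dzd1
        grads["bd1"] = dzd1.sum(axis=0)
        dctx = dzd1 @ P["Wd1"].T                                  # (B, F2)

        h, att, u = cache["h"], cache["att"], cache["u"]
        datt = np.einsum("bf,blf->bl", dctx, h)                   # (B, Lp)
        dh = att[:, :, None] * dctx[:, None, :]                   # (B, Lp, F2)
        dscores = att * (datt - (datt * att).sum(axis=1, keepdims=True))
        du = dscores[:, :, None] * P["va"]                        # (B, Lp, A)
        dpre = du * (1 - u ** 2)
        grads["va"] = np.einsum("bla,bl->a", u, dscores).astype(self.dtype)
        grads["Wa"] = np.tensordot(h, dpre, axes=([0, 1], [0, 1]))
        grads["ba"] = dpre.sum(axis=(0, 1))
        dh += np.tensordot(dpre, P["Wa"], axes=([2], [1]))

        da2 = _maxpool_backward(dh, cache["idx2"], s.pool2, cache["a2"].shape)
        dz2 = da2 * (cache["z2"] > 0)
        dp1, grads["W2"], grads["b2"] = _conv1d_backward(
            dz2, cache["cols2"], P["W2"], cache["p1"].shape
        )
        da1 = _maxpool_backward(dp1, cache["idx1"], s.pool1, cache["a1"].shape)
        dz1 = da1 * (cache["z1"] > 0)
        _, grads["W1"], grads["b1"] = _conv1d_backward(
            dz1, cache["cols1"], P["W1"], cache["x"].shape
        )
        return grads

    def attention_scores(self, X: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        """Per-sample softmax attention over pooled positions (eval mode)."""
        parts = []
        for i in range(0, len(X), batch_size):
            parts.append(self.forward(X[i:i + batch_size])["attention"])
        return np.vstack(parts)

    # --------------------------------------------------------- serialization
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.PARAM_NAMES:
            if self.params[k].shape != np.asarray(state[k]).shape:
                raise ValueError(f"shape mismatch for parameter {k}")
            self.params[k] = np.asarray(state[k], dtype=self.dtype)


class Adam:
    """Standard Adam over a parameter dict."""

    def __init__(self, params: dict, lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict) -> None:
        self.t += 1
        c1 = 1 - self.b1 ** self.t
        c2 = 1 - self.b2 ** self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g ** 2
            p -= (self.lr * (self.m[k] / c1)
                  / (np.sqrt(self.v[k] / c2) + self.eps)).astype(p.dtype)


def bce_loss(prob: np.ndarray, y: np.ndarray, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy."""
    p = np.clip(prob, eps, 1 - eps)
    y = np.asarray(y, dtype=float)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())
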
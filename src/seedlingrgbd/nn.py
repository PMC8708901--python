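"""Neural-network layers and optimiser built on the autograd engine.

Weight initialisation is Glorot-uniform from an explicit seeded generator,
so two modules built with the same seed are bit-identical and training is
reproducible run-to-run on one platform.
"""

from __future__ import annotations

import numpy as np

from .autograd import (Tensor, concat, conv2d_3x3, dropout, layer_norm,
                       maxpool2x2, softmax)

__all__ = ["Module", "Conv3x3", "Dense", "CnnFeatureExtractor", "GRU",
           "TransformerEncoder", "Adam"]


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def param_count(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Conv3x3(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in, fan_out = c_in * 9, c_out * 9
        self.w = Tensor(_glorot(rng, (c_out, c_in, 3, 3), fan_in, fan_out),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d_3x3(x, self.w, self.b)


class Dense(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = Tensor(_glorot(rng, (d_in, d_out), d_in, d_out),
                        requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class CnnFeatureExtractor(Module):
    """Conv/ReLU/max-pool stack followed by a dense feature layer.

    The classic small-image backbone: each 3x3 conv is followed by ReLU
    and 2x2 max-pooling, halving the spatial size; the final activation is
    flattened into a dense feature vector with ReLU and (training-time)
    dropout.
    """

    def __init__(self, c_in: int, filters: tuple[int, ...], image_hw: int,
                 dense_units: int | None, dropout_p: float,
                 rng: np.random.Generator):
        self.convs = []
        c = c_in
        hw = image_hw
        for f in filters:
            self.convs.append(Conv3x3(c, f, rng))
            c = f
            hw = hw // 2
        self.flat_dim = c * hw * hw
        # dense_units=None builds a conv-only extractor (used when streams
        # merge their flattened conv features before a shared dense layer)
        self.dense = Dense(self.flat_dim, dense_units, rng) if dense_units else None
        self.dropout_p = dropout_p
        self.out_dim = dense_units if dense_units else self.flat_dim

    def conv_features(self, x: Tensor) -> Tensor:
        """(N, C, H, W) -> flattened conv activations (N, flat_dim)."""
        for conv in self.convs:
            x = maxpool2x2(conv(x).relu())
        n = x.data.shape[0]
        return x.reshape(n, self.flat_dim)

    def __call__(self, x: Tensor, rng: np.random.Generator,
                 training: bool) -> Tensor:
        feats = self.conv_features(x)
        if self.dense is None:
            return feats
        h = self.dense(feats).relu()
        return dropout(h, self.dropout_p, rng, training)


class GRU(Module):
    """Single-layer gated recurrent unit (update and reset gates)."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        def mat(a, b):
            return Tensor(_glorot(rng, (a, b), a, b), requires_grad=True)

        self.wz, self.uz = mat(d_in, d_hidden), mat(d_hidden, d_hidden)
        self.wr, self.ur = mat(d_in, d_hidden), mat(d_hidden, d_hidden)
        self.wh, self.uh = mat(d_in, d_hidden), mat(d_hidden, d_hidden)
        self.bz = Tensor(np.zeros(d_hidden), requires_grad=True)
        self.br = Tensor(np.zeros(d_hidden), requires_grad=True)
        self.bh = Tensor(np.zeros(d_hidden), requires_grad=True)
        self.d_hidden = d_hidden

    def __call__(self, steps: list[Tensor]) -> Tensor:
        """Run over a list of (N, d_in) step inputs; returns the last hidden."""
        n = steps[0].data.shape[0]
        h = Tensor(np.zeros((n, self.d_hidden)))
        for x in steps:
            z = (x @ self.wz + h @ self.uz + self.bz).sigmoid()
            r = (x @ self.wr + h @ self.ur + self.br).sigmoid()
            hh = (x @ self.wh + (r * h) @ self.uh + self.bh).tanh()
            h = (Tensor(1.0) - z) * h + z * hh
        return h


class _MultiHeadAttention(Module):
    def __init__(self, d_model: int, heads: int, rng: np.random.Generator):
        if d_model % heads:
            raise ValueError("d_model must be divisible by the head count")
        self.h, self.dh = heads, d_model // heads
        self.wq = Dense(d_model, d_model, rng)
        self.wk = Dense(d_model, d_model, rng)
        self.wv = Dense(d_model, d_model, rng)
        self.wo = Dense(d_model, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        n, t, d = x.data.shape

        def heads(y: Tensor) -> Tensor:
            return y.reshape(n, t, self.h, self.dh).transpose((0, 2, 1, 3))

        q, k, v = heads(self.wq(x)), heads(self.wk(x)), heads(self.wv(x))
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(self.dh))
        attn = softmax(scores, axis=-1)
        out = (attn @ v).transpose((0, 2, 1, 3)).reshape(n, t, d)
        return self.wo(out)


class _TransformerBlock(Module):
    """Pre-norm transformer encoder block: LN-MHA residual, LN-FFN residual."""

    def __init__(self, d_model: int, heads: int, d_ff: int,
                 rng: np.random.Generator):
        self.attn = _MultiHeadAttention(d_model, heads, rng)
        self.ff1 = Dense(d_model, d_ff, rng)
        self.ff2 = Dense(d_ff, d_model, rng)
        self.g1 = Tensor(np.ones(d_model), requires_grad=True)
        self.b1 = Tensor(np.zeros(d_model), requires_grad=True)
        self.g2 = Tensor(np.ones(d_model), requires_grad=True)
        self.b2 = Tensor(np.zeros(d_model), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(layer_norm(x, self.g1, self.b1))
        return x + self.ff2(self.ff1(layer_norm(x, self.g2, self.b2)).relu())


class TransformerEncoder(Module):
    """Token projection + learned positional embedding + encoder stack.

    Each whole frame is one token: the flattened frame is projected to
    d_model, a learned positional embedding over the (short) frame sequence
    is added, and the stack's output tokens are mean-pooled.
    """

    def __init__(self, d_token_in: int, d_model: int, heads: int,
                 n_layers: int, seq_len: int, rng: np.random.Generator):
        self.proj = Dense(d_token_in, d_model, rng)
        self.pos = Tensor(rng.normal(0, 0.02, size=(seq_len, d_model)),
                          requires_grad=True)
        self.blocks = [_TransformerBlock(d_model, heads, 2 * d_model, rng)
                       for _ in range(n_layers)]
        self.gf = Tensor(np.ones(d_model), requires_grad=True)
        self.bf = Tensor(np.zeros(d_model), requires_grad=True)
        self.out_dim = d_model

    def __call__(self, tokens: Tensor) -> Tensor:
        """tokens: (N, T, d_token_in) -> pooled representation (N, d_model)."""
        x = self.proj(tokens) + self.pos
        for blk in self.blocks:
            x = blk(x)
        x = layer_norm(x, self.gf, self.bf)
        return x.mean(axis=1)


class Adam:
    """Adam optimiser over a fixed parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
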
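"""Neural-network layers and the Adam optimizer on top of :mod:`mmrisk.autodiff`.

Layers follow the usual transformer conventions: Xavier-uniform weight
init from a layer-local RNG, pre-LayerNorm residual blocks, GELU
feed-forwards.  Attention uses an additive-mask convention in which a
blocked key position receives attention weight exactly 0 and a row whose
keys are all blocked produces a zero output row (see
:func:`mmrisk.autodiff.masked_softmax`).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, masked_softmax

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "LayerNorm",
    "Dropout",
    "MultiHeadAttention",
    "TransformerEncoderLayer",
    "Adam",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal container: children and parameters are found by attribute scan."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params: list, seen: set) -> None:
        for name in sorted(vars(self)):
            value = getattr(self, name)
            items = value if isinstance(value, (list, tuple)) else [value]
            for item in items:
                if isinstance(item, Parameter):
                    if id(item) not in seen:
                        seen.add(id(item))
                        params.append(item)
                elif isinstance(item, Module):
                    item._collect(params, seen)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state_dict size mismatch")
        for p, arr in zip(params, state):
            if p.data.shape != arr.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.asarray(arr, dtype=np.float64).copy()


class Linear(Module):
    def __init__(self, dim_in: int, dim_out: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / (dim_in + dim_out))
        self.weight = Parameter(rng.uniform(-bound, bound, size=(dim_in, dim_out)))
        self.bias = Parameter(np.zeros(dim_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered ** 2.0).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps) ** -0.5 * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity unless a training RNG is supplied."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if rng is None or self.p == 0.0:
            return x
        keep = rng.random(x.shape) >= self.p
        return x * (keep / (1.0 - self.p))


class MultiHeadAttention(Module):
    """Masked scaled-dot-product attention; serves self- and cross-attention.

    ``d`` in the score scaling is the per-head key dimension.  ``key_keep``
    is a boolean (B, Tk) array; False columns are excluded from the
    softmax so they get weight exactly 0.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError(f"dim {dim} not divisible by {n_heads} heads")
        self.dim = dim
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.w_q = Linear(dim, dim, rng)
        self.w_k = Linear(dim, dim, rng)
        self.w_v = Linear(dim, dim, rng)
        self.w_o = Linear(dim, dim, rng)

    def _split(self, x: Tensor, batch: int, length: int) -> Tensor:
        # (B, T, D) -> (B, h, T, d)
        return x.reshape(batch, length, self.n_heads, self.head_dim).swapaxes(1, 2)

    def __call__(
        self,
        query: Tensor,
        key: Tensor,
        value: Tensor,
        key_keep: np.ndarray | None = None,
        return_weights: bool = False,
    ):
        if query.shape[-1] != self.dim or key.shape[-1] != self.dim:
            raise ValueError("attention input dim mismatch")
        b, tq, _ = query.shape
        tk = key.shape[1]
        q = self._split(self.w_q(query), b, tq)
        k = self._split(self.w_k(key), b, tk)
        v = self._split(self.w_v(value), b, tk)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.head_dim))
        if key_keep is None:
            keep = np.ones((b, 1, 1, tk), dtype=bool)
        else:
            keep = np.asarray(key_keep, dtype=bool).reshape(b, 1, 1, tk)
        weights = masked_softmax(scores, keep, axis=-1)
        out = (weights @ v).swapaxes(1, 2).reshape(b, tq, self.dim)
        out = self.w_o(out)
        alive = keep.any(axis=(1, 2, 3))  # samples with >= 1 usable key
        if not alive.all():
            # softmax over an empty key set contributes exactly nothing,
            # including the output-projection bias
            out = out * alive.astype(float)[:, None, None]
        if return_weights:
            return out, weights
        return out


class TransformerEncoderLayer(Module):
    """One pre-LN transformer encoder block (masked self-attention + GELU FFN)."""

    def __init__(
        self,
        dim: int,
        n_heads: int,
        rng: np.random.Generator,
        ffn_mult: int = 4,
        dropout: float = 0.1,
    ):
        self.attn = MultiHeadAttention(dim, n_heads, rng)
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.ff1 = Linear(dim, ffn_mult * dim, rng)
        self.ff2 = Linear(ffn_mult * dim, dim, rng)
        self.drop = Dropout(dropout)

    def __call__(
        self,
        x: Tensor,
        pad_keep: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        h = self.norm1(x)
        x = x + self.drop(self.attn(h, h, h, key_keep=pad_keep), rng)
        h = self.norm2(x)
        x = x + self.drop(self.ff2(self.drop(self.ff1(h).gelu(), rng)), rng)
        return x


class Adam:
    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        weight_decay: float = 0.0,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.weight_decay = weight_decay
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            m_hat = self.m[i] / (1.0 - self.b1 ** self.t)
            v_hat = self.v[i] / (1.0 - self.b2 ** self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
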
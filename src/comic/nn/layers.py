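"""Small neural building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, constant, parameter, softmax


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Base: parameters are discovered as Tensor attributes / sub-modules."""

    def parameters(self) -> list[tuple[str, Tensor]]:
        out = []
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                out.append((name, val))
            elif isinstance(val, Module):
                out.extend((f"{name}.{n}", p) for n, p in val.parameters())
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend((f"{name}.{i}.{n}", p) for n, p in item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append((f"{name}.{i}", item))
        return out


class Linear(Module):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int):
        self.W = parameter(xavier_uniform(rng, d_in, d_out))
        self.b = parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = parameter(np.ones(dim))
        self.beta = parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gamma + self.beta


class GatedMLP(Module):
    """3-layer network with layer normalization and GELU activation."""

    def __init__(self, rng: np.random.Generator, dim: int):
        self.lin = [Linear(rng, dim, dim) for _ in range(3)]
        self.norm = [LayerNorm(dim) for _ in range(3)]

    def __call__(self, x: Tensor) -> Tensor:
        for i in range(2):
            x = self.norm[i](self.lin[i](x)).gelu()
        return self.norm[2](self.lin[2](x))


class ClassifierMLP(Module):
    """3-layer GELU network with a terminal sigmoid, emitting a probability."""

    def __init__(self, rng: np.random.Generator, dim: int, hidden: int | None = None):
        h = hidden or dim
        self.lin1 = Linear(rng, dim, h)
        self.lin2 = Linear(rng, h, h)
        self.lin3 = Linear(rng, h, 1)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.lin1(x).gelu()
        h = self.lin2(h).gelu()
        return self.lin3(h).sigmoid()


class SelfAttentionBlock(Module):
    """Single-head scaled dot-product self-attention with residual + layer norm."""

    def __init__(self, rng: np.random.Generator, dim: int):
        self.Wq = parameter(xavier_uniform(rng, dim, dim))
        self.Wk = parameter(xavier_uniform(rng, dim, dim))
        self.Wv = parameter(xavier_uniform(rng, dim, dim))
        self.norm = LayerNorm(dim)
        self.scale = 1.0 / np.sqrt(dim)

    def __call__(self, x: Tensor) -> Tensor:
        # x: (..., n_tokens, dim)
        q, k, v = x @ self.Wq, x @ self.Wk, x @ self.Wv
        att = softmax((q @ k.swapaxes(-1, -2)) * self.scale, axis=-1)
        return self.norm(x + att @ v)


def positional_encoding(n_tokens: int, dim: int) -> np.ndarray:
    """Fixed sinusoidal positional encoding, shape (n_tokens, dim)."""
    pos = np.arange(n_tokens)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe


class Adam:
    def __init__(self, params: list[tuple[str, Tensor]], lr: float = 5e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {n: np.zeros_like(p.data) for n, p in params}
        self.v = {n: np.zeros_like(p.data) for n, p in params}

    def zero_grad(self):
        for _, p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for name, p in self.params:
            g = p.grad
            if g is None:
                continue
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            mhat = self.m[name] / (1 - self.b1**self.t)
            vhat = self.v[name] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def global_grad_norm(params: list[tuple[str, Tensor]]) -> float:
    total = 0.0
    for _, p in params:
        if p.grad is not None:
            total += float(np.sum(p.grad * p.grad))
    return float(np.sqrt(total))


def clip_grad_norm(params: list[tuple[str, Tensor]], max_norm: float) -> float:
    """Scale gradients in place so the global norm is at most max_norm.

    Returns the post-clip global norm.
    """
    norm = global_grad_norm(params)
    if norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for _, p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
        return max_norm
    return norm
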
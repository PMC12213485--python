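"""Minimal neural-network building blocks on top of :mod:`leafmoe.autodiff`.

Layers register their parameters so optimizers can walk a module tree.  Only
what the package needs is provided: linear maps, layer normalization, dropout
and the AdamW optimizer.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = ["Module", "Linear", "LayerNorm", "Dropout", "AdamW", "layer_norm",
           "save_params", "load_params"]


class Module:
    """Base class: tracks parameters and child modules via attribute assignment."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_children", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._children[name] = value
        object.__setattr__(self, name, value)

    def register(self, name: str, value: Tensor) -> Tensor:
        """Register a parameter stored outside attribute slots (e.g. in lists)."""
        self._params[name] = value
        return value

    def add_child(self, name: str, module: "Module") -> "Module":
        self._children[name] = module
        return module

    def parameters(self) -> list[Tensor]:
        params = list(self._params.values())
        for child in self._children.values():
            params.extend(child.parameters())
        return params

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


def _param(array: np.ndarray) -> Tensor:
    return Tensor(array, requires_grad=True)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        scale = np.sqrt(2.0 / (in_dim + out_dim))
        self.weight = _param(rng.normal(0.0, scale, size=(in_dim, out_dim)))
        self.bias = _param(np.zeros(out_dim)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = as_tensor(x) @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


def layer_norm(x: Tensor, gamma: Tensor | None = None, beta: Tensor | None = None,
               eps: float = 1e-6) -> Tensor:
    """Standardize the last axis to zero mean / unit variance, then affine.

    With ``gamma``/``beta`` omitted this is the identity-affine normalization;
    a constant input maps to zeros thanks to the epsilon guard.
    """
    x = as_tensor(x)
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered ** 2).mean(axis=-1, keepdims=True)
    out = centered / (var + eps).sqrt()
    if gamma is not None:
        out = out * gamma
    if beta is not None:
        out = out + beta
    return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.gamma = _param(np.ones(dim))
        self.beta = _param(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, self.eps)


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return as_tensor(x)
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return as_tensor(x) * Tensor(mask)


def save_params(model: Module, path) -> None:
    """Save a module's parameters; order is the module-tree traversal order."""
    np.savez(path, *[p.data for p in model.parameters()])


def load_params(model: Module, path) -> Module:
    """Load parameters saved by :func:`save_params` into a same-shaped model."""
    with np.load(path) as archive:
        arrays = [archive[k] for k in archive.files]
    params = model.parameters()
    if len(arrays) != len(params):
        raise ValueError(f"checkpoint has {len(arrays)} arrays, "
                         f"model has {len(params)} parameters")
    for p, a in zip(params, arrays):
        if p.data.shape != a.shape:
            raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
        p.data = a.astype(np.float64)
    return model


class AdamW(Module):
    """AdamW with decoupled weight decay applied to matrices only."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        super().__init__()
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g ** 2
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            if self.weight_decay and p.data.ndim >= 2:
                p.data *= 1.0 - self.lr * self.weight_decay
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
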
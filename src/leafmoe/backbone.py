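"""Feature extraction for the classifier: a small trainable vision transformer,
patch-to-vector pooling, layer normalization and training-time Gaussian noise.

The extractor contract is any callable mapping a batch of RGB images in [0, 1]
to an (B, N_tokens, D) token matrix; :class:`TinyViT` is the shipped
implementation, sized to train from scratch on the synthetic datasets
(<= 4 blocks, D <= 128) with no external weights.  The classifier pipeline is

    tokens -> pooled vector h -> layer norm h_norm -> (+ noise in training)

where the gating network always consumes the clean ``h_norm`` and the experts
consume the noise-perturbed vector during training; at eval both see
``h_norm``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor
from .nn import LayerNorm, Linear, Module, layer_norm

__all__ = ["NoiseConfig", "TinyViT", "pool_features", "normalize_features",
           "inject_noise", "extract_features", "patchify"]


@dataclass
class NoiseConfig:
    """Zero-mean Gaussian feature noise, active only in training.

    ``sigma`` is in units of the normalized feature scale (features are
    standardized before injection); the low default keeps subtle lesion
    signatures from being masked.
    """

    sigma: float = 0.05
    enabled: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError(f"noise sigma must be >= 0, got {self.sigma}")


def patchify(images: np.ndarray, patch_size: int) -> np.ndarray:
    """(B, S, S, 3) -> (B, (S/p)^2, p*p*3) row-major patch flattening."""
    b, s, s2, c = images.shape
    if c != 3:
        raise ValueError(f"expected 3-channel images, got {c} channels")
    if s != s2 or s % patch_size:
        raise ValueError(f"image size {s}x{s2} not divisible by patch {patch_size}")
    n = s // patch_size
    x = images.reshape(b, n, patch_size, n, patch_size, c)
    return x.transpose(0, 1, 3, 2, 4, 5).reshape(b, n * n, patch_size * patch_size * c)


class _Attention(Module):
    def __init__(self, dim: int, heads: int, rng):
        super().__init__()
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.heads = heads
        self.dh = dim // heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        b, n, d = x.shape
        qkv = self.qkv(x).reshape(b, n, 3, self.heads, self.dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]          # (B, heads, N, dh)
        attn = (q @ k.swapaxes(-1, -2)) * (self.dh ** -0.5)
        attn = attn.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, n, d)
        return self.proj(out)


class _Block(Module):
    def __init__(self, dim: int, heads: int, mlp_ratio: float, rng):
        super().__init__()
        hidden = int(dim * mlp_ratio)
        self.norm1 = LayerNorm(dim)
        self.attn = _Attention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.fc2(self.fc1(self.norm2(x)).relu())


class TinyViT(Module):
    """Small from-scratch vision transformer producing patch-token features.

    Emits (B, N_patches + 1, D) with a class token at index 0.  ``n_patches``
    is ``(image_size / patch_size)^2``.
    """

    def __init__(self, image_size: int = 64, patch_size: int = 8, dim: int = 32,
                 depth: int = 2, heads: int = 4, mlp_ratio: float = 2.0,
                 seed: int = 0):
        super().__init__()
        if depth > 4 or dim > 128:
            raise ValueError("TinyViT is capped at depth 4 and dim 128")
        rng = np.random.default_rng(seed)
        self.image_size = image_size
        self.patch_size = patch_size
        self.dim = dim
        self.has_cls_token = True
        self.n_patches = (image_size // patch_size) ** 2
        self.patch_embed = Linear(patch_size * patch_size * 3, dim, rng)
        self.cls_token = self.register(
            "cls_token", Tensor(rng.normal(0, 0.02, (1, 1, dim)), requires_grad=True))
        self.pos_embed = self.register(
            "pos_embed", Tensor(rng.normal(0, 0.02, (1, self.n_patches + 1, dim)),
                                requires_grad=True))
        self.blocks = [self.add_child(f"block{i}", _Block(dim, heads, mlp_ratio, rng))
                       for i in range(depth)]
        self.norm = LayerNorm(dim)

    def __call__(self, images: np.ndarray) -> Tensor:
        if images.shape[1] != self.image_size:
            raise ValueError(f"expected {self.image_size}px images, "
                             f"got {images.shape[1]}px")
        patches = Tensor(patchify(np.asarray(images, dtype=np.float64),
                                  self.patch_size))
        x = self.patch_embed(patches)                            # (B, N, D)
        b = x.shape[0]
        cls = self.cls_token + Tensor(np.zeros((b, 1, self.dim)))  # broadcast to batch
        x = _concat_tokens(cls, x)
        x = x + self.pos_embed
        for block in self.blocks:
            x = block(x)
        return self.norm(x)


def _concat_tokens(cls: Tensor, x: Tensor) -> Tensor:
    """Concatenate a class token ahead of the patch tokens, grad-correctly.

    Implemented as two selector matmuls so the tape only needs existing ops.
    """
    b, n, d = x.shape
    sel_cls = np.zeros((1, n + 1))
    sel_cls[0, 0] = 1.0
    sel_x = np.zeros((n, n + 1))
    sel_x[np.arange(n), np.arange(n) + 1] = 1.0
    out = cls.swapaxes(-1, -2) @ Tensor(sel_cls) + x.swapaxes(-1, -2) @ Tensor(sel_x)
    return out.swapaxes(-1, -2)


def extract_features(images, extractor) -> Tensor:
    """Run a batch through an extractor callable; returns (B, N_tokens, D)."""
    arr = images.images if hasattr(images, "images") else np.asarray(images)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError("expected a (B, S, S, 3) RGB batch")
    return extractor(arr)


def pool_features(tokens: Tensor, strategy: str = "cls_token",
                  has_cls_token: bool = True) -> Tensor:
    """Reduce (B, N_tokens, D) to a per-image vector (B, D)."""
    tokens = as_tensor(tokens)
    if strategy == "cls_token":
        if not has_cls_token:
            raise ValueError("extractor exposes no class token")
        return tokens[:, 0, :]
    if strategy == "mean":
        start = 1 if has_cls_token else 0
        return tokens[:, start:, :].mean(axis=1)
    raise ValueError(f"unknown pooling strategy {strategy!r}")


def normalize_features(h: Tensor, gamma: Tensor | None = None,
                       beta: Tensor | None = None, eps: float = 1e-6) -> Tensor:
    """Per-vector standardization with optional learned affine (layer norm)."""
    h = as_tensor(h)
    if h.shape[-1] < 2:
        raise ValueError("feature dimension must be >= 2")
    return layer_norm(h, gamma, beta, eps)


def inject_noise(h: Tensor, cfg: NoiseConfig, training: bool,
                 rng: np.random.Generator | None = None) -> Tensor:
    """Add i.i.d. N(0, sigma^2) to each feature during training; identity at eval."""
    h = as_tensor(h)
    if not training or not cfg.enabled or cfg.sigma == 0.0:
        return h
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    return h + Tensor(rng.normal(0.0, cfg.sigma, h.shape))
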
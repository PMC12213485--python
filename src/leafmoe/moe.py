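"""Mixture-of-experts layer: expert classifiers, gating, top-K routing and
weighted aggregation.

Every expert is a two-layer MLP with dropout emitting a softmax distribution
over classes.  The gate is a linear-softmax over the expert pool; routing
keeps the K largest gate weights, renormalizes them to sum to one (so the
aggregated prediction stays a probability distribution) and zeroes the rest.
All experts are evaluated densely — the pool is small, and the usage and
orthogonality regularizers as well as the diagnostics need every expert's
output — with unselected experts simply receiving weight zero.

Ties in the top-K selection break toward the lower expert index, which keeps
routing deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor, no_grad
from .backbone import NoiseConfig, TinyViT, inject_noise, normalize_features, pool_features
from .nn import Dropout, LayerNorm, Linear, Module

__all__ = ["MoEConfig", "Expert", "MoEOutput", "gate_forward", "select_top_k",
           "top_k_mask", "aggregate_predictions", "MoEHead", "ViTMoEClassifier",
           "SingleHeadClassifier", "expert_forward"]


@dataclass
class MoEConfig:
    num_experts: int = 10
    top_k: int = 3
    hidden_dim: int = 256
    dropout: float = 0.1

    def __post_init__(self):
        if not 1 <= self.top_k <= self.num_experts:
            raise ValueError(f"top_k must lie in [1, {self.num_experts}], "
                             f"got {self.top_k}")


class Expert(Module):
    """Two fully connected layers with dropout; softmax class distribution."""

    def __init__(self, in_dim: int, hidden_dim: int, n_classes: int,
                 dropout: float, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(in_dim, hidden_dim, rng)
        self.drop = Dropout(dropout, rng)
        self.fc2 = Linear(hidden_dim, n_classes, rng)

    def __call__(self, h: Tensor) -> Tensor:
        return self.fc2(self.drop(self.fc1(h)).relu()).softmax(axis=-1)


def expert_forward(h, expert: Expert, training: bool = False) -> Tensor:
    """Run one expert; dropout is active only when ``training``."""
    expert.train(training)
    return expert(as_tensor(h))


def gate_forward(h_norm, gate: Linear) -> Tensor:
    """Dense gating distribution over the expert pool (softmax of gate logits)."""
    return gate(as_tensor(h_norm)).softmax(axis=-1)


def top_k_mask(g: np.ndarray, k: int) -> np.ndarray:
    """0/1 mask of the K largest entries per row; ties favor lower index."""
    g = np.atleast_2d(g)
    b, e = g.shape
    if not 1 <= k <= e:
        raise ValueError(f"K must lie in [1, {e}], got {k}")
    order = np.argsort(-g, axis=-1, kind="stable")   # stable: lower index wins ties
    mask = np.zeros_like(g)
    np.put_along_axis(mask, order[:, :k], 1.0, axis=-1)
    return mask


def select_top_k(g, k: int) -> Tensor:
    """Sparse renormalized routing weights: keep K largest, renormalize to 1.

    Selection indices are computed on detached values; the renormalization is
    differentiable, so gradients flow to the selected gate outputs.
    """
    g = as_tensor(g)
    squeeze = g.ndim == 1
    g2 = g.reshape(1, -1) if squeeze else g
    mask = Tensor(top_k_mask(g2.data, k))
    kept = g2 * mask
    w = kept / kept.sum(axis=-1, keepdims=True)
    return w.reshape(-1) if squeeze else w


def aggregate_predictions(w, preds: list) -> Tensor:
    """p_final = sum_k w_k * p_k over the expert pool (unselected get w=0)."""
    w = as_tensor(w)
    e = w.shape[-1]
    if len(preds) != e:
        raise ValueError(f"{len(preds)} expert predictions for {e} gate weights")
    out = None
    for j, p in enumerate(preds):
        sel = np.zeros((e, 1))
        sel[j, 0] = 1.0
        wj = w @ Tensor(sel)                # (B, 1)
        term = as_tensor(p) * wj
        out = term if out is None else out + term
    return out


@dataclass
class MoEOutput:
    p_final: Tensor          # (B, C)
    gating: Tensor           # (B, E) dense softmax
    weights: Tensor          # (B, E) sparse renormalized top-K
    expert_preds: list = field(default_factory=list)   # E tensors of (B, C)


class MoEHead(Module):
    """Layer norm + noise + gate + expert pool over pooled feature vectors.

    The gate consumes the clean normalized features; experts consume the
    noise-perturbed features during training and the clean ones at eval.
    """

    def __init__(self, in_dim: int, n_classes: int, cfg: MoEConfig,
                 noise: NoiseConfig | None = None, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.n_classes = n_classes
        self.norm = LayerNorm(in_dim)
        self.noise = noise or NoiseConfig()
        self.noise_rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
        self.gate = Linear(in_dim, cfg.num_experts, rng)
        self.experts = [
            self.add_child(f"expert{j}", Expert(in_dim, cfg.hidden_dim, n_classes,
                                                cfg.dropout, rng))
            for j in range(cfg.num_experts)
        ]

    def expert_w1(self) -> list[Tensor]:
        return [ex.fc1.weight for ex in self.experts]

    def expert_w2(self) -> list[Tensor]:
        return [ex.fc2.weight for ex in self.experts]

    def __call__(self, h, top_k: int | None = None) -> MoEOutput:
        k = self.cfg.top_k if top_k is None else top_k
        h_norm = self.norm(as_tensor(h))
        h_expert = inject_noise(h_norm, self.noise, self.training, self.noise_rng)
        # The gate reads detached features: its cross-entropy target is a noisy
        # self-supervised label, and letting that gradient reshape the backbone
        # stalls representation learning.  The gate adapts to the features,
        # never the other way around.
        g = gate_forward(h_norm.detach(), self.gate)
        w = select_top_k(g, k)
        preds = [expert_forward(h_expert, ex, self.training) for ex in self.experts]
        p_final = aggregate_predictions(w, preds)
        return MoEOutput(p_final=p_final, gating=g, weights=w, expert_preds=preds)


class ViTMoEClassifier(Module):
    """End-to-end model: TinyViT backbone -> pooled features -> MoE head."""

    def __init__(self, n_classes: int, backbone: TinyViT | None = None,
                 moe: MoEConfig | None = None, noise: NoiseConfig | None = None,
                 pooling: str = "cls_token", seed: int = 0):
        super().__init__()
        self.backbone = backbone or TinyViT(seed=seed)
        self.pooling = pooling
        self.head = MoEHead(self.backbone.dim, n_classes, moe or MoEConfig(),
                            noise, seed=seed + 1)

    def __call__(self, images: np.ndarray) -> MoEOutput:
        tokens = self.backbone(images)
        h = pool_features(tokens, self.pooling, self.backbone.has_cls_token)
        return self.head(h)

    def predict(self, images: np.ndarray, batch_size: int = 128) -> np.ndarray:
        self.eval()
        out = []
        with no_grad():
            for i in range(0, len(images), batch_size):
                out.append(self(images[i:i + batch_size]).p_final.data)
        return np.concatenate(out).argmax(axis=-1)


class SingleHeadClassifier(Module):
    """Ablation baseline: the same backbone and expert-shaped MLP, no gating."""

    def __init__(self, n_classes: int, backbone: TinyViT | None = None,
                 hidden_dim: int = 256, dropout: float = 0.1,
                 noise: NoiseConfig | None = None, pooling: str = "cls_token",
                 seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed + 1)
        self.backbone = backbone or TinyViT(seed=seed)
        self.pooling = pooling
        self.norm = LayerNorm(self.backbone.dim)
        self.noise = noise or NoiseConfig()
        self.noise_rng = np.random.default_rng(np.random.SeedSequence([seed + 1, 7]))
        self.classifier = Expert(self.backbone.dim, hidden_dim, n_classes,
                                 dropout, rng)

    def __call__(self, images: np.ndarray) -> Tensor:
        tokens = self.backbone(images)
        h = pool_features(tokens, self.pooling, self.backbone.has_cls_token)
        h_norm = self.norm(h)
        h_in = inject_noise(h_norm, self.noise, self.training, self.noise_rng)
        return self.classifier(h_in)

    def predict(self, images: np.ndarray, batch_size: int = 128) -> np.ndarray:
        self.eval()
        out = []
        with no_grad():
            for i in range(0, len(images), batch_size):
                out.append(self(images[i:i + batch_size]).data)
        return np.concatenate(out).argmax(axis=-1)
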
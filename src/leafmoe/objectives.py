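"""The composite training objective: classification and gating cross-entropies
plus entropy, orthogonality and usage regularizers over the expert pool.

    L_total = L_class + L_gating
              + lambda_e * L_entropy + lambda_o * L_orthogonal + lambda_u * L_usage

Sign convention for the entropy term
------------------------------------
``L_entropy`` here is the *negative* Shannon entropy of the renormalized
top-K routing weights, (1/B) sum_i sum_j w_ij log w_ij, so it is 0 for a
one-hot routing (its maximum) and -log K for uniform routing over the K
selected experts (its minimum).  Minimizing the total with lambda_e >= 0
therefore pushes the gate toward high-entropy, balanced expert weights —
the behavior an entropy regularizer is meant to produce.  A "positive
entropy added to the loss" reading would reward confident gates instead,
contradicting its purpose, which is why this package fixes the sign.

The gating cross-entropy needs a per-instance target expert; no extra
annotation exists, so the target is self-supervised: the expert assigning
the highest probability to the true class (gradient-detached, ties to the
lower index).  The usage regularizer compares each expert's mean routing
weight against the uniform share 1/E over the full pool by default, because
its purpose is to keep *all* experts engaged; ``pool="selected"`` restricts
the target to 1/K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = ["LossWeights", "LossBundle", "classification_loss", "gating_targets",
           "gating_loss", "entropy_regularizer", "orthogonal_regularizer",
           "usage_regularizer", "total_loss"]

_EPS = 1e-12


@dataclass
class LossWeights:
    """Regularizer weights.

    The entropy weight defaults high enough to actually counteract the
    winner-take-all pull of the classification loss — weak entropy
    regularization leaves expert collapse essentially untouched.
    """

    lambda_entropy: float = 0.5
    lambda_orthogonal: float = 0.01
    lambda_usage: float = 0.1
    gating_enabled: bool = True
    orthogonal_on: str = "W1"     # which expert matrices the orthogonal term uses

    def __post_init__(self):
        if min(self.lambda_entropy, self.lambda_orthogonal, self.lambda_usage) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.orthogonal_on not in ("W1", "W2", "both"):
            raise ValueError(f"orthogonal_on must be W1/W2/both, "
                             f"got {self.orthogonal_on!r}")

    @staticmethod
    def none() -> "LossWeights":
        return LossWeights(0.0, 0.0, 0.0, gating_enabled=False)


@dataclass
class LossBundle:
    l_class: Tensor
    l_gating: Tensor
    l_entropy: Tensor
    l_orthogonal: Tensor
    l_usage: Tensor
    l_total: Tensor

    def scalars(self) -> dict[str, float]:
        return {name: getattr(self, name).item()
                for name in ("l_class", "l_gating", "l_entropy", "l_orthogonal",
                             "l_usage", "l_total")}


def _one_hot(indices: np.ndarray, depth: int) -> np.ndarray:
    indices = np.asarray(indices)
    if indices.min() < 0 or indices.max() >= depth:
        raise ValueError(f"index out of range [0, {depth})")
    eye = np.zeros((len(indices), depth))
    eye[np.arange(len(indices)), indices] = 1.0
    return eye


def classification_loss(p_final, labels) -> Tensor:
    """Mean cross-entropy of the aggregated prediction against true labels."""
    p = as_tensor(p_final)
    onehot = Tensor(_one_hot(labels, p.shape[-1]))
    return -((p + _EPS).log() * onehot).sum() / p.shape[0]


def gating_targets(expert_preds, labels) -> np.ndarray:
    """Self-supervised gate targets: expert with highest true-class probability.

    Operates on detached values; ties break toward the lower expert index.
    """
    labels = np.asarray(labels)
    stacked = np.stack([p.data if isinstance(p, Tensor) else np.asarray(p)
                        for p in expert_preds])          # (E, B, C)
    true_prob = stacked[:, np.arange(len(labels)), labels]   # (E, B)
    return true_prob.argmax(axis=0)                      # first max -> lower index


def gating_loss(g, targets) -> Tensor:
    """Mean cross-entropy of the dense gating distribution against targets."""
    g = as_tensor(g)
    onehot = Tensor(_one_hot(targets, g.shape[-1]))
    return -((g + _EPS).log() * onehot).sum() / g.shape[0]


def entropy_regularizer(w) -> Tensor:
    """Negative entropy of the routing weights: (1/B) sum_ij w_ij log w_ij.

    Zero entries contribute exactly zero (0 * log eps underflows to 0 via the
    product), matching the 0 log 0 := 0 convention.  Range [-log K, 0].
    """
    w = as_tensor(w)
    b = w.shape[0] if w.ndim > 1 else 1
    return (w * (w + _EPS).log()).sum() / b


def orthogonal_regularizer(weight_sets: list, which: str = "W1") -> Tensor:
    """Sum of pairwise Frobenius norms ||W_i W_j^T||_F across experts.

    ``weight_sets`` is either a list of matrices (one per expert) or, for
    ``which="both"``, a pair of such lists.  Zero iff every pairwise product
    vanishes, i.e. the experts' row spaces are mutually orthogonal.
    """
    if which == "both":
        first, second = weight_sets
        return orthogonal_regularizer(first, "W1") + orthogonal_regularizer(second, "W2")
    mats = [as_tensor(m) for m in weight_sets]
    if len(mats) < 2:
        raise ValueError("orthogonal regularizer needs at least 2 experts")
    shape = mats[0].shape
    for m in mats:
        if m.shape != shape:
            raise ValueError("all experts must share identical weight shapes")
    total = None
    for i in range(len(mats)):
        for j in range(i + 1, len(mats)):
            prod = mats[i] @ mats[j].swapaxes(-1, -2)
            norm = ((prod ** 2).sum() + 1e-16).sqrt()   # eps guards the grad at 0
            total = norm if total is None else total + norm
    return total


def usage_regularizer(w, num_experts: int | None = None,
                      pool: str = "full") -> Tensor:
    """Squared deviation of mean per-expert routing weight from uniform.

    With ``pool="full"`` (default) the target share is 1/E over the whole
    expert pool, using the sparse post-top-K weights (zeros for unselected);
    ``pool="selected"`` uses 1/K with K inferred from the weights' support.
    Range [0, 1 - 1/E]; the maximum is attained at total collapse.
    """
    w = as_tensor(w)
    if w.ndim == 1:
        w = w.reshape(1, -1)
    e_total = w.shape[-1] if num_experts is None else num_experts
    if w.shape[-1] != e_total:
        raise ValueError(f"weights have {w.shape[-1]} experts, expected {e_total}")
    usage = w.mean(axis=0)                           # (E,)
    if pool == "selected":
        k = int((np.abs(w.data) > 0).sum(axis=-1).max())
        target = 1.0 / max(k, 1)
    elif pool == "full":
        target = 1.0 / e_total
    else:
        raise ValueError(f"pool must be 'full' or 'selected', got {pool!r}")
    return ((usage - target) ** 2).sum()


def total_loss(l_class, l_gating, l_entropy, l_orthogonal, l_usage,
               weights: LossWeights) -> LossBundle:
    """Combine components into the weighted total; fail fast on NaN."""
    parts = {"l_class": as_tensor(l_class), "l_gating": as_tensor(l_gating),
             "l_entropy": as_tensor(l_entropy),
             "l_orthogonal": as_tensor(l_orthogonal), "l_usage": as_tensor(l_usage)}
    for name, t in parts.items():
        if not np.all(np.isfinite(t.data)):
            raise FloatingPointError(f"non-finite loss component: {name}")
    gate_term = parts["l_gating"] if weights.gating_enabled else Tensor(0.0)
    l_total = (parts["l_class"] + gate_term
               + weights.lambda_entropy * parts["l_entropy"]
               + weights.lambda_orthogonal * parts["l_orthogonal"]
               + weights.lambda_usage * parts["l_usage"])
    return LossBundle(parts["l_class"], parts["l_gating"], parts["l_entropy"],
                      parts["l_orthogonal"], parts["l_usage"], l_total)
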
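"""Training/evaluation loops, metrics, expert-usage tracking and the ablation
harnesses (expert-count sweep, regularization grid).

The loops are deliberately plain: seeded minibatch AdamW, every loss
component logged per epoch, and the per-expert mean routing weight tracked
each epoch so collapse dynamics are visible.  ``train`` accepts either an
end-to-end image classifier or a bare MoE head running on cached feature
vectors — the ablation harnesses use the latter to isolate gating dynamics
from representation learning.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .autodiff import Tensor, no_grad
from .moe import MoEConfig, MoEHead, MoEOutput, ViTMoEClassifier
from .nn import AdamW, Module
from .objectives import (LossWeights, classification_loss, entropy_regularizer,
                         gating_loss, gating_targets, orthogonal_regularizer,
                         total_loss, usage_regularizer)

__all__ = ["TrainConfig", "TrainingHistory", "MetricsReport", "train",
           "evaluate", "predict", "track_expert_usage", "sweep_experts",
           "ablate_regularizers", "mean_pairwise_similarity"]


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 32
    lr: float = 1e-3
    warmup_epochs: int = 2       # linear LR ramp; standard for from-scratch ViTs
    optimizer: str = "adamw"
    weight_decay: float = 0.01
    seed: int = 0
    deterministic: bool = True
    loss: LossWeights = field(default_factory=LossWeights)

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer.lower() != "adamw":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class TrainingHistory:
    """Per-epoch loss components, accuracies and per-expert mean usage."""

    losses: pd.DataFrame            # epoch rows: l_class .. l_total
    train_accuracy: np.ndarray
    val_accuracy: np.ndarray
    usage: np.ndarray               # (epochs, E) mean routing weight per expert

    def __len__(self):
        return len(self.losses)

    def to_frame(self) -> pd.DataFrame:
        df = self.losses.copy()
        df["train_accuracy"] = self.train_accuracy
        df["val_accuracy"] = self.val_accuracy
        for j in range(self.usage.shape[1]):
            df[f"usage_{j}"] = self.usage[:, j]
        return df


@dataclass
class MetricsReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    confusion: np.ndarray

    def to_dict(self) -> dict:
        out = {k: getattr(self, k) for k in
               ("accuracy", "macro_precision", "macro_recall", "macro_f1",
                "weighted_precision", "weighted_recall", "weighted_f1")}
        out["confusion"] = self.confusion.tolist()
        return out


def _as_xy(dataset):
    if hasattr(dataset, "images"):
        return dataset.images, dataset.labels
    x, y = dataset
    return np.asarray(x), np.asarray(y)


def _moe_head(model: Module) -> MoEHead | None:
    if isinstance(model, MoEHead):
        return model
    return getattr(model, "head", None) if isinstance(getattr(model, "head", None),
                                                      MoEHead) else None


def predict(model: Module, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Eval-mode argmax predictions for images or cached feature vectors."""
    model.eval()
    preds = []
    with no_grad():
        for i in range(0, len(x), batch_size):
            out = model(x[i:i + batch_size])
            p = out.p_final.data if isinstance(out, MoEOutput) else out.data
            preds.append(p.argmax(axis=-1))
    return np.concatenate(preds)


def _loss_bundle(model, out, yb, weights: LossWeights):
    head = _moe_head(model)
    if isinstance(out, MoEOutput):
        l_class = classification_loss(out.p_final, yb)
        if weights.gating_enabled:
            targets = gating_targets(out.expert_preds, yb)
            l_gating = gating_loss(out.gating, targets)
        else:
            l_gating = Tensor(0.0)
        l_entropy = entropy_regularizer(out.weights)
        l_usage = usage_regularizer(out.weights)
        if weights.orthogonal_on == "both":
            mats = [head.expert_w1(), head.expert_w2()]
        elif weights.orthogonal_on == "W2":
            mats = head.expert_w2()
        else:
            mats = head.expert_w1()
        l_orth = orthogonal_regularizer(mats, weights.orthogonal_on)
    else:   # single-head baseline: plain cross-entropy
        l_class = classification_loss(out, yb)
        l_gating = l_entropy = l_orth = l_usage = Tensor(0.0)
    return total_loss(l_class, l_gating, l_entropy, l_orth, l_usage, weights)


def train(model: Module, train_set, val_set, cfg: TrainConfig) -> TrainingHistory:
    """Seeded minibatch training; logs every loss component per epoch.

    Raises ``FloatingPointError`` with the offending component name if a loss
    goes non-finite.
    """
    x_train, y_train = _as_xy(train_set)
    if len(x_train) == 0:
        raise ValueError("empty training set")
    x_val, y_val = _as_xy(val_set)
    head = _moe_head(model)
    n_experts = head.cfg.num_experts if head is not None else 1

    params = model.parameters()
    opt = AdamW(params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))

    rows, train_accs, val_accs, usage_rows = [], [], [], []
    for epoch in range(cfg.epochs):
        if cfg.warmup_epochs > 0:
            opt.lr = cfg.lr * min(1.0, (epoch + 1) / cfg.warmup_epochs)
        model.train(True)
        order = shuffle_rng.permutation(len(x_train))
        epoch_losses: dict[str, float] = {}
        epoch_w_sum = np.zeros(n_experts)
        n_correct = 0
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            out = model(xb)
            bundle = _loss_bundle(model, out, yb, cfg.loss)
            opt.zero_grad()
            bundle.l_total.backward()
            opt.step()
            for name, value in bundle.scalars().items():
                epoch_losses[name] = epoch_losses.get(name, 0.0) + value
            p = out.p_final.data if isinstance(out, MoEOutput) else out.data
            n_correct += int((p.argmax(axis=-1) == yb).sum())
            if isinstance(out, MoEOutput):
                epoch_w_sum += out.weights.data.sum(axis=0)
            n_batches += 1
        rows.append({k: v / n_batches for k, v in epoch_losses.items()})
        train_accs.append(n_correct / len(x_train))
        val_accs.append(float((predict(model, x_val) == y_val).mean())
                        if len(x_val) else np.nan)
        usage_rows.append(epoch_w_sum / len(x_train) if n_experts > 1
                          else np.ones(1))
    return TrainingHistory(pd.DataFrame(rows), np.asarray(train_accs),
                           np.asarray(val_accs), np.stack(usage_rows))


def evaluate(model: Module, test_set, n_classes: int | None = None) -> MetricsReport:
    """Confusion-matrix-based metrics with macro and weighted averages."""
    x, y = _as_xy(test_set)
    y_hat = predict(model, x)
    if n_classes is None:
        n_classes = int(max(y.max(), y_hat.max())) + 1
    labels = np.arange(n_classes)
    present = np.unique(y)
    if len(present) < n_classes:
        warnings.warn(f"only {len(present)}/{n_classes} classes present in the "
                      "test set; macro averages skip absent classes",
                      stacklevel=2)
        macro_labels = present
    else:
        macro_labels = labels
    cm = confusion_matrix(y, y_hat, labels=labels)
    mp, mr, mf, _ = precision_recall_fscore_support(
        y, y_hat, labels=macro_labels, average="macro", zero_division=0)
    wp, wr, wf, _ = precision_recall_fscore_support(
        y, y_hat, labels=macro_labels, average="weighted", zero_division=0)
    return MetricsReport(float((y_hat == y).mean()), float(mp), float(mr),
                         float(mf), float(wp), float(wr), float(wf), cm)


def track_expert_usage(history: TrainingHistory,
                       collapse_threshold: float = 0.01) -> pd.DataFrame:
    """Per-expert min/mean/final usage plus a collapse flag.

    The collapse flag fires if any expert's final-epoch mean routing weight
    falls below ``collapse_threshold``.
    """
    if len(history) == 0:
        raise ValueError("empty training history")
    usage = history.usage
    df = pd.DataFrame({
        "expert": np.arange(usage.shape[1]),
        "min_usage": usage.min(axis=0),
        "mean_usage": usage.mean(axis=0),
        "final_usage": usage[-1],
    })
    df.attrs["collapsed"] = bool((usage[-1] < collapse_threshold).any())
    return df


def mean_pairwise_similarity(mats: list[np.ndarray]) -> float:
    """Mean over expert pairs of ||W_i W_j^T||_F / (||W_i||_F ||W_j||_F)."""
    arrs = [m.data if isinstance(m, Tensor) else np.asarray(m) for m in mats]
    sims = []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            denom = np.linalg.norm(arrs[i]) * np.linalg.norm(arrs[j])
            sims.append(np.linalg.norm(arrs[i] @ arrs[j].T) / max(denom, 1e-12))
    return float(np.mean(sims))


def sweep_experts(model_factory, train_set, val_set, base_cfg: TrainConfig,
                  k_values, seeds) -> pd.DataFrame:
    """Grid over top-K and seeds; ``model_factory(k, seed)`` builds the model.

    Returns one row per (K, seed) with the final validation accuracy and
    runtime; ``df.attrs['best_k']`` holds the accuracy-argmax K.
    """
    rows = []
    for k in k_values:
        for seed in seeds:
            model = model_factory(k, seed)
            cfg = TrainConfig(epochs=base_cfg.epochs, batch_size=base_cfg.batch_size,
                              lr=base_cfg.lr, weight_decay=base_cfg.weight_decay,
                              seed=seed, loss=base_cfg.loss)
            t0 = time.perf_counter()
            history = train(model, train_set, val_set, cfg)
            rows.append({"K": k, "seed": seed,
                         "val_accuracy": history.val_accuracy[-1],
                         "runtime_s": time.perf_counter() - t0})
    df = pd.DataFrame(rows)
    df.attrs["best_k"] = int(df.groupby("K")["val_accuracy"].mean().idxmax())
    return df


def ablate_regularizers(model_factory, train_set, val_set, base_cfg: TrainConfig,
                        lambda_grid, seeds) -> pd.DataFrame:
    """Grid over (lambda_e, lambda_o, lambda_u) triples and seeds.

    Each row records accuracy, the final expert-usage distribution and the
    mean pairwise normalized expert-weight similarity — the surface-plot-ready
    summary for studying regularizer interplay.
    """
    rows = []
    for le, lo, lu in lambda_grid:
        for seed in seeds:
            model = model_factory(seed)
            weights = LossWeights(lambda_entropy=le, lambda_orthogonal=lo,
                                  lambda_usage=lu,
                                  gating_enabled=base_cfg.loss.gating_enabled,
                                  orthogonal_on=base_cfg.loss.orthogonal_on)
            cfg = TrainConfig(epochs=base_cfg.epochs, batch_size=base_cfg.batch_size,
                              lr=base_cfg.lr, weight_decay=base_cfg.weight_decay,
                              seed=seed, loss=weights)
            history = train(model, train_set, val_set, cfg)
            head = _moe_head(model)
            rows.append({
                "lambda_entropy": le, "lambda_orthogonal": lo, "lambda_usage": lu,
                "seed": seed,
                "val_accuracy": history.val_accuracy[-1],
                "final_usage": history.usage[-1].tolist(),
                "min_final_usage": float(history.usage[-1].min()),
                "max_final_usage": float(history.usage[-1].max()),
                "weight_similarity": mean_pairwise_similarity(head.expert_w1()),
            })
    return pd.DataFrame(rows)
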
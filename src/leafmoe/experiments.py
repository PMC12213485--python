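"""Reproducible study harnesses over the synthetic benchmark.

Three experiments mirror the behavioral claims the architecture makes:

* ``collapse_experiment`` — with the entropy regularizer off, the gate is
  free to concentrate on few experts (expert collapse); with it on, every
  expert keeps a meaningful share of the routing mass.
* ``orthogonality_experiment`` — the orthogonality penalty measurably
  decorrelates the experts' first-layer weight matrices.
* ``desk_scale_experiment`` — the small ViT + MoE learns the lab domain to
  high accuracy and transfers to the wild domain at least as well as an
  identically trained single-classifier head.

The two regularizer experiments train only the MoE head on features cached
from a frozen, seeded small ViT: that isolates gating dynamics from
representation learning and keeps runs cheap.  Each experiment fixes its
dataset conditions (6 classes, severity 0.7 lab images) and varies only the
run seed, so conditions stay paired across the contrasted settings.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .autodiff import no_grad
from .backbone import NoiseConfig, TinyViT, pool_features
from .moe import MoEConfig, MoEHead, SingleHeadClassifier, ViTMoEClassifier
from .objectives import LossWeights
from .trainer import TrainConfig, mean_pairwise_similarity, predict, train
from .synth import SyntheticDatasetSpec, generate_dataset

__all__ = ["cached_features", "collapse_experiment", "orthogonality_experiment",
           "desk_scale_experiment", "REGULARIZER_SET_SPEC", "DESK_TRAIN_SPEC"]

# study conditions for the regularizer experiments: 6-class lab set,
# pronounced lesions, 150 images per class
REGULARIZER_SET_SPEC = SyntheticDatasetSpec(n_classes=6, images_per_class=150,
                                            severity=0.7, domain="lab", seed=123)
# desk-scale benchmark: default generator conditions, 100 images per class
DESK_TRAIN_SPEC = SyntheticDatasetSpec(n_classes=6, images_per_class=100,
                                       severity=0.7, domain="lab", seed=11)
_DESK_TEST_PER_CLASS = 30


def cached_features(dataset, backbone_seed: int = 500,
                    backbone: TinyViT | None = None) -> np.ndarray:
    """Mean-pooled tokens of a frozen seeded ViT for every image (one pass)."""
    vit = backbone or TinyViT(image_size=dataset.images.shape[1], seed=backbone_seed)
    vit.eval()
    feats = []
    with no_grad():
        for i in range(0, len(dataset), 256):
            tokens = vit(dataset.images[i:i + 256])
            feats.append(pool_features(tokens, "mean", vit.has_cls_token).data)
    return np.concatenate(feats)


def _head_run(features, labels, n_classes, weights: LossWeights, seed: int,
              epochs: int = 30, num_experts: int = 5, top_k: int | None = None):
    """Train a bare MoE head on cached features; returns (history, head)."""
    cfg = MoEConfig(num_experts=num_experts,
                    top_k=num_experts if top_k is None else top_k,
                    hidden_dim=64, dropout=0.1)
    head = MoEHead(features.shape[1], n_classes, cfg, NoiseConfig(), seed=seed)
    # head-only runs tolerate (and need) a faster schedule than end-to-end ones
    tc = TrainConfig(epochs=epochs, batch_size=32, lr=2e-3, seed=seed, loss=weights)
    history = train(head, (features, labels), (features[:0], labels[:0]), tc)
    return history, head


def collapse_experiment(seeds=(0, 1, 2, 3, 4), lambda_entropy: float | None = None,
                        epochs: int = 30) -> pd.DataFrame:
    """Expert-usage dynamics with and without the entropy regularizer.

    Dense gating over 5 experts (every expert's contribution is visible) and
    all other auxiliary losses off, so the only forces on the gate are the
    classification loss (whose winner-take-all pull produces collapse) and,
    in the contrasted condition, the entropy regularizer.  One row per
    (seed, condition) with final max/min expert usage.
    """
    if lambda_entropy is None:
        lambda_entropy = LossWeights().lambda_entropy
    data = generate_dataset(REGULARIZER_SET_SPEC)
    features = cached_features(data)
    rows = []
    for seed in seeds:
        for le in (0.0, lambda_entropy):
            weights = LossWeights(lambda_entropy=le, lambda_orthogonal=0.0,
                                  lambda_usage=0.0, gating_enabled=False)
            history, _ = _head_run(features, data.labels, data.n_classes,
                                   weights, seed, epochs)
            final = history.usage[-1]
            rows.append({"seed": seed, "lambda_entropy": le,
                         "max_final_usage": float(final.max()),
                         "min_final_usage": float(final.min()),
                         "final_usage": final.tolist()})
    return pd.DataFrame(rows)


def orthogonality_experiment(seeds=(0, 1, 2, 3, 4),
                             lambda_orthogonal: float = 0.01,
                             epochs: int = 30) -> pd.DataFrame:
    """Pairwise expert-weight similarity with and without the orthogonal term.

    Same data and head as the collapse experiment; paired seeds; reports the
    mean pairwise normalized ||W_i W_j^T||_F of the first-layer matrices.
    """
    data = generate_dataset(REGULARIZER_SET_SPEC)
    features = cached_features(data)
    rows = []
    for seed in seeds:
        for lo in (0.0, lambda_orthogonal):
            weights = LossWeights(lambda_entropy=0.0, lambda_orthogonal=lo,
                                  lambda_usage=0.0, gating_enabled=False)
            _, head = _head_run(features, data.labels, data.n_classes,
                                weights, seed, epochs)
            rows.append({"seed": seed, "lambda_orthogonal": lo,
                         "weight_similarity":
                             mean_pairwise_similarity(head.expert_w1())})
    return pd.DataFrame(rows)


def desk_scale_experiment(seeds=(0, 1, 2, 3, 4), epochs: int = 30) -> pd.DataFrame:
    """End-to-end small-ViT benchmark: MoE (E=10, K=3) vs single head, paired.

    Trains on the default lab set, evaluates on held-out lab and wild sets
    drawn from the same class semantics.  One row per seed with eval-mode
    train / lab-test accuracies for the MoE model and wild-domain accuracies
    for both models.
    """
    train_set = generate_dataset(DESK_TRAIN_SPEC)
    test_spec = SyntheticDatasetSpec(
        n_classes=DESK_TRAIN_SPEC.n_classes,
        images_per_class=_DESK_TEST_PER_CLASS,
        severity=DESK_TRAIN_SPEC.severity, seed=DESK_TRAIN_SPEC.seed + 1)
    lab_test = generate_dataset(test_spec)
    wild_test = generate_dataset(dataclasses.replace(test_spec, domain="wild"))

    rows = []
    for seed in seeds:
        moe = ViTMoEClassifier(train_set.n_classes,
                               TinyViT(seed=seed),
                               MoEConfig(num_experts=10, top_k=3, hidden_dim=64),
                               seed=seed)
        cfg = TrainConfig(epochs=epochs, batch_size=32, lr=1e-3, seed=seed)
        train(moe, train_set, (lab_test.images[:0], lab_test.labels[:0]), cfg)

        single = SingleHeadClassifier(train_set.n_classes, TinyViT(seed=seed),
                                      hidden_dim=64, seed=seed)
        train(single, train_set, (lab_test.images[:0], lab_test.labels[:0]), cfg)

        rows.append({
            "seed": seed,
            "moe_train_acc": float((predict(moe, train_set.images)
                                    == train_set.labels).mean()),
            "moe_lab_acc": float((predict(moe, lab_test.images)
                                  == lab_test.labels).mean()),
            "moe_wild_acc": float((predict(moe, wild_test.images)
                                   == wild_test.labels).mean()),
            "single_wild_acc": float((predict(single, wild_test.images)
                                      == wild_test.labels).mean()),
        })
    return pd.DataFrame(rows)
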
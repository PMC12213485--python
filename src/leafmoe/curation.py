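"""Dataset curation: cluster-based per-class downsampling and cross-dataset
divergence reports.

Redundancy-heavy classes are thinned by embedding per-image deep features
with t-SNE, k-means clustering the 2D embedding per class, and keeping one
representative per cluster — the medoid, i.e. the actual image nearest its
centroid, which makes the historically manual pick reproducible.  Domain
shift between two datasets is reported as class-wise and overall KL
divergence between diagonal-Gaussian fits to their feature clouds, plus
per-channel RGB pixel statistics.

Feature extractors here need no downloads: raw downsampled pixels, a seeded
random projection of them, or the pooled tokens of a (optionally trained)
small vision transformer.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .autodiff import no_grad
from .backbone import TinyViT, pool_features
from .synth import LabeledImageSet

__all__ = ["TsneConfig", "CurationPlan", "DomainShiftReport",
           "extract_curation_features", "embed_tsne", "cluster_and_select",
           "downsample_dataset", "kl_report", "pixel_stats",
           "gaussian_kl_diagonal"]


@dataclass
class TsneConfig:
    n_components: int = 2
    metric: str = "euclidean"
    perplexity: float = 30.0
    learning_rate: float = 500.0
    seed: int = 0


@dataclass
class CurationPlan:
    """Per-class cluster assignments and the chosen representatives."""

    cluster_ids: dict[int, np.ndarray]          # class -> per-image cluster id
    selected: dict[int, list[str]]              # class -> representative image ids
    n_clusters: int

    @property
    def selected_ids(self) -> list[str]:
        return [i for ids in self.selected.values() for i in ids]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"label": c, "id": i} for c, ids in self.selected.items()
                for i in ids]
        return pd.DataFrame(rows)


@dataclass
class DomainShiftReport:
    class_kl: dict[int, float]
    overall_kl: float
    pixel_stats_a: dict[str, list[float]]
    pixel_stats_b: dict[str, list[float]]
    skipped_classes: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"class_kl": {str(k): v for k, v in self.class_kl.items()},
                "overall_kl": self.overall_kl,
                "pixel_stats_a": self.pixel_stats_a,
                "pixel_stats_b": self.pixel_stats_b,
                "skipped_classes": self.skipped_classes}


# --------------------------------------------------------------------------
# feature extraction

def _pixel_features(images: np.ndarray, side: int = 16) -> np.ndarray:
    """Block-mean downsample to side x side and flatten."""
    b, s, _, c = images.shape
    f = s // side
    x = images[:, :side * f, :side * f, :].reshape(b, side, f, side, f, c)
    return x.mean(axis=(2, 4)).reshape(b, -1)


def extract_curation_features(images, extractor: str = "pixel",
                              seed: int = 0, model: TinyViT | None = None,
                              out_dim: int = 128) -> np.ndarray:
    """One fixed-length vector per image; extractors need no downloads.

    ``pixel``: block-mean downsampled RGB, flattened.
    ``random-projection``: seeded Gaussian projection of the pixel features
    to ``out_dim`` (distance-preserving, parameter-free).
    ``tiny-vit``: mean-pooled tokens of a small ViT — pass a trained model
    for learned features, otherwise a seeded random-weight one is used.
    """
    arr = images.images if isinstance(images, LabeledImageSet) else np.asarray(images)
    if extractor == "pixel":
        return _pixel_features(arr)
    if extractor == "random-projection":
        base = _pixel_features(arr, side=min(32, arr.shape[1]))
        rng = np.random.default_rng(seed)
        proj = rng.normal(0.0, 1.0 / np.sqrt(base.shape[1]),
                          size=(base.shape[1], out_dim))
        return base @ proj
    if extractor == "tiny-vit":
        vit = model or TinyViT(image_size=arr.shape[1], seed=seed)
        vit.eval()
        feats = []
        with no_grad():
            for i in range(0, len(arr), 256):
                tokens = vit(arr[i:i + 256])
                feats.append(pool_features(tokens, "mean", vit.has_cls_token).data)
        return np.concatenate(feats)
    raise ValueError(f"unknown extractor {extractor!r}")


# --------------------------------------------------------------------------
# embedding / clustering

def embed_tsne(features: np.ndarray, cfg: TsneConfig | None = None) -> np.ndarray:
    """Seeded t-SNE to 2D (perplexity 30, learning rate 500 by default)."""
    cfg = cfg or TsneConfig()
    n = len(features)
    if n <= cfg.perplexity:
        raise ValueError(f"{n} samples cannot support perplexity {cfg.perplexity}")
    if n < 3 * cfg.perplexity:
        warnings.warn(f"only {n} samples for perplexity {cfg.perplexity}; "
                      "3x perplexity is recommended", stacklevel=2)
    tsne = TSNE(n_components=cfg.n_components, metric=cfg.metric,
                perplexity=cfg.perplexity, learning_rate=cfg.learning_rate,
                init="pca", random_state=cfg.seed)
    return tsne.fit_transform(np.asarray(features, dtype=np.float64))


def cluster_and_select(embedding: np.ndarray, n_clusters: int,
                       seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """K-means on the embedding; representative = medoid of each cluster.

    Returns (cluster id per point, representative point indices).  If the
    class is smaller than ``n_clusters`` every point becomes its own cluster.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    embedding = np.asarray(embedding)
    if len(embedding) == 0:
        raise ValueError("empty embedding")
    k = min(n_clusters, len(embedding))
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    ids = km.fit_predict(embedding)
    reps = np.empty(k, dtype=np.int64)
    for c in range(k):
        members = np.flatnonzero(ids == c)
        d = np.linalg.norm(embedding[members] - km.cluster_centers_[c], axis=1)
        reps[c] = members[d.argmin()]
    return ids, reps


def downsample_dataset(dataset: LabeledImageSet, n_per_class: int,
                       extractor: str = "pixel", tsne: TsneConfig | None = None,
                       seed: int = 0, model: TinyViT | None = None) -> CurationPlan:
    """Build a balanced subset: per class, embed, cluster, keep one medoid each.

    Classes smaller than ``n_per_class`` are kept whole.  The perplexity is
    capped per class at (class size - 1) / 3 so small classes still embed.
    """
    tsne = tsne or TsneConfig(seed=seed)
    features = extract_curation_features(dataset, extractor, seed=seed, model=model)
    cluster_ids: dict[int, np.ndarray] = {}
    selected: dict[int, list[str]] = {}
    for c in np.unique(dataset.labels):
        idx = np.flatnonzero(dataset.labels == c)
        if len(idx) <= n_per_class:
            cluster_ids[int(c)] = np.arange(len(idx))
            selected[int(c)] = [dataset.ids[i] for i in idx]
            continue
        class_tsne = tsne
        cap = max(2.0, (len(idx) - 1) / 3)
        if tsne.perplexity > cap:
            class_tsne = dataclasses.replace(tsne, perplexity=cap)
        emb = embed_tsne(features[idx], class_tsne)
        ids, reps = cluster_and_select(emb, n_per_class, seed=seed)
        cluster_ids[int(c)] = ids
        selected[int(c)] = [dataset.ids[idx[r]] for r in sorted(reps)]
    return CurationPlan(cluster_ids, selected, n_per_class)


# --------------------------------------------------------------------------
# divergence reporting

def gaussian_kl_diagonal(mu_a, var_a, mu_b, var_b) -> float:
    """Closed-form KL(N(mu_a, diag var_a) || N(mu_b, diag var_b))."""
    mu_a, var_a = np.asarray(mu_a, dtype=np.float64), np.asarray(var_a, dtype=np.float64)
    mu_b, var_b = np.asarray(mu_b, dtype=np.float64), np.asarray(var_b, dtype=np.float64)
    return float(0.5 * np.sum(var_a / var_b + (mu_b - mu_a) ** 2 / var_b
                              - 1.0 + np.log(var_b / var_a)))


def _fit_kl(fa: np.ndarray, fb: np.ndarray, var_floor: float) -> float:
    mu_a, var_a = fa.mean(axis=0), np.maximum(fa.var(axis=0), var_floor)
    mu_b, var_b = fb.mean(axis=0), np.maximum(fb.var(axis=0), var_floor)
    return gaussian_kl_diagonal(mu_a, var_a, mu_b, var_b)


def kl_report(features_a: np.ndarray, features_b: np.ndarray,
              labels_a=None, labels_b=None,
              images_a=None, images_b=None,
              var_floor: float = 1e-6) -> DomainShiftReport:
    """Class-wise and overall KL between diagonal-Gaussian feature fits.

    Classes with fewer than 2 samples on either side are skipped with a
    warning.  The overall row pools every sample regardless of class.  Pass
    image arrays to include RGB pixel statistics in the report.
    """
    features_a, features_b = np.asarray(features_a), np.asarray(features_b)
    class_kl: dict[int, float] = {}
    skipped: list[int] = []
    if labels_a is not None and labels_b is not None:
        labels_a, labels_b = np.asarray(labels_a), np.asarray(labels_b)
        shared = np.intersect1d(np.unique(labels_a), np.unique(labels_b))
        for c in shared:
            fa = features_a[labels_a == c]
            fb = features_b[labels_b == c]
            if len(fa) < 2 or len(fb) < 2:
                warnings.warn(f"class {c}: fewer than 2 samples on one side; "
                              "row skipped", stacklevel=2)
                skipped.append(int(c))
                continue
            class_kl[int(c)] = _fit_kl(fa, fb, var_floor)
    overall = _fit_kl(features_a, features_b, var_floor)
    stats_a = pixel_stats(images_a) if images_a is not None else {}
    stats_b = pixel_stats(images_b) if images_b is not None else {}
    return DomainShiftReport(class_kl, overall, stats_a, stats_b, skipped)


def pixel_stats(dataset) -> dict[str, list[float]]:
    """Per-channel mean and std over all pixels of all images, in [0, 1]."""
    arr = dataset.images if isinstance(dataset, LabeledImageSet) else np.asarray(dataset)
    if arr.size == 0:
        raise ValueError("empty dataset")
    flat = arr.reshape(-1, arr.shape[-1]).astype(np.float64)
    return {"mean": flat.mean(axis=0).tolist(), "std": flat.std(axis=0).tolist()}
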
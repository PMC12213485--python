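"""Curation contracts: features, embedding, clustering, KL reports, pixels."""

import dataclasses

import numpy as np
import pytest
from sklearn.metrics import silhouette_score

from leafmoe.curation import (CurationPlan, TsneConfig, cluster_and_select,
                              downsample_dataset, embed_tsne,
                              extract_curation_features, gaussian_kl_diagonal,
                              kl_report, pixel_stats)
from leafmoe.synth import (SyntheticDatasetSpec, generate_dataset,
                           make_domain_pair, plant_redundancy)


@pytest.fixture(scope="module")
def duplicate_heavy_class():
    """5 distinct base images x 40 near-duplicates each, single class."""
    base = generate_dataset(SyntheticDatasetSpec(n_classes=2, images_per_class=5,
                                                 severity=0.8, seed=3))
    cls0 = base.subset(np.flatnonzero(base.labels == 0))
    return plant_redundancy(cls0, 40, jitter=0.02, seed=9)


class TestFeatures:
    def test_one_vector_per_image_constant_length(self, small_lab_set):
        feats = extract_curation_features(small_lab_set, "pixel")
        assert feats.shape[0] == len(small_lab_set)
        assert feats.ndim == 2

    @pytest.mark.parametrize("extractor", ["pixel", "random-projection", "tiny-vit"])
    def test_identical_images_give_identical_vectors(self, extractor, small_lab_set):
        doubled = np.concatenate([small_lab_set.images[:3]] * 2)
        feats = extract_curation_features(doubled, extractor, seed=0)
        np.testing.assert_allclose(feats[:3], feats[3:], atol=1e-12)

    def test_duplicate_groups_are_tight_in_feature_space(self):
        base = generate_dataset(SyntheticDatasetSpec(
            n_classes=2, images_per_class=5, severity=0.8, seed=3))
        cls0 = base.subset(np.flatnonzero(base.labels == 0))
        dupes = plant_redundancy(cls0, 40, jitter=0.002, seed=9)
        feats = extract_curation_features(dupes, "pixel")
        group = np.array([int(i.split("-c0-i")[1].split("-")[0])
                          for i in dupes.ids])
        within, between = [], []
        rng = np.random.default_rng(0)
        for _ in range(300):
            i, j = rng.integers(0, len(feats), 2)
            d = np.linalg.norm(feats[i] - feats[j])
            (within if group[i] == group[j] else between).append(d)
        assert np.mean(within) < 0.2 * np.mean(between)

    def test_unknown_extractor_rejected(self, small_lab_set):
        with pytest.raises(ValueError):
            extract_curation_features(small_lab_set, "vgg16")


class TestTsne:
    def test_point_count_and_determinism(self, rng):
        feats = rng.normal(size=(120, 10))
        cfg = TsneConfig(seed=1)
        emb1 = embed_tsne(feats, cfg)
        emb2 = embed_tsne(feats, cfg)
        assert emb1.shape == (120, 2)
        np.testing.assert_array_equal(emb1, emb2)

    def test_too_few_samples_hard_error(self, rng):
        with pytest.raises(ValueError, match="perplexity"):
            embed_tsne(rng.normal(size=(20, 5)), TsneConfig(perplexity=30))

    def test_low_sample_count_warns(self, rng):
        with pytest.warns(UserWarning, match="recommended"):
            embed_tsne(rng.normal(size=(40, 5)), TsneConfig(perplexity=15))

    def test_separated_clusters_stay_separated(self, rng):
        feats = np.concatenate([rng.normal(0, 0.1, size=(60, 8)),
                                rng.normal(5, 0.1, size=(60, 8))])
        labels = np.repeat([0, 1], 60)
        emb = embed_tsne(feats, TsneConfig(seed=0))
        assert silhouette_score(emb, labels) > 0.5


class TestClusterSelect:
    def test_exact_representative_count(self, rng):
        emb = rng.normal(size=(500, 2))
        ids, reps = cluster_and_select(emb, 100, seed=0)
        assert len(reps) == 100
        assert len(np.unique(reps)) == 100

    def test_small_class_kept_whole(self, rng):
        emb = rng.normal(size=(50, 2))
        _, reps = cluster_and_select(emb, 100, seed=0)
        assert len(reps) == 50

    def test_representative_is_cluster_medoid(self, rng):
        emb = rng.normal(size=(60, 2))
        ids, reps = cluster_and_select(emb, 5, seed=0)
        for c, r in enumerate(reps):
            assert ids[r] == c

    def test_planted_modes_all_covered(self, rng):
        modes = rng.normal(0, 0.05, size=(3, 1, 2)) + np.array(
            [[0, 0], [10, 0], [0, 10]])[:, None, :]
        emb = np.concatenate([m + rng.normal(0, 0.1, size=(40, 2)) for m in modes])
        ids, reps = cluster_and_select(emb, 10, seed=0)
        mode_of = np.repeat([0, 1, 2], 40)
        assert set(mode_of[reps]) == {0, 1, 2}

    def test_empty_embedding_rejected(self):
        with pytest.raises(ValueError):
            cluster_and_select(np.zeros((0, 2)), 3)


class TestDownsample:
    def test_plan_counts_and_determinism(self, duplicate_heavy_class):
        plan = downsample_dataset(duplicate_heavy_class, 50, seed=0)
        assert len(plan.selected[0]) == 50
        plan2 = downsample_dataset(duplicate_heavy_class, 50, seed=0)
        assert plan.selected == plan2.selected
        assert all(sel in duplicate_heavy_class.ids for sel in plan.selected_ids)

    def test_identity_when_n_exceeds_class_size(self, small_lab_set):
        plan = downsample_dataset(small_lab_set, 1000, seed=0)
        assert sorted(plan.selected_ids) == sorted(small_lab_set.ids)

    def test_plan_frame_layout(self, small_lab_set):
        plan = downsample_dataset(small_lab_set, 1000, seed=0)
        df = plan.to_frame()
        assert set(df.columns) == {"label", "id"} and len(df) == len(small_lab_set)


class TestKlReport:
    def test_self_divergence_is_zero(self, rng):
        f = rng.normal(size=(100, 6))
        labels = rng.integers(0, 3, size=100)
        report = kl_report(f, f, labels, labels)
        assert report.overall_kl == pytest.approx(0.0, abs=1e-9)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in report.class_kl.values())

    def test_unit_gaussian_shift_closed_form(self):
        assert gaussian_kl_diagonal([0.0], [1.0], [1.0], [1.0]) == pytest.approx(0.5, abs=1e-9)
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, size=(200_000, 1))
        b = rng.normal(1, 1, size=(200_000, 1))
        assert kl_report(a, b).overall_kl == pytest.approx(0.5, abs=0.02)

    def test_nonnegative_on_random_fits(self, rng):
        for _ in range(20):
            a = rng.normal(rng.normal(), abs(rng.normal()) + 0.1, size=(50, 4))
            b = rng.normal(rng.normal(), abs(rng.normal()) + 0.1, size=(60, 4))
            assert kl_report(a, b).overall_kl >= 0.0

    def test_small_class_skipped_with_warning(self, rng):
        f = rng.normal(size=(10, 3))
        labels_a = np.array([0] * 9 + [1])
        labels_b = np.array([0] * 8 + [1] * 2)
        with pytest.warns(UserWarning, match="skipped"):
            report = kl_report(f, f, labels_a, labels_b)
        assert report.skipped_classes == [1]
        assert 1 not in report.class_kl

    def test_domain_pair_diverges_more_than_lab_halves(self):
        lab, wild = make_domain_pair(SyntheticDatasetSpec(
            n_classes=3, images_per_class=60, seed=5))
        fl = extract_curation_features(lab, "pixel")
        fw = extract_curation_features(wild, "pixel")
        half_a, half_b = fl[::2], fl[1::2]
        assert (kl_report(fl, fw).overall_kl
                > 5 * kl_report(half_a, half_b).overall_kl)


class TestPixelStats:
    def test_constant_images(self):
        stats = pixel_stats(np.full((3, 8, 8, 3), 0.5))
        np.testing.assert_allclose(stats["mean"], 0.5)
        np.testing.assert_allclose(stats["std"], 0.0)

    def test_half_black_half_white(self):
        imgs = np.concatenate([np.zeros((2, 4, 4, 3)), np.ones((2, 4, 4, 3))])
        stats = pixel_stats(imgs)
        np.testing.assert_allclose(stats["mean"], 0.5)
        np.testing.assert_allclose(stats["std"], 0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pixel_stats(np.zeros((0, 4, 4, 3)))

    def test_default_pair_direction_wild_darker(self):
        lab, wild = make_domain_pair(SyntheticDatasetSpec(
            n_classes=2, images_per_class=40, seed=8))
        lab_mean = np.array(pixel_stats(lab)["mean"])
        wild_mean = np.array(pixel_stats(wild)["mean"])
        # clutter-dominated wild background renders darker than the bright
        # lab bench on every channel
        assert (wild_mean < lab_mean).all()
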
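"""Image embeddings, triple generation and triplet-loss training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryoclust.imgembed import (
    BackboneUnavailableError,
    SiameseConfig,
    SiameseEmbedder,
    TinyCNNEmbedder,
    generate_triples,
    load_encoder,
    pretrained_embed,
    save_encoder,
    siamese_embed,
    split_complexes,
    train_siamese,
    triplet_loss,
)


class TestTinyCNN:
    def test_shape_and_duplicate_rows(self, rng):
        imgs = rng.random((6, 32, 32))
        imgs[3] = imgs[0]
        emb = pretrained_embed(imgs, "tiny-cnn", seed=0)
        assert emb.shape == (6, TinyCNNEmbedder.feature_dim)
        assert np.array_equal(emb[0], emb[3])

    def test_seeded_determinism(self, rng):
        imgs = rng.random((4, 32, 32))
        a = pretrained_embed(imgs, "tiny-cnn", seed=1)
        b = pretrained_embed(imgs, "tiny-cnn", seed=1)
        assert np.array_equal(a, b)
        c = pretrained_embed(imgs, "tiny-cnn", seed=2)
        assert not np.array_equal(a, c)

    def test_pretrained_backbones_raise_with_fallback_hint(self, rng):
        imgs = rng.random((2, 32, 32))
        with pytest.raises(BackboneUnavailableError, match="tiny-cnn"):
            pretrained_embed(imgs, "resnet18")

    def test_unknown_backbone_errors(self, rng):
        with pytest.raises(ValueError, match="unknown backbone"):
            pretrained_embed(rng.random((2, 16, 16)), "lenet")


class TestGenerateTriples:
    def test_forced_negative(self):
        spec = generate_triples(["a", "a", "b"], n_negatives=10, seed=0)
        assert len(spec) == 10
        assert all(t[2] == 2 for t in spec.triples)

    def test_random_mode_count_formula(self):
        labels = ["a"] * 3 + ["b"] * 3
        spec = generate_triples(labels, n_negatives=10, seed=0)
        assert len(spec) == (3 + 3) * 10  # C(3,2)=3 pairs per class

    def test_per_class_count(self):
        labels = np.repeat(np.arange(4), 2)
        spec = generate_triples(labels, mode="per_class", seed=0)
        # one pair per class, 3 negatives (one per other class)
        assert len(spec) == 4 * 1 * 3

    def test_all_triples_valid(self):
        labels = np.array([0, 0, 0, 1, 1, 2, 2, 2])
        spec = generate_triples(labels, n_negatives=5, seed=3)
        spec.validate(labels)  # raises on violation

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            generate_triples([1, 1, 1])


class TestTripletLoss:
    def test_equal_pos_neg_gives_margin(self, rng):
        a, b = rng.normal(size=(2, 8))
        assert np.isclose(triplet_loss(a, b, b, margin=0.5), 0.5)

    def test_clamped_at_zero(self):
        eA = np.zeros(2)
        eP = np.array([np.sqrt(0.2), 0])  # d^2 = 0.2
        eN = np.array([1.0, 0])  # d^2 = 1.0
        assert triplet_loss(eA, eP, eN, margin=0.5) == 0.0

    def test_default_margin_half(self):
        eA = np.zeros(1)
        eP = np.array([np.sqrt(1.1)])
        eN = np.array([1.0])
        assert np.isclose(triplet_loss(eA, eP, eN), 0.6)

    def test_unsquared_variant(self):
        eA, eP, eN = np.zeros(1), np.array([3.0]), np.array([1.0])
        assert np.isclose(triplet_loss(eA, eP, eN, margin=0.5,
                                       squared=False), 2.5, atol=1e-5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.01, 2.0))
    def test_nonnegative_and_zero_when_separated(self, seed, margin):
        r = np.random.default_rng(seed)
        eA, eP, eN = r.normal(size=(3, 4))
        loss = triplet_loss(eA, eP, eN, margin)
        assert loss >= 0.0
        dAP = np.sum((eA - eP) ** 2)
        dAN = np.sum((eA - eN) ** 2)
        if dAN >= dAP + margin:
            assert loss == 0.0


class TestSplitComplexes:
    def test_seventy_thirty_rounding(self):
        train, test = split_complexes(np.repeat(np.arange(10), 2))
        assert len(train) == 7 and len(test) == 3

    def test_partition_property(self):
        labels = np.repeat(np.arange(6), 3)
        train, test = split_complexes(labels, seed=4)
        assert train | test == set(range(6))
        assert train & test == set()

    def test_deterministic(self):
        labels = np.repeat(np.arange(9), 2)
        assert split_complexes(labels, seed=1) == split_complexes(labels,
                                                                  seed=1)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            split_complexes([1, 1, 1])


class TestSiameseTraining:
    def test_loss_decreases_and_classes_separate(self, texture_toyset):
        est = SiameseEmbedder(epochs=10, batch_size=2,
                              random_state=0).fit(texture_toyset)
        hist = est.history_["train_loss"]
        assert hist[-1] < hist[0]
        emb = est.transform(texture_toyset.images)
        assert emb.shape == (len(texture_toyset), 256)
        y = texture_toyset.labels
        same = np.equal.outer(y, y) & ~np.eye(len(y), dtype=bool)
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(emb))
        assert D[same].mean() < D[~np.equal.outer(y, y)].mean()

    def test_frozen_backbone_unchanged(self, texture_toyset):
        triples = generate_triples(texture_toyset.labels, 2, seed=0)
        cfg = SiameseConfig(epochs=2)
        enc, _ = train_siamese(texture_toyset, triples, cfg)
        before = [k.copy() for k in enc.backbone.kernels_]
        enc2, _ = train_siamese(texture_toyset, triples, cfg)
        for k1, k2 in zip(before, enc2.backbone.kernels_):
            assert np.array_equal(k1, k2)

    def test_inference_deterministic_and_duplicates_equal(self,
                                                          texture_toyset):
        est = SiameseEmbedder(epochs=2, random_state=0).fit(texture_toyset)
        imgs = texture_toyset.images[:4]
        imgs = np.concatenate([imgs, imgs[:1]])
        e1 = est.transform(imgs)
        e2 = est.transform(imgs)
        assert np.array_equal(e1, e2)
        assert np.array_equal(e1[0], e1[4])

    def test_image_size_mismatch_errors(self, texture_toyset):
        est = SiameseEmbedder(epochs=1, random_state=0).fit(texture_toyset)
        with pytest.raises(ValueError, match="differs from training"):
            siamese_embed(est.encoder_, np.zeros((2, 16, 16)))

    def test_empty_triples_error(self, texture_toyset):
        from cryoclust.imgembed import TripletSpec

        with pytest.raises(ValueError, match="empty"):
            train_siamese(texture_toyset, TripletSpec(triples=[]))

    def test_encoder_roundtrip(self, texture_toyset, tmp_path):
        est = SiameseEmbedder(epochs=1, random_state=0).fit(texture_toyset)
        p = tmp_path / "enc.pkl"
        save_encoder(p, est.encoder_)
        enc = load_encoder(p)
        assert np.allclose(
            enc(texture_toyset.images[:3]),
            est.transform(texture_toyset.images[:3]),
        )
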
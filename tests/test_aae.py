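"""Adversarial-autoencoder contracts: architecture, losses, training."""

import numpy as np
import pytest

from feedback_rsa import aae, synthetic
from feedback_rsa.aae import (
    AAEConfig,
    LAYER_IDS,
    adversarial_step,
    build_model,
    draw_fake_codes,
    extract_activations,
    images_to_nchw,
    make_plain_autoencoder,
    make_untrained_model,
    preprocess_images,
    reconstruction_loss,
    save_model,
    load_model,
    train,
)

TINY = dict(image_size=32, channels_per_block=(4, 6, 8, 8, 8), latent_dim=8,
            batch_size=16)


class TestConfigAndArchitecture:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            AAEConfig(image_size=48)
        with pytest.raises(ValueError):
            AAEConfig(latent_dim=2, n_categories=4)
        with pytest.raises(ValueError):
            AAEConfig(channels_per_block=(8, 8, 8))
        with pytest.raises(ValueError):
            AAEConfig(decoder_channels=(8, 8))

    def test_reconstruction_shape_matches_input(self):
        model = build_model(AAEConfig(image_size=64,
                                      channels_per_block=(4, 4, 8, 8, 8),
                                      latent_dim=8, seed=0))
        x = np.zeros((2, 3, 64, 64))
        recon, acts = model.forward_generator(x, train=False)
        assert recon.shape == (2, 3, 64, 64)
        assert set(acts) == set(LAYER_IDS)

    def test_discriminator_input_width_is_latent_plus_categories(self):
        model = build_model(AAEConfig(**TINY, seed=0))
        first_dense = model.discriminator.layers[0]
        assert first_dense.W.value.shape[0] == 8 + 4
        wide = build_model(AAEConfig(image_size=32,
                                     channels_per_block=(4, 6, 8, 8, 8),
                                     latent_dim=128, seed=0))
        assert wide.discriminator.layers[0].W.value.shape[0] == 132

    def test_generator_has_thirteen_parameterized_layers(self):
        model = build_model(AAEConfig(**TINY, seed=0))
        assert model.n_parameterized_layers == 13


class TestPreprocess:
    def test_linear_map_endpoints_and_midpoint(self):
        raw = np.stack([np.full((32, 32, 3), v) for v in (0.0, 255.0, 127.5)])
        out = preprocess_images(raw, size=32)
        assert np.allclose(out.images[0], -1.0)
        assert np.allclose(out.images[1], 1.0)
        assert np.allclose(out.images[2], 0.0, atol=1e-12)

    def test_resize_preserves_mean_against_block_average(self):
        yy, xx = np.mgrid[0:224, 0:224]
        checker = (((xx // 16) + (yy // 16)) % 2 * 255.0)
        raw = np.repeat(checker[..., None], 3, axis=2)[None]
        out = preprocess_images(raw, size=64)
        # brute-force oracle: averaging 3.5x3.5 blocks preserves the mean
        oracle_mean = checker.mean() / 127.5 - 1.0
        assert out.images.mean() == pytest.approx(oracle_mean, abs=0.01)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            preprocess_images(np.zeros((0, 8, 8, 3)), size=32)


class TestReconstructionLoss:
    def test_identity_and_closed_forms(self):
        x = np.random.default_rng(0).uniform(-1, 1, (2, 3, 8, 8))
        assert reconstruction_loss(x, x, "mse") == 0.0
        assert reconstruction_loss(x, x, "mae") == 0.0
        ones = np.ones((2, 3, 4, 4))
        assert reconstruction_loss(ones, -ones, "mse") == pytest.approx(4.0)
        assert reconstruction_loss(ones, -ones, "mae") == pytest.approx(2.0)

    def test_matches_brute_force_pixel_loop(self):
        rng = np.random.default_rng(1)
        x, fx = rng.standard_normal((2, 1, 4, 4)), rng.standard_normal((2, 1, 4, 4))
        mse = sum((a - b) ** 2 for a, b in zip(x.ravel(), fx.ravel())) / x.size
        mae = sum(abs(a - b) for a, b in zip(x.ravel(), fx.ravel())) / x.size
        assert reconstruction_loss(x, fx, "mse") == pytest.approx(mse)
        assert reconstruction_loss(x, fx, "mae") == pytest.approx(mae)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.zeros((1, 3, 8, 8)), np.zeros((1, 3, 4, 4)))


class TestActivations:
    def test_duplicated_images_give_identical_rows(self):
        model = build_model(AAEConfig(**TINY, seed=0))
        imgs = synthetic.generate_image_dataset(1, 32, seed=0)
        dup = synthetic.ImageSet(
            images=np.concatenate([imgs.images[:1], imgs.images[:1]]),
            labels=np.array([0, 0]))
        acts = extract_activations(model, dup)
        for lid in LAYER_IDS:
            assert np.array_equal(acts[lid][0], acts[lid][1])

    def test_latent_matrix_shape_and_determinism(self):
        model = build_model(AAEConfig(**TINY, seed=0))
        imgs = synthetic.generate_image_dataset(2, 32, seed=0)
        a = extract_activations(model, imgs, layers=["LV"])
        b = extract_activations(model, imgs, layers=["LV"])
        assert a["LV"].shape == (8, 8)
        assert np.array_equal(a["LV"], b["LV"])

    def test_unknown_layer_rejected(self):
        model = build_model(AAEConfig(**TINY, seed=0))
        imgs = synthetic.generate_image_dataset(1, 32, seed=0)
        with pytest.raises(ValueError, match="unknown layer"):
            extract_activations(model, imgs, layers=["E7"])

    def test_feature_count_follows_architecture_arithmetic(self):
        model = build_model(AAEConfig(**TINY, seed=0))
        imgs = synthetic.generate_image_dataset(1, 32, seed=0)
        acts = extract_activations(model, imgs)
        # E1: 4 channels at 16x16 after one pool
        assert acts["E1"].shape[1] == 4 * 16 * 16


class TestAblations:
    def test_untrained_model_is_seed_deterministic(self):
        cfg = AAEConfig(**TINY, seed=3)
        imgs = synthetic.generate_image_dataset(1, 32, seed=0)
        a = extract_activations(make_untrained_model(cfg), imgs, ["LV"])
        b = extract_activations(make_untrained_model(cfg), imgs, ["LV"])
        c = extract_activations(make_untrained_model(cfg, seed=4), imgs, ["LV"])
        assert np.array_equal(a["LV"], b["LV"])
        assert not np.array_equal(a["LV"], c["LV"])

    def test_plain_autoencoder_has_no_discriminator(self):
        cfg = AAEConfig(**TINY, seed=0, epochs=2)
        plain = make_plain_autoencoder(cfg)
        assert plain.discriminator is None
        data = synthetic.generate_image_dataset(4, 32, seed=0)
        trace = train(plain, data, cfg)
        assert len(trace.reconstruction_loss) == 2
        assert trace.discriminator_loss == [] and trace.generator_loss == []
        with pytest.raises(RuntimeError):
            adversarial_step(plain, images_to_nchw(data.images), data.labels,
                             np.random.default_rng(0))


class TestTraining:
    def test_zero_epochs_is_a_no_op(self):
        cfg = AAEConfig(**TINY, seed=0, epochs=0)
        model = build_model(cfg)
        imgs = synthetic.generate_image_dataset(1, 32, seed=0)
        before = extract_activations(model, imgs, ["D6"])["D6"].copy()
        trace = train(model, synthetic.generate_image_dataset(4, 32, seed=1),
                      cfg)
        assert len(trace) == 0
        after = extract_activations(model, imgs, ["D6"])["D6"]
        assert np.array_equal(before, after)

    def test_reconstruction_loss_descends(self):
        cfg = AAEConfig(**TINY, seed=0, epochs=25)
        model = build_model(cfg)
        data = synthetic.generate_image_dataset(8, 32, seed=1)
        trace = train(model, data, cfg)
        assert trace.reconstruction_loss[-1] < trace.reconstruction_loss[0]
        assert all(np.isfinite(trace.reconstruction_loss))

    def test_empty_dataset_rejected(self):
        cfg = AAEConfig(**TINY, seed=0, epochs=1)
        empty = synthetic.ImageSet(images=np.zeros((0, 32, 32, 3)),
                                   labels=np.zeros(0, dtype=int))
        with pytest.raises(ValueError):
            train(build_model(cfg), empty, cfg)


class TestAdversarial:
    def test_fake_one_hot_codes_are_uniform(self):
        codes = draw_fake_codes(10000, 4, np.random.default_rng(0))
        freqs = codes.mean(axis=0)
        assert codes.shape == (10000, 4)
        assert np.all(np.abs(freqs - 0.25) < 0.02)

    def test_untrained_discriminator_is_uninformative(self):
        cfg = AAEConfig(**TINY, seed=0)
        model = build_model(cfg)
        data = synthetic.generate_image_dataset(16, 32, seed=2)
        rng = np.random.default_rng(0)
        lv = model.encode(images_to_nchw(data.images), train=False)
        onehot = np.zeros((len(data), 4))
        onehot[np.arange(len(data)), data.labels] = 1
        real_logits = model.discriminate(lv, onehot, train=False)
        z = rng.standard_normal((len(data), cfg.latent_dim))
        fake_logits = model.discriminate(z, draw_fake_codes(len(data), 4, rng),
                                         train=False)
        acc = 0.5 * (np.mean(real_logits > 0) + np.mean(fake_logits <= 0))
        assert 0.35 <= acc <= 0.65

    def test_adversarial_step_returns_finite_losses_and_updates(self):
        cfg = AAEConfig(**TINY, seed=0)
        model = build_model(cfg)
        data = synthetic.generate_image_dataset(4, 32, seed=0)
        lv_before = model.encode(images_to_nchw(data.images), train=False)
        d_loss, g_loss = adversarial_step(model, images_to_nchw(data.images),
                                          data.labels,
                                          np.random.default_rng(0))
        assert np.isfinite(d_loss) and np.isfinite(g_loss)
        lv_after = model.encode(images_to_nchw(data.images), train=False)
        assert not np.array_equal(lv_before, lv_after)


class TestCheckpoint:
    def test_save_load_roundtrip_preserves_activations(self, tmp_path):
        cfg = AAEConfig(**TINY, seed=0, epochs=2)
        model = build_model(cfg)
        data = synthetic.generate_image_dataset(4, 32, seed=1)
        train(model, data, cfg)
        path = tmp_path / "model.h5"
        save_model(model, path)
        back = load_model(path)
        a = extract_activations(model, data)
        b = extract_activations(back, data)
        for lid in LAYER_IDS:
            assert np.allclose(a[lid], b[lid])
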
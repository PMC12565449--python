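"""Auto-encoder embedding and transformer sequence encoder."""

import numpy as np
import pytest

from nodulefusion import _nn
from nodulefusion.dataio import StageConfig
from nodulefusion.preprocess import LungSliceStack
from nodulefusion.temporal_path import (MAX_SLICES, CAEConfig, CAEModel,
                                        EmbeddingSequence, TemporalEncoder,
                                        cae_finetune, cae_pretrain,
                                        embed_sequence, temporal_forward,
                                        temporal_train)


def _stack(images, case_id="t"):
    return LungSliceStack(case_id=case_id, images=images,
                          lung_masks=np.ones_like(images, dtype=np.uint8))


def _images(rng, n=6, size=256):
    return rng.random((n, size, size))


@pytest.fixture(scope="module")
def tiny_cae():
    rng = np.random.default_rng(3)
    return CAEModel(CAEConfig.reduced(), rng)


class TestArchitecture:
    def test_full_scale_dimensions(self, rng):
        cfg = CAEConfig()
        assert cfg.filters == (16, 32, 64, 128, 256)
        assert cfg.bottleneck_hw == 8          # five 2x2 poolings of 256
        model = CAEModel(cfg, rng)
        x = rng.random((1, 1, 256, 256))
        emb = model.encode(_nn.Tensor(x))
        assert emb.shape == (1, 256)
        rec = model.reconstruct(_nn.Tensor(x))
        assert rec.shape == x.shape

    def test_reduced_reconstruction_shape(self, tiny_cae, rng):
        x = tiny_cae.prepare(_images(rng, 2))
        rec = tiny_cae.reconstruct(_nn.Tensor(x))
        assert rec.shape == x.shape

    def test_input_size_must_survive_poolings(self):
        with pytest.raises(ValueError, match="pooling"):
            CAEConfig(input_size=100)


class TestPretraining:
    @staticmethod
    def _smooth_images(rng, n, size=64):
        """Structured (smooth) images: reconstructable beyond the mean."""
        from scipy.ndimage import gaussian_filter
        imgs = gaussian_filter(rng.random((n, size, size)), (0, 6, 6))
        lo, hi = imgs.min(), imgs.max()
        return (imgs - lo) / (hi - lo)

    def test_loss_decreases_and_beats_constant_baseline(self, rng):
        images = self._smooth_images(rng, 24)
        # the best constant predictor of a set of images is their mean image
        holdout = self._smooth_images(np.random.default_rng(9), 8)
        cfg = StageConfig(optimizer="adam", learning_rate=1e-3, epochs=12,
                          batch_size=8)
        small = CAEConfig(input_size=64, filters=(8, 16, 32, 32, 64),
                          embedding=64)
        model, hist = cae_pretrain(images, cfg, seed=0, config=small)
        assert hist["best_val"] < hist["val"][0]
        xh = model.prepare(holdout)
        rec = model.reconstruct(_nn.Tensor(xh)).data
        model_mse = float(((rec - xh) ** 2).mean())
        const = model.prepare(images).mean(axis=0, keepdims=True)
        const_mse = float(((xh - const) ** 2).mean())
        assert model_mse < const_mse

    def test_identical_seeds_identical_weights(self, rng):
        images = _images(rng, 8, 64)
        cfg = StageConfig(optimizer="adam", learning_rate=1e-3, epochs=2,
                          batch_size=4)
        m1, _ = cae_pretrain(images, cfg, seed=5, config=CAEConfig.reduced())
        m2, _ = cae_pretrain(images, cfg, seed=5, config=CAEConfig.reduced())
        for a, b in zip(m1.state(), m2.state()):
            assert np.array_equal(a, b)


class TestFinetuneFreezePolicy:
    def test_only_bottleneck_block_updates(self, rng):
        images = _images(rng, 8, 64)
        cfg = StageConfig(optimizer="adam", learning_rate=1e-3, epochs=2,
                          batch_size=4)
        model, _ = cae_pretrain(images, cfg, seed=2,
                                config=CAEConfig.reduced())
        frozen_before = [p.data.copy() for p in model.enc_convs[0].parameters()]
        dense_before = model.enc_dense.weight.data.copy()
        last_enc_before = model.enc_convs[-1].weight.data.copy()
        cae_finetune(model, images, cfg, seed=2)
        for a, b in zip(frozen_before, model.enc_convs[0].parameters()):
            assert np.array_equal(a, b.data)   # first conv bitwise unchanged
        assert not np.array_equal(dense_before, model.enc_dense.weight.data)
        assert not np.array_equal(last_enc_before,
                                  model.enc_convs[-1].weight.data)

    def test_tiny_learning_rate_changes_nothing_material(self, rng):
        images = _images(rng, 4, 64)
        cfg = StageConfig(optimizer="adam", learning_rate=1e-3, epochs=1,
                          batch_size=4)
        model, _ = cae_pretrain(images, cfg, seed=4,
                                config=CAEConfig.reduced())
        before = model.state()
        zero_cfg = StageConfig(optimizer="adam", learning_rate=1e-30,
                               epochs=1, batch_size=4)
        cae_finetune(model, images, zero_cfg, seed=4)
        for a, b in zip(before, model.state()):
            np.testing.assert_allclose(a, b, atol=1e-6)


class TestEmbedSequence:
    def test_padding_structure(self, tiny_cae, rng):
        seq = embed_sequence(tiny_cae, _stack(_images(rng, 4)))
        assert seq.true_length == 4
        assert np.all(seq.embeddings[4:] == 0)
        assert seq.validity.tolist() == [1] * 4 + [0] * 21

    def test_full_length_no_padding(self, tiny_cae, rng):
        seq = embed_sequence(tiny_cae, _stack(_images(rng, 25)))
        assert seq.true_length == 25
        assert seq.validity.sum() == MAX_SLICES

    def test_too_many_slices_instructs_subsampling(self, tiny_cae, rng):
        images = _images(rng, 30)
        with pytest.raises(ValueError, match="subsample"):
            embed_sequence(tiny_cae, _stack(images))
        seq = embed_sequence(tiny_cae, _stack(images), subsample=True)
        assert seq.true_length == 25

    def test_permuting_slices_permutes_rows(self, tiny_cae, rng):
        images = _images(rng, 5)
        seq = embed_sequence(tiny_cae, _stack(images))
        perm = [3, 1, 4, 0, 2]
        seq_p = embed_sequence(tiny_cae, _stack(images[perm]))
        np.testing.assert_array_equal(seq_p.embeddings[:5],
                                      seq.embeddings[perm])

    def test_nonzero_padding_rejected(self, rng):
        emb = np.zeros((25, 8))
        emb[10] = 1.0   # beyond the claimed length
        with pytest.raises(ValueError, match="padded rows"):
            EmbeddingSequence(embeddings=emb,
                              validity=np.r_[np.ones(5), np.zeros(20)])


class TestTemporalEncoder:
    @pytest.fixture(scope="class")
    @staticmethod
    def encoder():
        return TemporalEncoder(16, np.random.default_rng(0), dropout=0.3)

    def _seq(self, rng, n, dim=16):
        emb = np.zeros((MAX_SLICES, dim))
        emb[:n] = rng.normal(size=(n, dim))
        val = np.zeros(MAX_SLICES)
        val[:n] = 1
        return EmbeddingSequence(embeddings=emb, validity=val)

    @pytest.mark.parametrize("n", [1, 7, 25])
    def test_output_is_32d_for_any_length(self, encoder, rng, n):
        feat = temporal_forward(encoder, self._seq(rng, n))
        assert feat.shape == (32,)
        assert np.all(np.isfinite(feat))

    def test_padding_garbage_invariance(self, encoder, rng):
        seq = self._seq(rng, 6)
        base = encoder._forward_batch(seq.embeddings[None],
                                      seq.validity[None]).data
        for _ in range(5):
            garbage = seq.embeddings.copy()
            garbage[6:] = rng.normal(0, 10, garbage[6:].shape)
            out = encoder._forward_batch(garbage[None],
                                         seq.validity[None]).data
            assert np.array_equal(out, base)

    def test_extra_zero_padding_is_inert(self, encoder, rng):
        seq = self._seq(rng, 6)
        out1 = temporal_forward(encoder, seq)
        # re-assert rows >= 6 are zero, i.e. "padding the padding"
        seq2 = EmbeddingSequence(embeddings=seq.embeddings.copy(),
                                 validity=seq.validity.copy())
        out2 = temporal_forward(encoder, seq2)
        assert np.array_equal(out1, out2)

    def test_single_slice_pool_equals_encoded_row(self, encoder, rng):
        seq = self._seq(rng, 1)
        _, pooled = encoder._forward_batch(seq.embeddings[None],
                                           seq.validity[None],
                                           return_pooled=True)
        # replicate the encoder stack directly on the same batch
        x = _nn.Tensor(encoder._standardize(seq.embeddings[None],
                                            seq.validity[None]))
        x = _nn.add(x, _nn.Tensor(encoder.pe[None]
                                  * seq.validity[None][:, :, None]))
        mask = np.where(seq.validity[None][:, None, None, :] > 0, 0.0, -1e9)
        for block in encoder.blocks:
            x = block(x, mask=mask)
        np.testing.assert_allclose(pooled.data[0], x.data[0, 0], atol=1e-6)

    def test_all_invalid_sequence_rejected(self):
        with pytest.raises(ValueError, match="no valid slices"):
            EmbeddingSequence(embeddings=np.zeros((25, 16)),
                              validity=np.zeros(25))


class TestTemporalTraining:
    def test_learns_separable_sequences(self, rng):
        # class 1 sequences carry a mean offset on the valid rows
        seqs, y = [], []
        for i in range(24):
            label = i % 2
            n = int(rng.integers(3, 10))
            emb = np.zeros((MAX_SLICES, 16))
            emb[:n] = rng.normal(size=(n, 16)) + 1.5 * label
            val = np.r_[np.ones(n), np.zeros(MAX_SLICES - n)]
            seqs.append(EmbeddingSequence(embeddings=emb, validity=val))
            y.append(label)
        cfg = StageConfig(optimizer="adam", learning_rate=1e-3, epochs=80,
                          batch_size=8, dropout=0.3)
        enc, hist = temporal_train(seqs, np.array(y), cfg, seed=42)
        acc = (enc.logits(seqs).data.argmax(1) == np.array(y)).mean()
        assert acc >= 0.9
        assert hist["loss"][-1] < hist["loss"][0]

    def test_single_class_rejected(self, rng):
        seqs = [EmbeddingSequence(
            embeddings=np.r_[rng.normal(size=(3, 16)), np.zeros((22, 16))],
            validity=np.r_[np.ones(3), np.zeros(22)]) for _ in range(4)]
        with pytest.raises(ValueError, match="both classes"):
            temporal_train(seqs, np.zeros(4, dtype=int),
                           StageConfig(epochs=1, batch_size=2), seed=0)
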
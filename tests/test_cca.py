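"""Criss-cross attention fusion: affinity, aggregation, classification."""

import numpy as np
import pytest

from nodulefusion import _nn
from nodulefusion.cca_fusion import (MAP_H, MAP_W, PROJ_DIM, FusionModel,
                                     cca_affinity, cca_aggregate,
                                     fuse_and_classify, fusion_train,
                                     project_triple, ProjectedTriple)
from nodulefusion.dataio import StageConfig

from _oracles import naive_cca


def _model(rng, bias=False, dims=None):
    dims = dims or {"radiomic": 36, "spatial": 256, "temporal": 32}
    return FusionModel(dims, rng, bias=bias)


class TestProjection:
    def test_maps_are_10x10(self, rng):
        model = _model(rng)
        triple = project_triple(model, rng.normal(size=36),
                                rng.normal(size=256), rng.normal(size=32))
        for m in (triple.q_map, triple.k_map, triple.v_map):
            assert m.shape == (10, 10, 1)

    def test_row_major_reshape_places_element_23_at_2_3(self, rng):
        model = _model(rng, dims={"radiomic": 100, "spatial": 100,
                                  "temporal": 100})
        # identity projection: element k of the 100-d input lands at
        # (k // 10, k % 10) in the map
        for path in ("radiomic", "spatial", "temporal"):
            model.proj[path].weight.data[...] = np.eye(100)
        x = np.zeros(100)
        x[23] = 5.0
        triple = project_triple(model, x, np.zeros(100), np.zeros(100))
        assert triple.q_map[2, 3, 0] == pytest.approx(5.0)
        assert np.count_nonzero(triple.q_map) == 1

    def test_zero_input_zero_map_without_bias(self, rng):
        model = _model(rng, bias=False)
        triple = project_triple(model, np.zeros(36), np.zeros(256),
                                np.zeros(32))
        assert np.all(triple.q_map == 0)

    def test_zero_input_constant_map_with_bias(self, rng):
        model = _model(rng, bias=True)
        t1 = project_triple(model, np.zeros(36), np.zeros(256), np.zeros(32))
        t2 = project_triple(model, np.zeros(36), np.zeros(256), np.zeros(32))
        assert np.array_equal(t1.q_map, t2.q_map)   # pure function of bias


class TestAffinity:
    def test_constant_k_gives_uniform_weights(self, rng):
        q = rng.normal(size=(10, 10, 1))
        k = np.full((10, 10, 1), 0.7)
        attn = cca_affinity(q, k)
        assert attn.weights.shape == (10, 10, 19)
        np.testing.assert_allclose(attn.weights, 1.0 / 19, atol=1e-12)

    def test_softmax_shift_invariance(self, rng):
        q = rng.normal(size=(6, 6, 2))
        k = rng.normal(size=(6, 6, 2))
        a1 = cca_affinity(q, k)
        # adding a constant vector offset to Q shifts every affinity of a
        # position by a constant only when K is constant; instead test the
        # definition directly: softmax(d + c) == softmax(d)
        shifted = a1.affinities + 3.14
        e = np.exp(shifted - shifted.max(axis=-1, keepdims=True))
        w = e / e.sum(axis=-1, keepdims=True)
        np.testing.assert_allclose(w, a1.weights, atol=1e-12)

    def test_weights_sum_to_one(self, rng):
        for _ in range(5):
            attn = cca_affinity(rng.normal(size=(8, 5, 3)),
                                rng.normal(size=(8, 5, 3)))
            np.testing.assert_allclose(attn.weights.sum(-1), 1.0, atol=1e-9)
            assert attn.weights.shape[-1] == 8 + 5 - 1

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        q = rng.normal(size=(10, 10, 1))
        k = rng.normal(size=(10, 10, 1))
        v = rng.normal(size=(10, 10, 1))
        attn = cca_affinity(q, k)
        fused = cca_aggregate(attn, v)
        w_o, f_o = naive_cca(q, k, v)
        np.testing.assert_allclose(attn.weights, w_o, atol=1e-9)
        np.testing.assert_allclose(fused.map, f_o, atol=1e-9)


class TestAggregation:
    def test_uniform_attention_is_cross_mean(self, rng):
        h, w = 7, 5
        q = np.zeros((h, w, 1))          # zero Q -> uniform weights
        k = rng.normal(size=(h, w, 1))
        v = rng.normal(size=(h, w, 1))
        fused = cca_aggregate(cca_affinity(q, k), v)
        for r in range(h):
            for c in range(w):
                cross = [v[r, j, 0] for j in range(w)] + \
                        [v[i, c, 0] for i in range(h) if i != r]
                assert fused.map[r, c, 0] == pytest.approx(np.mean(cross),
                                                           rel=1e-9)

    def test_constant_v_passes_through(self, rng):
        q = rng.normal(size=(10, 10, 1))
        k = rng.normal(size=(10, 10, 1))
        v = np.full((10, 10, 1), -2.5)
        fused = cca_aggregate(cca_affinity(q, k), v)
        np.testing.assert_allclose(fused.map, -2.5, atol=1e-9)

    def test_convex_hull_bound(self, rng):
        for _ in range(5):
            q = rng.normal(size=(9, 9, 4))
            k = rng.normal(size=(9, 9, 4))
            v = rng.normal(size=(9, 9, 4))
            fused = cca_aggregate(cca_affinity(q, k), v)
            for r in range(9):
                for c in range(9):
                    cross = np.array([v[r, j] for j in range(9)]
                                     + [v[i, c] for i in range(9) if i != r])
                    assert np.all(fused.map[r, c] >= cross.min(0) - 1e-9)
                    assert np.all(fused.map[r, c] <= cross.max(0) + 1e-9)

    def test_residual_flag_adds_v(self, rng):
        q, k, v = (rng.normal(size=(10, 10, 1)) for _ in range(3))
        attn = cca_affinity(q, k)
        base = cca_aggregate(attn, v, residual=False)
        res = cca_aggregate(attn, v, residual=True)
        np.testing.assert_allclose(res.map, base.map + v, atol=1e-12)


class TestClassify:
    def test_probabilities_sum_to_one(self, rng):
        model = _model(rng)
        for _ in range(5):
            triple = project_triple(model, rng.normal(size=36),
                                    rng.normal(size=256),
                                    rng.normal(size=32))
            p = fuse_and_classify(model, triple)
            assert p.shape == (2,)
            assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_pure_function(self, rng):
        model = _model(rng)
        feats = {"radiomic": rng.normal(size=(1, 36)),
                 "spatial": rng.normal(size=(1, 256)),
                 "temporal": rng.normal(size=(1, 32))}
        p1 = model.predict_proba(feats)
        p2 = model.predict_proba(feats)
        assert np.array_equal(p1, p2)

    def test_swapping_head_rows_swaps_probabilities(self, rng):
        model = _model(rng)
        feats = {"radiomic": rng.normal(size=(3, 36)),
                 "spatial": rng.normal(size=(3, 256)),
                 "temporal": rng.normal(size=(3, 32))}
        p1 = model.predict_proba(feats)
        model.head.weight.data[...] = model.head.weight.data[:, ::-1]
        model.head.bias.data[...] = model.head.bias.data[::-1]
        p2 = model.predict_proba(feats)
        np.testing.assert_allclose(p2, p1[:, ::-1], atol=1e-6)

    def test_training_path_matches_single_case_path(self, rng):
        """FusionModel.predict_proba (batched autodiff path) and
        fuse_and_classify (numpy criss-cross ops) agree."""
        model = _model(rng)
        model.fit_normalizer({"radiomic": rng.normal(size=(8, 36)),
                              "spatial": rng.normal(size=(8, 256)),
                              "temporal": rng.normal(size=(8, 32))})
        r, s, t = (rng.normal(size=36), rng.normal(size=256),
                   rng.normal(size=32))
        batched = model.predict_proba({"radiomic": r[None], "spatial": s[None],
                                       "temporal": t[None]})[0]
        single = fuse_and_classify(model, project_triple(model, r, s, t))
        np.testing.assert_allclose(batched, single, atol=1e-5)


class TestFusionTraining:
    def _separable_features(self, rng, n=40):
        y = np.repeat([0, 1], n // 2)
        mk = lambda d, shift: (rng.normal(size=(n, d))
                               + shift * y[:, None])
        return {"radiomic": mk(36, 2.0), "spatial": mk(256, 0.5),
                "temporal": mk(32, 1.5)}, y

    def test_learns_separable_features(self, rng):
        feats, y = self._separable_features(rng)
        cfg = StageConfig(optimizer="adamw", learning_rate=1e-3, epochs=20,
                          batch_size=8, weight_decay=0.05, patience=5)
        model, _ = fusion_train(feats, y, cfg, seed=42)
        pred = model.predict_proba(feats)[:, 1] >= 0.5
        assert (pred == y).mean() >= 0.9

    def test_patience_zero_stops_after_first_non_improvement(self, rng):
        # label-free noise: the validation loss cannot keep improving, so a
        # patience of 0 must halt right after the first non-improving epoch
        feats = {"radiomic": rng.normal(size=(20, 36)),
                 "spatial": rng.normal(size=(20, 256)),
                 "temporal": rng.normal(size=(20, 32))}
        y = np.tile([0, 1], 10)
        cfg = StageConfig(optimizer="adamw", learning_rate=1e-3, epochs=50,
                          batch_size=8, weight_decay=0.05, patience=0)
        _, hist = fusion_train(feats, y, cfg, seed=1)
        vals = hist["val"]
        assert len(vals) == int(np.argmin(vals)) + 2

    def test_single_class_fold_rejected(self, rng):
        feats, _ = self._separable_features(rng, n=10)
        cfg = StageConfig(epochs=1, batch_size=4)
        with pytest.raises(ValueError, match="both classes"):
            fusion_train(feats, np.zeros(10, dtype=int), cfg, seed=0)
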
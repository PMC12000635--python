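"""Quantization, feature assembly, lazy training and 1-NN prediction."""

import numpy as np
import pytest

from t1knn.knn import (
    FeatureBlock,
    T1ClassGrid,
    T1NearestNeighborModel,
    T1NearestNeighborResults,
    TrainingStore,
    assemble_features,
    dequantize,
    linear_scan_predict,
    predict_t1,
    quantize_t1,
    train,
)
from t1knn.phantom import TISSUES, render_contrast
from t1knn.preprocess import build_training_mask

GRID = T1ClassGrid()


class TestQuantize:
    @pytest.mark.parametrize(
        "t1,value",
        [(400.0, 400.0), (1234.0, 1230.0), (5000.0, 3980.0), (100.0, 400.0), (405.0, 410.0)],
    )
    def test_round_and_clamp(self, t1, value):
        assert dequantize(quantize_t1(t1, GRID), GRID) == value

    def test_grid_class_count(self):
        assert GRID.n_classes == 359
        assert GRID.values()[0] == 400.0 and GRID.values()[-1] == 3980.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            quantize_t1(np.nan, GRID)

    def test_misaligned_grid_rejected(self):
        with pytest.raises(ValueError):
            T1ClassGrid(400, 3985, 10)


def _block(vectors, shape=(4, 4, 4)):
    vectors = np.atleast_2d(vectors)
    return FeatureBlock(vectors, np.arange(vectors.shape[0]), shape)


def _row(mprage, flair=0.0, probs=(0, 0, 0, 0, 0, 0, 0)):
    return [mprage, flair, *probs]


class TestAssembleFeatures:
    def test_pure_wm_row_construction(self, phantom48):
        mpr = render_contrast(phantom48, "mprage")
        fla = render_contrast(phantom48, "flair")
        wm_sel = (phantom48.prob_maps["wm"] > 0.999) & ~phantom48.lesion_mask
        mpr_n = mpr / mpr[wm_sel].mean()
        fla_n = fla / fla[wm_sel].mean()
        feats = assemble_features(mpr_n, fla_n, phantom48.prob_maps, wm_sel)
        np.testing.assert_allclose(feats.vectors[:, 0], 1.0, rtol=1e-12)
        np.testing.assert_allclose(feats.vectors[:, 1], 1.0, rtol=1e-12)
        np.testing.assert_allclose(feats.vectors[:, 2], 1.0, rtol=1e-9)  # p_WM
        np.testing.assert_allclose(feats.vectors[:, 3:], 0.0, atol=1e-9)

    def test_empty_voxel_set_rejected(self, phantom48):
        mpr = render_contrast(phantom48, "mprage")
        with pytest.raises(ValueError, match="no voxels"):
            assemble_features(mpr, mpr, phantom48.prob_maps, np.zeros(phantom48.shape, bool))

    def test_nonfinite_rows_dropped_and_counted(self, phantom48):
        mpr = render_contrast(phantom48, "mprage")
        fla = render_contrast(phantom48, "flair")
        mask = phantom48.brain_mask.copy()
        idx = np.argwhere(mask)[:5]
        bad = mpr.copy()
        for i, j, k in idx:
            bad[i, j, k] = np.nan
        feats = assemble_features(bad, fla, phantom48.prob_maps, mask)
        assert feats.n_dropped == 5
        assert feats.vectors.shape[0] == int(mask.sum()) - 5

    def test_grid_mismatch_rejected(self, phantom48):
        mpr = render_contrast(phantom48, "mprage")
        with pytest.raises(ValueError, match="grid mismatch"):
            assemble_features(mpr, mpr[:-1], phantom48.prob_maps, phantom48.brain_mask)


class TestTrainingStore:
    def test_store_roundtrip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(3)
        vec = rng.random((20, 9))
        ref = np.zeros((4, 4, 4))
        ref.ravel()[:20] = rng.uniform(400, 3980, 20)
        store = train(_block(vec), ref, GRID, provenance={"subject": "synthA"})
        path = tmp_path / "model.npz"
        store.save(path)
        loaded = TrainingStore.load(path)
        np.testing.assert_array_equal(loaded.features, store.features)
        np.testing.assert_array_equal(loaded.labels, store.labels)
        assert loaded.grid == store.grid
        assert loaded.provenance == store.provenance
        query = _block(rng.random((50, 9)), (4, 4, 4))
        # identical predictions after reload
        np.testing.assert_array_equal(
            predict_t1(store, query).t1, predict_t1(loaded, query).t1
        )

    def test_version_mismatch_rejected(self, tmp_path):
        path = tmp_path / "bad.npz"
        np.savez(path, format_version=np.array("t1knn-store-0"), features=np.ones((1, 9)))
        with pytest.raises(ValueError, match="format-version"):
            TrainingStore.load(path)

    def test_single_voxel_store(self):
        store = train(_block(np.ones((1, 9)) * 0.5), np.full((4, 4, 4), 900.0), GRID)
        assert store.size == 1

    def test_conflicting_duplicates_retained(self):
        vec = np.vstack([np.full(9, 0.5), np.full(9, 0.5)])
        ref = np.zeros((4, 4, 4))
        ref.ravel()[:2] = [800.0, 1200.0]
        store = train(_block(vec), ref, GRID)
        assert store.size == 2  # lazy learner keeps both; query tie-break resolves

    def test_invalid_reference_dropped(self):
        vec = np.random.default_rng(0).random((4, 9))
        ref = np.zeros((4, 4, 4))
        ref.ravel()[:4] = [900.0, np.nan, -5.0, 1100.0]
        store = train(_block(vec), ref, GRID)
        assert store.size == 2
        assert store.provenance["n_dropped_invalid_reference"] == 2


class TestPredict:
    def _two_point_store(self):
        vec = np.zeros((2, 9))
        vec[0, 0] = 1.0
        vec[1, 0] = 2.0
        ref = np.zeros((4, 4, 4))
        ref.ravel()[:2] = [800.0, 1200.0]
        return train(_block(vec), ref, GRID)

    def test_exact_match_returns_training_label(self):
        store = self._two_point_store()
        q = _block(_row(2.0))
        assert predict_t1(store, q).t1.ravel()[0] == 1200.0

    def test_nearest_by_euclidean_distance(self):
        store = self._two_point_store()
        q = _block(_row(1.4))
        assert predict_t1(store, q).t1.ravel()[0] == 800.0  # 0.4 < 0.6

    def test_equidistant_tie_takes_lowest_class(self):
        store = self._two_point_store()
        q = _block(_row(1.5))
        assert predict_t1(store, q).t1.ravel()[0] == 800.0

    def test_k_exceeding_store_rejected(self):
        store = self._two_point_store()
        with pytest.raises(ValueError, match="store size"):
            predict_t1(store, _block(_row(1.0)), k=3)

    def test_majority_vote_k3(self):
        vec = np.zeros((3, 9))
        vec[:, 0] = [1.0, 1.1, 5.0]
        ref = np.zeros((4, 4, 4))
        ref.ravel()[:3] = [800.0, 800.0, 3000.0]
        store = train(_block(vec), ref, GRID)
        assert predict_t1(store, _block(_row(1.05)), k=3).t1.ravel()[0] == 800.0

    def test_oracle_equivalence_random_pairs(self):
        """Accelerated neighbour search equals the exhaustive linear scan on
        10,000 random query/store pairs."""
        rng = np.random.default_rng(29)
        m = 2000
        vec = np.hstack([rng.random((m, 2)) * 2, rng.random((m, 7))])
        ref = np.zeros((50, 50, 1))
        ref.ravel()[:m] = rng.uniform(400, 3980, m)
        store = train(FeatureBlock(vec, np.arange(m), (50, 50, 1)), ref, GRID)
        nq = 10_000
        qv = np.hstack([rng.random((nq, 2)) * 2, rng.random((nq, 7))])
        query = FeatureBlock(qv, np.arange(nq), (100, 100, 1))
        fast = predict_t1(store, query).t1.ravel()[:nq]
        slow = dequantize(linear_scan_predict(store, query), GRID)
        np.testing.assert_array_equal(fast, slow)

    def test_self_consistency_zero_training_error(self):
        """With unique training rows, predicting the training set reproduces
        every label (a 1-NN property)."""
        rng = np.random.default_rng(31)
        m = 500
        vec = np.hstack([rng.random((m, 2)) * 2, rng.random((m, 7))])
        ref = np.zeros((32, 32, 1))
        ref.ravel()[:m] = rng.uniform(400, 3980, m)
        block = FeatureBlock(vec, np.arange(m), (32, 32, 1))
        store = train(block, ref, GRID)
        pred = predict_t1(store, block)
        np.testing.assert_array_equal(
            pred.t1.ravel()[:m], dequantize(store.labels, GRID)
        )


class TestPhantomPrediction:
    def test_noiseless_pure_tissue_recovery_exact(self, phantom48):
        """Training and predicting the noiseless phantom recovers the
        quantized ground-truth T1 at every pure-tissue voxel."""
        mpr = render_contrast(phantom48, "mprage")
        fla = render_contrast(phantom48, "flair")
        p_wm = phantom48.prob_maps["wm"]
        mpr_n = mpr / mpr[p_wm > 0.95].mean()
        fla_n = fla / fla[p_wm > 0.95].mean()
        tmask = build_training_mask(
            phantom48.brain_mask, phantom48.training_mask, phantom48.prob_maps
        )
        feats_train = assemble_features(mpr_n, fla_n, phantom48.prob_maps, tmask)
        res = T1NearestNeighborModel(feats_train, phantom48.t1_volume).fit()
        feats_all = assemble_features(mpr_n, fla_n, phantom48.prob_maps, phantom48.brain_mask)
        pred = res.predict(feats_all)
        for name in TISSUES:
            sel = (phantom48.prob_maps[name] > 0.999) & ~phantom48.lesion_mask
            expected = dequantize(quantize_t1(phantom48.t1_volume[sel], GRID), GRID)
            np.testing.assert_array_equal(pred.t1[sel], expected)

    def test_end_to_end_scale_invariance(self, study48):
        """Multiplying raw MPRAGE/FLAIR by arbitrary positive constants
        leaves the predictions unchanged (WM normalization contract)."""
        from t1knn import preprocess as pp

        ph = study48["phantom"]
        p_wm = ph.prob_maps["wm"]
        tmask = build_training_mask(ph.brain_mask, ph.training_mask, ph.prob_maps)

        def predict_with_scale(c_m, c_f):
            mpr = study48["mprage"] * c_m
            fla = study48["flair"] * c_f
            mpr_n = pp.normalize_by_wm(mpr, pp.wm_reference_mean(mpr, p_wm))
            fla_n = pp.normalize_by_wm(fla, pp.wm_reference_mean(fla, p_wm))
            feats = assemble_features(mpr_n, fla_n, ph.prob_maps, tmask)
            res = T1NearestNeighborModel(feats, ph.t1_volume).fit()
            q = assemble_features(mpr_n, fla_n, ph.prob_maps, ph.brain_mask)
            return res.predict(q).t1

        np.testing.assert_array_equal(predict_with_scale(1.0, 1.0), predict_with_scale(3.7, 0.2))


def test_results_summary_and_persistence(tmp_path, phantom48):
    mpr = render_contrast(phantom48, "mprage")
    sel = phantom48.prob_maps["wm"] > 0.999
    feats = assemble_features(mpr, mpr, phantom48.prob_maps, sel)
    res = T1NearestNeighborModel(feats, phantom48.t1_volume).fit()
    text = res.summary()
    assert "training exemplars" in text and "class grid" in text
    res.save(tmp_path / "m.npz")
    loaded = T1NearestNeighborResults.load(tmp_path / "m.npz")
    assert loaded.store.size == res.store.size
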
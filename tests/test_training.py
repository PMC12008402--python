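import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octvf import (
    GenConfig,
    TrainConfig,
    augment_sample,
    lr_schedule,
    make_dataset,
    masked_mse,
    patient_wise_folds,
    predict_tta,
    preprocess_volume,
    target_normalizer,
    train_fold,
)
from octvf.labeling import label_vector_vertical_permutation
from octvf.pipeline import prepare_samples
from octvf.training import (
    NormStats,
    SampleArrays,
    _masked_mse_grad,
    flip_sample_vertically,
)


class TestPreprocess:
    def test_minmax_endpoints(self):
        v = np.random.default_rng(0).uniform(0, 255, size=(64, 64, 32))
        cfg = TrainConfig()
        out = preprocess_volume(v, cfg)
        assert out.min() == pytest.approx(-1.0, abs=1e-6)
        assert out.max() == pytest.approx(1.0, abs=1e-6)
        assert out.shape == cfg.input_shape

    def test_constant_volume_maps_to_zeros(self):
        assert np.all(preprocess_volume(np.full((10, 10, 10), 7.0)) == 0)

    def test_downsampled_ramp_stays_monotone(self):
        v = np.broadcast_to(np.linspace(0, 1, 64), (8, 8, 64)).copy()
        out = preprocess_volume(v, TrainConfig(input_shape=(8, 8, 16)))
        assert np.all(np.diff(out[4, 4, :]) >= 0)

    def test_non_3d_rejected(self):
        with pytest.raises(ValueError):
            preprocess_volume(np.zeros((4, 4)))


class TestFolds:
    def test_20_patients_16_2_2(self):
        folds = patient_wise_folds([f"p{i}" for i in range(20)], TrainConfig())
        assert len(folds) == 10
        for f in folds:
            assert (len(f.train), len(f.val), len(f.test)) == (16, 2, 2)
            assert not (f.train & f.val or f.train & f.test or f.val & f.test)

    def test_test_sets_partition_patients(self):
        patients = [f"p{i}" for i in range(23)]
        folds = patient_wise_folds(patients, TrainConfig())
        seen = [p for f in folds for p in f.test]
        assert sorted(seen) == sorted(patients)

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            patient_wise_folds(["a", "b"], TrainConfig())

    def test_samples_of_one_patient_stay_together(self):
        # 5 samples of one patient land in exactly one set of each fold
        ids = np.array([f"p{i}" for i in range(12)] + ["p0"] * 4)
        folds = patient_wise_folds(ids, TrainConfig())
        for f in folds:
            assert sum("p0" in s for s in (f.train, f.val, f.test)) == 1


class TestNormalizer:
    def test_hand_computed_stats(self):
        labels = np.array([[1.0, 10.0], [3.0, 10.0], [5.0, 40.0]])
        masks = np.array([[0, 0], [0, 1], [0, 0]], dtype=float)
        ns = target_normalizer(labels, masks, TrainConfig())
        assert ns.mean[0] == pytest.approx(3.0)
        assert ns.sd[0] == pytest.approx(np.sqrt(8 / 3))
        assert ns.mean[1] == pytest.approx(25.0)  # masked entry excluded
        assert ns.sd[1] == pytest.approx(15.0)

    def test_apply_invert_identity_on_unmasked(self):
        rng = np.random.default_rng(0)
        labels = rng.normal(20, 5, size=(10, 4))
        masks = (rng.random((10, 4)) < 0.3).astype(float)
        masks[0] = 0  # keep every position represented
        ns = target_normalizer(labels, masks, TrainConfig())
        z = ns.apply(labels, masks)
        back = ns.invert(z)
        keep = masks == 0
        assert np.allclose(back[keep], labels[keep])
        assert np.all(z[~keep] == 0.0)

    def test_constant_column_gets_floor(self):
        labels = np.full((5, 1), 7.0)
        masks = np.zeros((5, 1))
        ns = target_normalizer(labels, masks, TrainConfig())
        assert ns.sd[0] == TrainConfig().sd_floor
        assert np.all(ns.apply(labels, masks) == 0.0)

    def test_fully_masked_position_reported(self):
        labels = np.zeros((4, 3))
        masks = np.zeros((4, 3))
        masks[:, 1] = 1
        with pytest.raises(ValueError, match="1"):
            target_normalizer(labels, masks, TrainConfig())


class TestMaskedMSE:
    def test_no_mask_equals_plain_mse(self, rng):
        p, t = rng.normal(size=(4, 122)), rng.normal(size=(4, 122))
        m = np.zeros((4, 122))
        assert masked_mse(p, t, m) == pytest.approx(np.mean((p - t) ** 2))

    def test_identity_zero(self, rng):
        p = rng.normal(size=(2, 122))
        assert masked_mse(p, p, np.zeros_like(p)) == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (int(rng.integers(1, 6)), int(rng.integers(1, 30)))
        p = rng.normal(size=shape)
        t = rng.normal(size=shape)
        m = (rng.random(shape) < 0.4).astype(float)
        if np.all(m == 1):
            m[0, 0] = 0
        # brute force: loop over entries
        acc, n = 0.0, 0
        for i in range(shape[0]):
            for j in range(shape[1]):
                if m[i, j] == 0:
                    acc += (p[i, j] - t[i, j]) ** 2
                    n += 1
        assert masked_mse(p, t, m) == pytest.approx(acc / n, abs=1e-10)

    def test_all_masked_errors(self):
        with pytest.raises(ValueError):
            masked_mse(np.ones((1, 4)), np.ones((1, 4)), np.ones((1, 4)))

    def test_gradient_zero_through_masked_entries(self, rng):
        p = rng.normal(size=(3, 10))
        t = rng.normal(size=(3, 10))
        m = np.zeros((3, 10))
        m[1, 3] = m[2, 7] = 1
        g = _masked_mse_grad(p, t, m)
        assert g[1, 3] == 0.0 and g[2, 7] == 0.0
        # perturbing a masked prediction leaves the loss unchanged
        base = masked_mse(p, t, m)
        p2 = p.copy()
        p2[1, 3] += 123.0
        assert masked_mse(p2, t, m) == base


class TestLRSchedule:
    @pytest.mark.parametrize("epoch,lr", [
        (1, 6e-4), (2, 8e-4), (3, 1e-3), (8, 6e-4),
        (4, 1e-3 + (6e-4 - 1e-3) / 5),
    ])
    def test_schedule_values(self, epoch, lr):
        assert lr_schedule(epoch, TrainConfig()) == pytest.approx(lr)

    @pytest.mark.parametrize("epoch", [0, 9, -1])
    def test_out_of_range(self, epoch):
        with pytest.raises(ValueError):
            lr_schedule(epoch, TrainConfig())


class TestAugmentation:
    def test_flip_is_involution(self, rng):
        v = rng.normal(size=(8, 8, 4))
        lab = rng.normal(size=122)
        mask = (rng.random(122) < 0.2).astype(float)
        v2, l2, m2 = flip_sample_vertically(*flip_sample_vertically(v, lab, mask))
        assert np.array_equal(v2, v)
        assert np.array_equal(l2, lab)
        assert np.array_equal(m2, mask)

    def test_symmetric_sample_is_fixed_point(self):
        v = np.ones((8, 8, 4))
        lab = np.full(122, 25.0)
        mask = np.zeros(122)
        v2, l2, m2 = flip_sample_vertically(v, lab, mask)
        assert np.array_equal(v2, v) and np.array_equal(l2, lab)

    def test_superior_defect_moves_inferior_consistently(self, grid24):
        """A labelled superior-field defect must land on the mirrored
        inferior point while the (inferior-retina) volume damage moves to
        the superior half."""
        perm = label_vector_vertical_permutation()
        nb = list(grid24.non_blind_indices)
        src = nb.index(grid24.index_of(9, 9))      # superior field point
        dst = nb.index(grid24.index_of(9, -9))     # its inferior mirror
        lab = np.full(122, 30.0)
        lab[src] = 10.0
        v = np.zeros((8, 8, 4))
        v[6, :, :] = 1.0  # inferior retina damage (bottom rows)
        v2, l2, _ = flip_sample_vertically(v, lab, np.zeros(122))
        assert l2[dst] == 10.0 and l2[src] == 30.0
        assert np.all(v2[1, :, :] == 1.0)

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_augment_preserves_multisets(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(4, 4, 2))
        lab = rng.normal(size=122)
        mask = np.zeros(122)
        v2, l2, m2 = augment_sample(v, lab, mask, rng, flip_prob=0.5)
        assert sorted(l2) == pytest.approx(sorted(lab))
        assert sorted(v2.ravel()) == pytest.approx(sorted(v.ravel()))


class TestPredictTTA:
    def test_constant_model_unchanged(self, rng):
        class Const:
            def __call__(self, v):
                return np.tile(np.arange(122.0), (len(v), 1))

        v = rng.normal(size=(3, 8, 8, 4)).astype(np.float32)
        out = predict_tta(Const(), v)
        perm = label_vector_vertical_permutation()
        expected = 0.5 * (np.arange(122.0) + np.arange(122.0)[perm])
        assert np.allclose(out, np.tile(expected, (3, 1)))

    def test_linear_model_matches_two_pass_average(self, rng):
        w = rng.normal(size=(8 * 8 * 4, 122)).astype(np.float32)

        class Lin:
            def __call__(self, v):
                return v.reshape(len(v), -1) @ w

        v = rng.normal(size=(2, 8, 8, 4)).astype(np.float32)
        perm = label_vector_vertical_permutation()
        model = Lin()
        manual = 0.5 * (
            model(v) + model(np.ascontiguousarray(v[:, ::-1]))[:, perm]
        )
        assert np.allclose(predict_tta(model, v), manual, atol=1e-5)


def tiny_dataset(n_patients=14, seed=0):
    gen = GenConfig(n_patients=n_patients, volume_shape=(16, 16, 8),
                    exams_per_eye=3, seed=seed, test_retest_sd_db=0.5)
    cfg = TrainConfig(input_shape=(16, 16, 8), seed=seed)
    data = prepare_samples(make_dataset(gen), train_cfg=cfg).samples
    return data, cfg


class TestTrainFold:
    def test_deterministic_given_seed(self):
        data, cfg = tiny_dataset()
        fold = patient_wise_folds(data.patient_ids, cfg)[0]
        r1 = train_fold(data, fold, cfg)
        r2 = train_fold(data, fold, cfg)
        assert r1.val_losses == r2.val_losses
        assert r1.selected_epoch == r2.selected_epoch

    def test_selected_epoch_minimizes_validation_loss(self):
        data, cfg = tiny_dataset()
        fold = patient_wise_folds(data.patient_ids, cfg)[0]
        res = train_fold(data, fold, cfg)
        assert res.selected_epoch == int(np.argmin(res.val_losses)) + 1
        assert len(res.val_losses) == cfg.total_epochs

    def test_training_loss_decreases_on_learnable_set(self):
        data, cfg = tiny_dataset(n_patients=20, seed=3)
        fold = patient_wise_folds(data.patient_ids, cfg)[0]
        res = train_fold(data, fold, cfg)
        assert res.train_losses[-1] < res.train_losses[0]
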
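"""Architecture contracts and training behavior."""

import hashlib
import pickle

import numpy as np
import pytest

from conftest import fast_cfg, make_blob_dataset, split_arrays
from slicemap.exceptions import ParameterError
from slicemap.models import Cnn2dSpec, TrainConfig, _pooled_extent, build_cnn2d, \
    build_cnn3d_patch, build_fusion, run_hyperparameter_search, train_model

SMALL_SPEC = Cnn2dSpec()


class TestBuildCnn2d:
    def test_pooled_side_64_is_8(self):
        assert _pooled_extent(64, 3) == 8

    def test_forward_one_logit_per_sample(self):
        model = build_cnn2d(input_shape=(32, 32), seed=0)
        logits = model.predict_logits(np.zeros((5, 32, 32), dtype=np.float32))
        assert logits.shape == (5,)

    def test_too_small_input_rejected(self):
        with pytest.raises(ParameterError):
            build_cnn2d(input_shape=(4, 4))

    def test_same_seed_identical_parameters(self):
        a = build_cnn2d(input_shape=(16, 16), seed=3)
        b = build_cnn2d(input_shape=(16, 16), seed=3)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_different_seed_differs(self):
        a = build_cnn2d(input_shape=(16, 16), seed=3)
        b = build_cnn2d(input_shape=(16, 16), seed=4)
        assert any(not np.array_equal(pa.value, pb.value)
                   for pa, pb in zip(a.params(), b.params()))

    def test_channels_must_increase(self):
        with pytest.raises(ParameterError):
            Cnn2dSpec(channels=(8, 8, 32))

    def test_translation_invariant_parameter_count(self):
        # weight sharing: conv parameter count does not grow with image size
        small = build_cnn2d(input_shape=(16, 16), seed=0)
        large = build_cnn2d(input_shape=(64, 64), seed=0)
        n_conv = lambda m: sum(p.value.size for layer in m.net.layers
                               for p in layer.params()
                               if layer.__class__.__name__ == "Conv")
        assert n_conv(small) == n_conv(large)


class TestBuildCnn3d:
    def test_pooled_side_24_is_3(self):
        assert _pooled_extent(24, 3) == 3

    def test_forward_batch(self):
        model = build_cnn3d_patch(input_shape=(16, 16, 16), seed=0)
        logits = model.predict_logits(np.zeros((4, 16, 16, 16), dtype=np.float32))
        assert logits.shape == (4,)

    def test_non_cubic_accepted_when_all_sides_large(self):
        model = build_cnn3d_patch(input_shape=(16, 20, 24), seed=0)
        assert model.predict_logits(np.zeros((2, 16, 20, 24), dtype=np.float32)).shape == (2,)

    def test_small_side_rejected(self):
        with pytest.raises(ParameterError):
            build_cnn3d_patch(input_shape=(8, 24, 24))


class TestBuildFusion:
    def test_forward_one_logit(self):
        model = build_fusion([(16, 16), (16, 20), (20, 16)], seed=0)
        xs = [np.zeros((3, 16, 16), dtype=np.float32),
              np.zeros((3, 16, 20), dtype=np.float32),
              np.zeros((3, 20, 16), dtype=np.float32)]
        assert model.predict_logits(xs).shape == (3,)

    def test_requires_three_inputs(self):
        with pytest.raises(ParameterError):
            build_fusion([(16, 16), (16, 16)])

    def test_zero_images_give_constant_logits(self):
        model = build_fusion([(16, 16)] * 3, seed=1)
        xs = [np.zeros((6, 16, 16), dtype=np.float32)] * 3
        logits = model.predict_logits(xs)
        assert np.ptp(logits) < 1e-6


def _small_split(n=96, side=16, effect=3.0, seed=0):
    images, labels, ids = make_blob_dataset(n, side, effect, seed)
    return split_arrays(images, labels, ids, int(0.64 * n), int(0.16 * n))


class TestTrainModel:
    def test_separable_blobs_high_mcc(self):
        tr, va, te = _small_split()
        mccs = []
        for seed in (0, 1):
            model = build_cnn2d(input_shape=(16, 16), seed=seed)
            res = train_model(model, tr, va, te, fast_cfg(seed=seed, max_epochs=12))
            mccs.append(res.test_predictions.metrics()["mcc"])
        assert np.mean(mccs) >= 0.95

    def test_shuffled_labels_near_zero_mcc(self):
        tr, va, te = _small_split()
        rng = np.random.default_rng(9)
        tr = (tr[0], rng.permutation(tr[1]), tr[2])
        va = (va[0], rng.permutation(va[1]), va[2])
        te = (te[0], rng.permutation(te[1]), te[2])
        mccs = []
        for seed in (0, 1, 2):
            model = build_cnn2d(input_shape=(16, 16), seed=seed)
            res = train_model(model, tr, va, te, fast_cfg(seed=seed))
            mccs.append(res.test_predictions.metrics()["mcc"])
        assert abs(np.mean(mccs)) <= 0.15

    def test_zero_epochs_rejected(self):
        with pytest.raises(ParameterError):
            TrainConfig(max_epochs=0)

    def test_single_class_train_rejected(self):
        tr, va, te = _small_split()
        bad = (tr[0], np.zeros_like(tr[1]), tr[2])
        model = build_cnn2d(input_shape=(16, 16), seed=0)
        with pytest.raises(ParameterError):
            train_model(model, bad, va, te, fast_cfg())

    def test_best_epoch_minimizes_val_loss(self):
        tr, va, te = _small_split(n=48)
        model = build_cnn2d(input_shape=(16, 16), seed=0)
        res = train_model(model, tr, va, te, fast_cfg(max_epochs=6))
        losses = res.history["val_loss"].to_numpy()
        assert res.best_epoch == int(np.argmin(losses))

    def test_deterministic_given_seed(self):
        tr, va, te = _small_split(n=48)
        results = []
        for _ in range(2):
            model = build_cnn2d(input_shape=(16, 16), seed=5)
            res = train_model(model, tr, va, te, fast_cfg(seed=5, max_epochs=3))
            results.append(res.test_predictions.logits)
        np.testing.assert_array_equal(results[0], results[1])

    def test_test_set_never_touches_training(self):
        tr, va, te = _small_split(n=48)

        def state_hash(with_test):
            model = build_cnn2d(input_shape=(16, 16), seed=2)
            train_model(model, tr, va, te if with_test else None,
                        fast_cfg(seed=2, max_epochs=3))
            return hashlib.sha256(pickle.dumps(model.state_dict())).hexdigest()

        assert state_hash(True) == state_hash(False)


class TestHyperparameterSearch:
    def test_single_config_returned(self):
        tr, va, te = _small_split(n=48)
        build = lambda cfg, seed: build_cnn2d(input_shape=(16, 16), seed=seed)
        table, best = run_hyperparameter_search(build, tr, va, te,
                                                grid=[{"weight_decay": 0.1}],
                                                base_cfg=fast_cfg(max_epochs=3),
                                                n_repeats=2)
        assert len(table) == 1
        assert best == {"weight_decay": 0.1}
        assert {"mcc_mean", "mcc_sd"} <= set(table.columns)

    def test_signal_config_beats_shuffled(self):
        images, labels, ids = make_blob_dataset(96, 16, 3.0, seed=1)
        shuffled = np.random.default_rng(0).permutation(labels)
        grids = {"true": labels, "shuffled": shuffled}

        def build(cfg, seed):
            return build_cnn2d(input_shape=(16, 16), seed=seed)

        scores = {}
        for name, labs in grids.items():
            tr, va, te = split_arrays(images, labs, ids, 60, 16)
            table, _ = run_hyperparameter_search(build, tr, va, te, [{"tag": name}],
                                                 fast_cfg(max_epochs=8), n_repeats=2)
            scores[name] = table["mcc_mean"].iloc[0]
        assert scores["true"] > scores["shuffled"] + 0.3

    def test_empty_grid_rejected(self):
        with pytest.raises(ParameterError):
            run_hyperparameter_search(lambda c, s: None, None, None, None, [],
                                      fast_cfg(), 1)

    def test_reference_grid_axes_expressible(self):
        # weight decay x StepLR step x batch-norm toggle
        grid = [{"weight_decay": wd, "scheduler_step": step, "use_batch_norm": bn}
                for wd in (0.1, 0.01, 0.001)
                for step in (5, 10, 15, None)
                for bn in (True, False)]
        assert len(grid) == 24
        for cfg in grid[:3]:
            TrainConfig(weight_decay=cfg["weight_decay"],
                        scheduler_step=cfg["scheduler_step"])
            Cnn2dSpec(use_batch_norm=cfg["use_batch_norm"])
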
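"""Architecture assembly, parameter accounting, ablations, training drivers."""

import numpy as np
import pytest

from ccfmcaps import (ArchitectureConfig, TrainConfig, ablate,
                      build_baseline, build_ccfm, count_parameters,
                      export_activations, predict_and_reconstruct, train)
from ccfmcaps.networks import load_weights, save_weights


# ------------------------------------------------- closed-form param ledger
def ccfm_params_oracle(h, w, c, k):
    """Layer-by-layer arithmetic, written independently of the builder."""
    conv = lambda cin, f, kk: f * kk * kk * cin + f
    bn = lambda ch: 4 * ch
    pool = lambda n: (n + 1) // 2
    lane = conv(c, 256, 3) + bn(256) + conv(256, 128, 3) + bn(128)
    hh = pool(pool(h - 2) - 2)
    ww = pool(pool(w - 2) - 2)
    total = 2 * lane + bn(256)
    total += conv(256, 16 * 8, 3)  # primary capsule convolution
    n_caps = (((hh - 3) // 2 + 1) * ((ww - 3) // 2 + 1)) * 16
    total += k * n_caps * 8 * 16  # routing transforms, no bias
    flat = h * w * c
    total += (16 * k) * 512 + 512 + 512 * 1024 + 1024 + 1024 * flat + flat
    return total


def baseline_params_oracle(h, w, c, k):
    conv = lambda cin, f, kk: f * kk * kk * cin + f
    total = conv(c, 256, 9) + conv(256, 32 * 8, 9)
    n_caps = (((h - 8 - 9) // 2 + 1) * ((w - 8 - 9) // 2 + 1)) * 32
    total += k * n_caps * 8 * 16
    flat = h * w * c
    total += (16 * k) * 512 + 512 + 512 * 1024 + 1024 + 1024 * flat + flat
    return total


SHAPES = [(32, 32, 3), (28, 28, 1)]
CLASSES = [2, 3, 4, 8, 10]


class TestParameterAccounting:
    @pytest.mark.parametrize("shape", SHAPES)
    @pytest.mark.parametrize("k", CLASSES)
    def test_ccfm_matches_closed_form(self, shape, k):
        net = build_ccfm(ArchitectureConfig(input_shape=shape, num_classes=k))
        assert count_parameters(net).total == ccfm_params_oracle(*shape, k)

    @pytest.mark.parametrize("shape", SHAPES)
    @pytest.mark.parametrize("k", CLASSES)
    def test_baseline_matches_closed_form(self, shape, k):
        net = build_baseline(ArchitectureConfig(input_shape=shape,
                                                num_classes=k))
        assert count_parameters(net).total == baseline_params_oracle(*shape, k)

    def test_totals_linear_in_class_count(self):
        for oracle, slope in [(ccfm_params_oracle, 26_624),
                              (baseline_params_oracle, 270_336)]:
            totals = [oracle(32, 32, 3, k) for k in range(2, 12)]
            assert set(np.diff(totals)) == {slope}

    def test_feature_lanes_are_parameter_free(self):
        pb = count_parameters(build_ccfm(ArchitectureConfig(num_classes=4)))
        rows = dict(pb.rows)
        for name in ("CLAHE", "CDH", "MP1", "MP2", "MP3", "MP4", "Dropout"):
            assert rows[name] == 0
        assert pb.total == sum(n for _, n in pb.rows)

    def test_breakdown_table_export(self):
        pb = count_parameters(build_baseline(ArchitectureConfig(num_classes=3)))
        df = pb.to_frame()
        assert df["parameters"].sum() == pb.total


class TestShapes:
    def test_printed_shape_chain_32x32(self):
        net = build_ccfm(ArchitectureConfig(input_shape=(32, 32, 3),
                                            num_classes=4))
        s = net.shapes
        assert s["Conv1"] == s["Conv3"] == (30, 30, 256)
        assert s["MP1"] == s["MP3"] == (15, 15, 256)
        assert s["Conv2"] == s["Conv4"] == (13, 13, 128)
        assert s["MP2"] == s["MP4"] == (7, 7, 128)
        assert s["Concat"] == (7, 7, 256)
        assert s["PrimaryCaps"] == (144, 8)

    def test_baseline_capsule_grids(self):
        net = build_baseline(ArchitectureConfig(input_shape=(32, 32, 3),
                                                num_classes=3))
        assert net.shapes["PrimaryCaps"] == (8 * 8 * 32, 8)
        net = build_baseline(ArchitectureConfig(input_shape=(28, 28, 1),
                                                num_classes=10))
        assert net.shapes["PrimaryCaps"] == (6 * 6 * 32, 8)

    def test_empty_capsule_grid_rejected(self):
        with pytest.raises(ValueError):
            build_ccfm(ArchitectureConfig(input_shape=(8, 8, 3),
                                          num_classes=2))

    def test_forward_batch_contract(self, tiny_leaf_set):
        X, _ = tiny_leaf_set
        net = build_ccfm(ArchitectureConfig(input_shape=(16, 16, 3),
                                            num_classes=2))
        scores, recon = predict_and_reconstruct(net, X[:5])
        assert scores.shape == (5, 2)
        assert (scores >= 0).all() and (scores < 1).all()
        assert recon.shape == X[:5].shape

    def test_untrained_reconstruction_deterministic(self, tiny_leaf_set):
        X, _ = tiny_leaf_set
        cfg = ArchitectureConfig(input_shape=(16, 16, 3), num_classes=2,
                                 seed=7)
        _, r1 = predict_and_reconstruct(build_ccfm(cfg), X[:2])
        _, r2 = predict_and_reconstruct(build_ccfm(cfg), X[:2])
        np.testing.assert_array_equal(r1, r2)


class TestAblation:
    def test_empty_removal_is_identity(self):
        cfg = ArchitectureConfig(num_classes=4)
        assert count_parameters(build_ccfm(ablate(cfg, []))).total \
            == count_parameters(build_ccfm(cfg)).total

    def test_dropout_removal_keeps_parameter_count(self):
        cfg = ArchitectureConfig(num_classes=4)
        assert count_parameters(build_ccfm(ablate(cfg, ["Dropout"]))).total \
            == count_parameters(build_ccfm(cfg)).total

    def test_cdh_removal_feeds_raw_image(self, tiny_leaf_set):
        X, _ = tiny_leaf_set
        cfg = ArchitectureConfig(input_shape=(16, 16, 3), num_classes=2)
        net = build_ccfm(ablate(cfg, ["CDH"]))
        assert not net.use_cdh
        x1, x2 = net.prepare_inputs(X[:3])
        np.testing.assert_array_equal(x2, X[:3])
        # shape chain unchanged
        assert net.shapes["Concat"] == build_ccfm(cfg).shapes["Concat"]

    def test_conv_removal_shrinks_and_still_runs(self, tiny_leaf_set):
        X, _ = tiny_leaf_set
        cfg = ArchitectureConfig(input_shape=(16, 16, 3), num_classes=2)
        net = build_ccfm(ablate(cfg, ["Conv2&4", "MP2&4"]))
        assert count_parameters(net).total < count_parameters(
            build_ccfm(cfg)).total
        scores, _ = predict_and_reconstruct(net, X[:2])
        assert scores.shape == (2, 2)

    def test_unknown_component_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ablate(ArchitectureConfig(num_classes=2), ["Conv9"])

    def test_shape_chain_errors_and_ablation_rescue(self):
        # 14 px cannot survive two conv+pool stages plus the capsule conv…
        small = ArchitectureConfig(input_shape=(14, 14, 3), num_classes=2)
        with pytest.raises(ValueError):
            build_ccfm(small)
        # …but removing the first pooling pair leaves a non-empty grid
        net = build_ccfm(ablate(small, ["MP1&3"]))
        assert net.shapes["PrimaryCaps"][0] > 0


class TestTraining:
    def test_single_epoch_history(self, tiny_leaf_set):
        X, y = tiny_leaf_set
        net = build_ccfm(ArchitectureConfig(input_shape=(16, 16, 3),
                                            num_classes=2, seed=0))
        hist = train(net, X, y, TrainConfig(epochs=1, batch_size=10, seed=0))
        assert len(hist) == 1
        assert np.isfinite(hist[0]["loss"])
        assert {"margin", "recon_mse", "train_acc", "lr"} <= hist[0].keys()

    def test_fixed_seed_reproduces_first_epoch(self, tiny_leaf_set):
        X, y = tiny_leaf_set
        losses = []
        for _ in range(2):
            net = build_ccfm(ArchitectureConfig(input_shape=(16, 16, 3),
                                                num_classes=2, seed=3))
            hist = train(net, X, y,
                         TrainConfig(epochs=1, batch_size=10, seed=5))
            losses.append(hist[0]["loss"])
        assert losses[0] == losses[1]

    def test_learning_rate_decays_exponentially(self, tiny_leaf_set):
        X, y = tiny_leaf_set
        net = build_ccfm(ArchitectureConfig(input_shape=(16, 16, 3),
                                            num_classes=2, seed=0))
        hist = train(net, X, y, TrainConfig(epochs=3, batch_size=20, seed=0))
        lrs = [h["lr"] for h in hist]
        assert lrs[1] == pytest.approx(0.9 * lrs[0])
        assert lrs[2] == pytest.approx(0.81 * lrs[0])

    def test_label_count_mismatch_rejected(self, tiny_leaf_set):
        X, y = tiny_leaf_set
        net = build_ccfm(ArchitectureConfig(input_shape=(16, 16, 3),
                                            num_classes=2))
        with pytest.raises(ValueError, match="classes"):
            train(net, X, y + 5, TrainConfig(epochs=1))

    def test_validation_tracking(self, tiny_leaf_set):
        X, y = tiny_leaf_set
        net = build_ccfm(ArchitectureConfig(input_shape=(16, 16, 3),
                                            num_classes=2, seed=0))
        hist = train(net, X[:16], y[:16],
                     TrainConfig(epochs=1, batch_size=8, seed=0),
                     validation=(X[16:], y[16:]))
        assert "val_acc" in hist[0]

    def test_weights_roundtrip(self, tiny_leaf_set, tmp_path):
        X, y = tiny_leaf_set
        cfg = ArchitectureConfig(input_shape=(16, 16, 3), num_classes=2,
                                 seed=1)
        net = build_ccfm(cfg)
        train(net, X, y, TrainConfig(epochs=1, batch_size=10, seed=1))
        s1, _ = predict_and_reconstruct(net, X[:4])
        path = tmp_path / "w.npz"
        save_weights(net, str(path))
        fresh = build_ccfm(ArchitectureConfig(input_shape=(16, 16, 3),
                                              num_classes=2, seed=99))
        load_weights(fresh, str(path))
        s2, _ = predict_and_reconstruct(fresh, X[:4])
        np.testing.assert_allclose(s1, s2, atol=1e-12)


class TestActivationsExport:
    def test_printed_layer_shapes(self, rng):
        net = build_ccfm(ArchitectureConfig(input_shape=(32, 32, 3),
                                            num_classes=3))
        img = rng.random((32, 32, 3))
        assert export_activations(net, img, "Conv1").shape == (30, 30, 256)
        assert export_activations(net, img, "PrimaryCaps").shape == (144, 8)
        assert export_activations(net, img, "ClassCaps").shape == (3, 16)

    def test_unknown_layer_raises(self, rng, tiny_leaf_set):
        X, _ = tiny_leaf_set
        net = build_ccfm(ArchitectureConfig(input_shape=(16, 16, 3),
                                            num_classes=2))
        with pytest.raises(KeyError, match="unknown layer"):
            export_activations(net, X[0], "Conv99")
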
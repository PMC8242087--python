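"""Network contracts: parameter counts, gradients, splits, training basics."""

import numpy as np
import pytest

from diffbp import (ArchitectureConfig, SequenceWindow, TrainConfig,
                    build_model, count_parameters, predict, split_dataset,
                    train)
from diffbp.model import TrainedModel, _loss_and_grads
from diffbp import nn


def closed_form_count(arch: ArchitectureConfig) -> tuple[int, int, int]:
    """Independent layerwise parameter enumeration.

    conv: k*c_in*f + f; batch norm: 4f (2f non-trainable); LSTM:
    4*(u*(c_in+u)+u); dense: c_in*u + u.
    """
    f, k, u = arch.conv_filters, arch.conv_kernel, arch.lstm_units
    d1, d2 = arch.dense_units
    conv = k * 1 * f + f
    bn = 4 * f
    bilstm = 2 * 4 * (u * (f + u) + u)
    lstm1 = 4 * (u * (2 * u + u) + u)
    lstm2 = 4 * (u * (u + u) + u)
    heads = 2 * ((u * d1 + d1) + (d1 * d2 + d2) + (d2 * 1 + 1))
    total = conv + bn + bilstm + lstm1 + lstm2 + heads
    non_trainable = 2 * f
    return total, total - non_trainable, non_trainable


def make_linear_windows(n, seed=0, noise=0.5):
    """Toy task: labels are affine in the fraction of positive samples."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        frac = rng.uniform(0.2, 0.8)
        x = np.where(rng.uniform(size=250) < frac, 1.0, -1.0)
        sbp = 100.0 + 40.0 * frac + rng.normal(0, noise)
        out.append(SequenceWindow(diff=x, sbp_label=sbp, dbp_label=sbp - 45.0,
                                  source_beat=0))
    return out


class TestParameterCounts:
    def test_default_architecture_published_counts(self):
        model = build_model(ArchitectureConfig())
        pc = count_parameters(model)
        assert pc.total == 38_370
        assert pc.trainable == 38_258
        assert pc.non_trainable == 112

    def test_layerwise_closed_forms_default(self):
        """conv 616 + BN 224 + BiLSTM 19,040 + LSTM 9,520 + LSTM 6,384 +
        heads 2,586 = 38,370."""
        arch = ArchitectureConfig()
        total, trainable, non_trainable = closed_form_count(arch)
        assert (616 + 224 + 19_040 + 9_520 + 6_384 + 2_586) == total == 38_370
        pc = count_parameters(build_model(arch))
        assert (pc.total, pc.trainable, pc.non_trainable) == (
            total, trainable, non_trainable)

    @pytest.mark.parametrize("arch", [
        ArchitectureConfig(conv_filters=1, conv_kernel=1, lstm_units=1,
                           dense_units=(1, 1)),
        ArchitectureConfig(conv_filters=8, conv_kernel=5, lstm_units=4,
                           dense_units=(6, 3), input_len=64),
    ])
    def test_closed_form_oracle_other_architectures(self, arch):
        pc = count_parameters(build_model(arch))
        total, trainable, non_trainable = closed_form_count(arch)
        assert (pc.total, pc.trainable, pc.non_trainable) == (
            total, trainable, non_trainable)

    def test_total_is_trainable_plus_non_trainable(self):
        pc = count_parameters(build_model(ArchitectureConfig(
            conv_filters=3, lstm_units=2, dense_units=(4, 2))))
        assert pc.total == pc.trainable + pc.non_trainable


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients of the full two-head loss (incl. conv L2 and
        training-mode batch norm) agree with central differences."""
        arch = ArchitectureConfig(input_len=12, conv_filters=3, conv_kernel=3,
                                  lstm_units=2, dense_units=(3, 2),
                                  l2_lambda=1e-2)
        m = TrainedModel(arch, seed=5)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 12, 1))
        ys, yd = rng.normal(size=4), rng.normal(size=4)

        def loss():
            ps, pd = m.forward(X, training=True)
            return (float(np.mean((ps - ys) ** 2) + np.mean((pd - yd) ** 2))
                    + m.l2_penalty())

        _, _, _, _, ds, dd = _loss_and_grads(m, X, ys, yd, training=True)
        m.backward(ds, dd)
        h = 1e-6
        for lay in m.all_layers():
            for key, p in lay.params.items():
                g = lay.grads[key].ravel()
                flat = p.ravel()
                idxs = np.random.default_rng(1).choice(
                    flat.size, size=min(8, flat.size), replace=False)
                for j in idxs:
                    orig = flat[j]
                    flat[j] = orig + h
                    lp = loss()
                    flat[j] = orig - h
                    lm = loss()
                    flat[j] = orig
                    num = (lp - lm) / (2 * h)
                    assert abs(num - g[j]) < 1e-6 + 1e-4 * abs(num), (
                        f"{type(lay).__name__}.{key}[{j}]")


class TestSplitDataset:
    def test_sizes_100(self):
        ws = make_linear_windows(100)
        tr, va, te = split_dataset(ws, TrainConfig(seed=1))
        assert (len(tr), len(va), len(te)) == (72, 8, 20)

    def test_seeded_and_disjoint_exhaustive(self):
        ws = make_linear_windows(53)
        cfg = TrainConfig(seed=3)
        a = split_dataset(ws, cfg)
        b = split_dataset(ws, cfg)
        for pa, pb in zip(a, b):
            assert [id(w) for w in pa] == [id(w) for w in pb]
        ids = [id(w) for part in a for w in part]
        assert sorted(ids) == sorted(id(w) for w in ws)

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(make_linear_windows(5), TrainConfig())

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(test_fraction=0.0).validate()
        with pytest.raises(ValueError):
            TrainConfig(val_fraction=1.0).validate()


class TestTraining:
    def test_overfits_single_window(self):
        ws = make_linear_windows(1, noise=0.0)
        arch = ArchitectureConfig(conv_filters=4, lstm_units=3,
                                  dense_units=(4, 2))
        model = build_model(arch, seed=0)
        cfg = TrainConfig(max_epochs=120, early_stop_patience=120,
                          batch_size=1, seed=0)
        train(model, ws, [], cfg)
        assert model.history["loss"][-1] < model.history["loss"][0]

    def test_learns_linear_task(self):
        """Validation MSE well below label variance on an affine toy task."""
        ws = make_linear_windows(220, seed=4)
        arch = ArchitectureConfig(conv_filters=6, conv_kernel=8, lstm_units=4,
                                  dense_units=(8, 4))
        model = build_model(arch, seed=1)
        cfg = TrainConfig(max_epochs=30, early_stop_patience=30, seed=1)
        tr, va, te = split_dataset(ws, cfg)
        train(model, tr, va, cfg)
        ys = np.array([w.sbp_label for w in va])
        ps, _ = predict(model, va)
        assert np.mean((ps - ys) ** 2) < 0.1 * ys.var()

    def test_early_stopping_on_constant_labels(self):
        ws = [SequenceWindow(diff=np.zeros(250), sbp_label=120.0,
                             dbp_label=80.0, source_beat=0)
              for _ in range(12)]
        arch = ArchitectureConfig(conv_filters=2, lstm_units=2,
                                  dense_units=(2, 2))
        model = build_model(arch, seed=0)
        cfg = TrainConfig(max_epochs=500, early_stop_patience=3, seed=0)
        train(model, ws[:8], ws[8:], cfg)
        assert len(model.history["loss"]) < 100

    def test_multitask_losses_both_decrease(self):
        ws = make_linear_windows(60, seed=2)
        arch = ArchitectureConfig(conv_filters=4, lstm_units=3,
                                  dense_units=(4, 2))
        model = build_model(arch, seed=2)
        cfg = TrainConfig(max_epochs=15, early_stop_patience=15, seed=2)
        train(model, ws, [], cfg)
        best = model.best_epoch - 1
        assert model.history["loss_sbp"][best] < model.history["loss_sbp"][0]
        assert model.history["loss_dbp"][best] < model.history["loss_dbp"][0]

    def test_training_reproducible(self):
        ws = make_linear_windows(40, seed=6)
        arch = ArchitectureConfig(conv_filters=3, lstm_units=2,
                                  dense_units=(3, 2))
        cfg = TrainConfig(max_epochs=5, early_stop_patience=5, seed=9)
        hist = []
        preds = []
        for _ in range(2):
            m = build_model(arch, seed=9)
            train(m, ws[:30], ws[30:], cfg)
            hist.append(m.history["loss"])
            preds.append(predict(m, ws[30:]))
        assert hist[0] == hist[1]
        np.testing.assert_array_equal(preds[0][0], preds[1][0])
        np.testing.assert_array_equal(preds[0][1], preds[1][1])


class TestPredict:
    @pytest.fixture(scope="class")
    def small_model(self):
        return build_model(ArchitectureConfig(conv_filters=3, lstm_units=2,
                                              dense_units=(3, 2)), seed=3)

    def test_inference_deterministic_and_order_preserving(self, small_model):
        X = np.random.default_rng(5).normal(size=(7, 250, 1))
        a = predict(small_model, X)
        b = predict(small_model, X)
        np.testing.assert_array_equal(a[0], b[0])
        single = predict(small_model, X[3:4])
        assert a[0][3] == pytest.approx(single[0][0])
        assert a[0].shape == a[1].shape == (7,)

    def test_zeroed_output_layer_predicts_zero(self, small_model):
        import copy
        m = copy.deepcopy(small_model)
        for head in m.heads.values():
            head[-1].params["W"][:] = 0.0
            head[-1].params["b"][:] = 0.0
        ps, pd = predict(m, np.ones((3, 250, 1)))
        np.testing.assert_array_equal(ps, np.zeros(3))
        np.testing.assert_array_equal(pd, np.zeros(3))

    def test_wrong_length_rejected(self, small_model):
        with pytest.raises(ValueError, match="shape"):
            predict(small_model, np.zeros((2, 100, 1)))

    def test_divergence_detected(self):
        ws = [SequenceWindow(diff=np.zeros(250), sbp_label=s,
                             dbp_label=s, source_beat=0)
              for s in (1e160, -1e160, 1e160, -1e160)]
        model = build_model(ArchitectureConfig(conv_filters=2, lstm_units=2,
                                               dense_units=(2, 2)), seed=0)
        from diffbp.model import TrainingDiverged
        with pytest.raises((TrainingDiverged, ValueError)):
            train(model, ws, [], TrainConfig(max_epochs=3,
                                             early_stop_patience=3, seed=0))
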
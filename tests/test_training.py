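import math

import numpy as np
import pytest
from scipy.special import logsumexp

from tftf.autodiff import Tensor
from tftf.model_core import TFTFModel, loss_from_logits
from tftf.training import (
    TrainConfig,
    crossvalidate,
    eq_loss,
    f1_plateau_stop,
    loss_plateau_stop,
    stratified_folds,
    train,
)

from conftest import encode_toy, tiny_config


class TestLoss:
    def test_symmetric_logits_ln2(self):
        assert eq_loss([1.3], [1.3], [1]) == pytest.approx(math.log(2), abs=1e-12)
        assert eq_loss([1.3], [1.3], [2]) == pytest.approx(math.log(2), abs=1e-12)

    def test_confident_correct_loss_vanishes(self):
        assert eq_loss([50.0], [0.0], [1]) == pytest.approx(0.0, abs=1e-12)

    def test_two_sample_batch_is_mean(self):
        l1 = eq_loss([2.0], [1.0], [1])
        l2 = eq_loss([0.5], [1.5], [2])
        both = eq_loss([2.0, 0.5], [1.0, 1.5], [1, 2])
        assert both == pytest.approx((l1 + l2) / 2, abs=1e-12)
        # hand evaluation: -log softmax of the true-class output
        assert l1 == pytest.approx(-math.log(math.exp(2) / (math.exp(2) + math.exp(1))))

    def test_matches_independent_logsumexp_cross_entropy(self):
        rng = np.random.default_rng(0)
        x1, x2 = rng.standard_normal(64) * 5, rng.standard_normal(64) * 5
        labels = rng.integers(1, 3, 64)
        logits = np.stack([x1, x2], axis=1)
        expected = float(
            np.mean(logsumexp(logits, axis=1) - logits[np.arange(64), labels - 1])
        )
        assert eq_loss(x1, x2, labels) == pytest.approx(expected, abs=1e-8)

    def test_autodiff_loss_agrees(self):
        rng = np.random.default_rng(1)
        logits = rng.standard_normal((32, 2))
        labels = rng.integers(1, 3, 32)
        auto = float(loss_from_logits(Tensor(logits), labels).data)
        assert auto == pytest.approx(eq_loss(logits[:, 0], logits[:, 1], labels), abs=1e-8)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            eq_loss([], [], [])
        with pytest.raises(ValueError):
            eq_loss([1.0], [0.0], [3])


class TestStopRules:
    def test_f1_plateau_fires_after_window(self):
        # reference 80; the next four epochs all improve < 0.2 points
        seq = [80.0, 80.1, 80.1, 80.1, 80.1]
        assert not f1_plateau_stop(seq[:4])
        assert f1_plateau_stop(seq)  # stop after epoch 5

    def test_f1_plateau_resets_on_improvement(self):
        assert not f1_plateau_stop([80.0, 80.1, 80.1, 80.1, 80.5])

    def test_loss_plateau_needs_full_window(self):
        flat = [0.5] * 50
        assert not loss_plateau_stop(flat)  # only 50 values: no prior window
        assert loss_plateau_stop(flat + [0.5])

    def test_loss_plateau_ignores_steep_descent(self):
        descending = list(np.linspace(3.0, 1.0, 60))
        assert not loss_plateau_stop(descending)


class TestTraining:
    def test_descent_on_single_sample(self):
        model = TFTFModel(tiny_config(seed=0, dtype="float64"))
        data, labels = encode_toy(model, n=1, seed=4)
        labels = np.array([1])
        before = float(loss_from_logits(model.forward(data)[0], labels).data)
        # one optimizer step on that sample strictly decreases its loss
        from tftf.autodiff import Adam

        opt = Adam(model.params, lr=1e-4)
        loss = loss_from_logits(model.forward(data)[0], labels)
        opt.zero_grad(); loss.backward(); opt.step()
        after = float(loss_from_logits(model.forward(data)[0], labels).data)
        assert after < before

    def test_separable_data_reaches_high_accuracy(self):
        model = TFTFModel(tiny_config(seed=1))
        data, labels = encode_toy(model, n=200, seed=2, informative_signal=25.0)
        cfg = TrainConfig(learning_rate=1e-3, batch_size=64, max_epochs=50,
                          stop_rule=None, seed=1)
        history = train(model, data, labels, cfg)
        conf = model.confidences(data)
        acc = ((conf > 0) == (labels == 1)).mean()
        assert acc >= 0.99
        assert history["epochs"] <= 50

    def test_f1_plateau_stops_training(self):
        model = TFTFModel(tiny_config(seed=3))
        data, labels = encode_toy(model, n=80, seed=5, informative_signal=25.0)
        cfg = TrainConfig(learning_rate=1e-3, batch_size=40, max_epochs=40,
                          stop_rule="f1_plateau", seed=0)
        history = train(model, data, labels, cfg)
        assert history["stopped"] in {"f1_plateau", "max_epochs"}
        assert len(history["val_f1"]) == history["epochs"]

    def test_single_class_rejected(self):
        model = TFTFModel(tiny_config(seed=0))
        data, labels = encode_toy(model, n=8)
        with pytest.raises(ValueError):
            train(model, data, np.ones_like(labels), TrainConfig())

    def test_divergence_aborts_with_diagnostic(self):
        model = TFTFModel(tiny_config(seed=0))
        model.params["clf/W2"].data[:] = np.nan
        data, labels = encode_toy(model, n=8)
        with pytest.raises(RuntimeError, match="diverged"):
            train(model, data, labels, TrainConfig(stop_rule=None, max_epochs=1))


class TestCrossValidation:
    def make_cells(self, model, k=4):
        cells = {}
        for i, cell in enumerate(["cellA", "cellB"]):
            data, labels = encode_toy(model, n=4 * k, seed=10 + i,
                                      informative_signal=25.0)
            cells[cell] = (data, labels)
        return cells

    def test_folds_partition_samples(self):
        rng = np.random.default_rng(0)
        labels = np.array([1, 2] * 20)
        folds = stratified_folds(labels, 10, rng)
        assert len(folds) == 40
        for f in range(10):
            sel = folds == f
            assert sel.sum() == 4
            assert (labels[sel] == 1).sum() == 2  # class balance per fold

    def test_fold_assignment_deterministic(self):
        labels = np.array([1, 2] * 50)
        a = stratified_folds(labels, 10, np.random.default_rng(3))
        b = stratified_folds(labels, 10, np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_pooled_f1_is_mean_over_folds(self):
        model_cfg = tiny_config(seed=0)
        cells = self.make_cells(TFTFModel(model_cfg), k=4)
        cfg = TrainConfig(learning_rate=1e-3, batch_size=64, max_epochs=1,
                          stop_rule=None, seed=0)
        res = crossvalidate(lambda: TFTFModel(model_cfg), cells, cfg, k=4, seed=0)
        assert res["mean_f1"] == pytest.approx(
            np.mean([r.f1 for r in res["per_fold"]])
        )
        assert len(res["per_fold"]) == 4
        # every sample appears in exactly one test fold
        for cell, folds in res["fold_assignment"].items():
            assert len(folds) == 16
            assert set(folds) == {0, 1, 2, 3}

    def test_small_cell_excluded_with_warning(self):
        model_cfg = tiny_config(seed=0)
        model = TFTFModel(model_cfg)
        cells = self.make_cells(model, k=4)
        tiny_data, tiny_labels = encode_toy(model, n=4, seed=99)
        cells["tiny"] = (tiny_data, tiny_labels)
        cfg = TrainConfig(learning_rate=1e-3, batch_size=64, max_epochs=1,
                          stop_rule=None, seed=0)
        with pytest.warns(UserWarning, match="tiny"):
            res = crossvalidate(lambda: TFTFModel(model_cfg), cells, cfg, k=4, seed=0)
        assert "tiny" not in res["fold_assignment"]
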
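import math

import numpy as np
import pytest

from tftf.autodiff import Tensor
from tftf.model_core import ModelConfig, Prediction, TFTFModel, balancer_weight_activation
from tftf.tokenization import encode_batch

from conftest import encode_toy, tiny_config


def _naive_attention(x, Wq, bq, Wk, bk, n_heads, head_dim):
    """Explicit-loop multi-head attention probabilities (independent oracle)."""
    L = x.shape[0]
    maps = np.zeros((n_heads, L, L))
    for h in range(n_heads):
        sl = slice(h * head_dim, (h + 1) * head_dim)
        q = x @ Wq[:, sl] + bq[sl]
        k = x @ Wk[:, sl] + bk[sl]
        for i in range(L):
            logits = np.array(
                [np.dot(q[i], k[j]) / math.sqrt(head_dim) for j in range(L)]
            )
            e = np.exp(logits - logits.max())
            maps[h, i] = e / e.sum()
    return maps


class TestAttention:
    def test_matches_explicit_loop_oracle(self):
        """Multi-head attention equals a naive per-head loop implementation."""
        model = TFTFModel(ModelConfig(seed=3, dtype="float64"))
        c = model.config
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1, 4, c.embed_dim))
        keep = np.ones((1, 1, 1, 4), bool)
        maps = []
        model._block(Tensor(x), "trf0", keep, maps)
        p = model.params
        expected = _naive_attention(
            x[0], p["trf0/Wq"].data, p["trf0/bq"].data,
            p["trf0/Wk"].data, p["trf0/bk"].data, c.n_heads, c.head_dim,
        )
        assert np.allclose(maps[0][0], expected, atol=1e-6)

    def test_rows_sum_to_one_every_head_and_block(self, tiny_model):
        data, _ = encode_toy(tiny_model, n=4)
        _, _, maps = tiny_model.forward(data, collect_attention=True)
        for block in maps:
            sums = block.sum(axis=-1)
            assert np.allclose(sums, 1.0, atol=1e-5)

    def test_head_dimension_algebra(self):
        model = TFTFModel(ModelConfig(seed=0))
        p = model.params
        assert p["trf0/Wq"].data.shape == (8, 8 * 16)  # embed 8 -> 8 heads x 16
        assert p["trf0/Wo"].data.shape == (128, 8)  # concat 128 -> embed 8

    def test_post_norm_output_is_standardized(self, tiny_model):
        """Post-norm blocks end in layer norm: per-position mean 0, var 1
        at initialisation (gamma = 1, beta = 0)."""
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 8, tiny_model.config.embed_dim)).astype(np.float32)
        keep = np.ones((2, 1, 1, 8), bool)
        out = tiny_model._block(Tensor(x), "trf0", keep, None)
        assert np.allclose(out.data.mean(axis=-1), 0.0, atol=1e-4)
        assert np.allclose(out.data.var(axis=-1), 1.0, atol=1e-2)


class TestBalancer:
    def test_activation_identity_and_range(self):
        assert balancer_weight_activation(0.0) == 1.0
        # mathematically open interval (0, 2); strictly inside at moderate x
        assert 0 < balancer_weight_activation(-10.0) < balancer_weight_activation(10.0) < 2
        xs = np.linspace(-50, 50, 100001)
        w = balancer_weight_activation(xs)
        # limits: sup 2 (reached only at machine precision), inf 0
        assert w.max() == 2.0 and w.min() == 0.0
        assert np.all(np.diff(w) >= 0)  # monotone

    def test_zeroed_head_gives_unit_weights(self, tiny_model):
        model = TFTFModel(tiny_config(seed=5))
        model.params["bal_head/W"].data[:] = 0
        model.params["bal_head/b"].data[:] = 0
        data, _ = encode_toy(model, n=4)
        _, weights, _ = model.forward(data)
        assert np.allclose(weights, 1.0)  # Weight(0) = 1 for both neurons

    def test_weights_strictly_inside_0_2(self, tiny_model):
        data, _ = encode_toy(tiny_model, n=8)
        _, weights, _ = tiny_model.forward(data)
        assert np.all(weights > 0) and np.all(weights < 2)

    def test_frozen_override_dna_only(self, tiny_model):
        data, _ = encode_toy(tiny_model, n=4)
        _, weights, _ = tiny_model.forward(data, balancer_override=(1.0, 0.0))
        assert np.all(weights == [1.0, 0.0])

    def test_no_omics_forces_dna_only(self):
        model = TFTFModel(tiny_config(n_omics=0, seed=2))
        seqs = ["ACGT" * 25 + "A"] * 3
        data = encode_batch(seqs, [[] for _ in seqs], model.vocab, model.binning)
        logits, weights, _ = model.forward(data)
        assert np.all(weights == [1.0, 0.0])
        assert logits.data.shape == (3, 2)


class TestForward:
    def test_deterministic_embeddings_and_outputs(self, tiny_model):
        data, _ = encode_toy(tiny_model, n=4)
        l1, w1, _ = tiny_model.forward(data)
        l2, w2, _ = tiny_model.forward(data)
        assert np.array_equal(l1.data, l2.data) and np.array_equal(w1, w2)

    def test_pad_tail_content_cannot_leak(self, tiny_model):
        data, _ = encode_toy(tiny_model, n=4)
        l1, _, _ = tiny_model.forward(data)
        poisoned = {k: (v.copy() if hasattr(v, "copy") else v) for k, v in data.items()}
        pad = poisoned["mask"]  # PAD slots
        poisoned["dna"][pad] = 5  # arbitrary real token ids in the PAD tail
        for j in range(poisoned["omics"].shape[0]):
            poisoned["omics"][j][pad] = 7
        l2, _, _ = tiny_model.forward(poisoned)
        assert np.array_equal(l1.data, l2.data)

    def test_out_of_vocabulary_id_rejected(self, tiny_model):
        data, _ = encode_toy(tiny_model, n=2)
        data["dna"][0, 1] = 999
        with pytest.raises(ValueError):
            tiny_model.forward(data)

    def test_confidence_definition(self):
        p = Prediction.from_outputs(1.5, 0.25)
        assert p.confidence == 1.5 - 0.25 and p.label is True
        assert Prediction.from_outputs(-1.0, 2.0).label is False

    def test_parameter_count_reported(self):
        model = TFTFModel(ModelConfig(seed=0))
        n = model.transformer_parameter_count()
        assert 10_000 < n < 100_000  # same order as the full-size network
        assert model.num_parameters() > n


class TestCheckpoint:
    def test_roundtrip_bit_identical(self, tmp_path, tiny_model):
        path = tmp_path / "ckpt.npz"
        tiny_model.save(path)
        back = TFTFModel.load(path)
        assert back.config == tiny_model.config
        assert np.array_equal(back.binning.edges, tiny_model.binning.edges)
        for k in tiny_model.params:
            assert np.array_equal(back.params[k].data, tiny_model.params[k].data)
        data, _ = encode_toy(tiny_model, n=3)
        assert np.array_equal(
            tiny_model.forward(data)[0].data, back.forward(data)[0].data
        )

    def test_save_is_byte_deterministic(self, tmp_path, tiny_model):
        tiny_model.save(tmp_path / "a.npz")
        tiny_model.save(tmp_path / "b.npz")
        assert (tmp_path / "a.npz").read_bytes() == (tmp_path / "b.npz").read_bytes()

    def test_same_seed_same_init(self):
        a = TFTFModel(tiny_config(seed=11))
        b = TFTFModel(tiny_config(seed=11))
        for k in a.params:
            assert np.array_equal(a.params[k].data, b.params[k].data)
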
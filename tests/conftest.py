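import numpy as np
import pytest

from tftf.model_core import ModelConfig, TFTFModel
from tftf.synthetic import WorldConfig, generate
from tftf.tokenization import encode_batch


def tiny_config(**kw) -> ModelConfig:
    """A scaled-down architecture for fast unit tests."""
    base = dict(
        n_heads=2, head_dim=4, balancer_blocks=1, transformer_blocks=1,
        ffn_hidden=8, classifier_hidden=8, seed=0,
    )
    base.update(kw)
    return ModelConfig(**base)


@pytest.fixture(scope="session")
def tiny_model():
    return TFTFModel(tiny_config())


@pytest.fixture(scope="session")
def small_world():
    """A small 3-cell world used by IO/scan/CLI tests."""
    return generate(
        WorldConfig(
            genome_length=60_000, n_cell_types=3, n_sites=8, n_decoys=4,
            p_bind=0.7, min_gap=1200, seed=7,
        )
    )


def toy_batch(n=32, seed=0, separable=True, informative_signal=10.0):
    """Random 101-bp windows; even indices get a signal bump (positives)."""
    rng = np.random.default_rng(seed)
    seqs, sigs, labels = [], [], []
    x = np.arange(101)
    for i in range(n):
        pos = i % 2 == 0
        seq = "".join(rng.choice(list("ACGT"), 101))
        sig = rng.exponential(1.0, 101)
        if pos and separable:
            sig = sig + informative_signal * np.exp(-((x - 50) ** 2) / (2 * 20.0**2))
        seqs.append(seq)
        sigs.append([sig])
        labels.append(1 if pos else 2)
    return seqs, sigs, np.array(labels)


def encode_toy(model, n=32, seed=0, **kw):
    seqs, sigs, labels = toy_batch(n, seed, **kw)
    return encode_batch(seqs, sigs, model.vocab, model.binning), labels
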